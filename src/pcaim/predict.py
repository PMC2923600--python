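"""k-nearest-neighbor prediction of latitude/longitude in PC space.

A test sample is placed at the unweighted arithmetic mean of the coordinates
of its k nearest training samples under Euclidean distance in the top-2 PC
projection (k = 10 by default). Inverse-distance weighting and a circular
longitude mean are available as options; neither is on by default because
simple averaging performs comparably at continental scale.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import (
    GenotypeMatrix,
    GeoTable,
    Panel,
    PredictionRecord,
    ValidationError,
)
from .io import encode_and_center
from .pca import fit_pca, project


class KNNCoordinateRegressor(RegressorMixin, BaseEstimator):
    """Predict (latitude, longitude) as the mean over k nearest neighbors.

    Parameters
    ----------
    n_neighbors : int, default 10
    weighting : None or "inverse-distance", default None
        Optional inverse-distance-power weighting of neighbor coordinates.
    power : float, default 1.0
        Exponent for inverse-distance weighting.
    circular_longitude : bool, default False
        Average longitudes on the circle (needed only when data straddle
        the +/-180 meridian).
    tie_break : sequence of str, optional keys; ties in distance are broken
        by ascending key (falling back to training index order).
    """

    def __init__(
        self,
        n_neighbors: int = 10,
        weighting: str | None = None,
        power: float = 1.0,
        circular_longitude: bool = False,
    ):
        self.n_neighbors = n_neighbors
        self.weighting = weighting
        self.power = power
        self.circular_longitude = circular_longitude

    def fit(self, X, y, tie_break: Sequence | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must be >= 1")
        if X.ndim != 2 or y.shape != (X.shape[0], 2):
            raise ValueError("X must be (n, d) and y (n, 2) of (lat, lon)")
        if X.shape[0] == 0:
            raise ValidationError("empty training set")
        self.X_ = X
        self.y_ = y
        if tie_break is None:
            self.tie_rank_ = np.arange(X.shape[0])
        else:
            # rank of each training sample under its tie-break key
            order = np.argsort(np.asarray(tie_break), kind="stable")
            self.tie_rank_ = np.empty(X.shape[0], dtype=int)
            self.tie_rank_[order] = np.arange(X.shape[0])
        self.n_features_in_ = X.shape[1]
        return self

    def kneighbors(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(distances, indices) of the k nearest training samples per row,
        sorted by (distance, tie-break key)."""
        X = np.asarray(X, dtype=float)
        k = self.n_neighbors
        if k > self.X_.shape[0]:
            warnings.warn(
                f"n_neighbors={k} exceeds {self.X_.shape[0]} training samples; "
                "using all of them",
                stacklevel=2,
            )
            k = self.X_.shape[0]
        d = cdist(X, self.X_)
        out_d = np.empty((X.shape[0], k))
        out_i = np.empty((X.shape[0], k), dtype=int)
        for i in range(X.shape[0]):
            order = np.lexsort((self.tie_rank_, d[i]))[:k]
            out_i[i] = order
            out_d[i] = d[i, order]
        return out_d, out_i

    def predict(self, X) -> np.ndarray:
        dists, idx = self.kneighbors(X)
        preds = np.empty((len(idx), 2))
        for i in range(len(idx)):
            preds[i] = self._aggregate(self.y_[idx[i]], dists[i])
        return preds

    def _aggregate(self, coords: np.ndarray, dists: np.ndarray) -> np.ndarray:
        if self.weighting is None:
            w = None  # plain mean, exact when all neighbor coords coincide
        elif self.weighting == "inverse-distance":
            if (dists == 0).any():
                w = (dists == 0).astype(float)  # exact matches dominate
            else:
                w = dists ** (-self.power)
            w = w / w.sum()
        else:
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        lat = float(coords[:, 0].mean() if w is None else w @ coords[:, 0])
        if self.circular_longitude:
            ww = np.full(len(coords), 1.0 / len(coords)) if w is None else w
            rad = np.deg2rad(coords[:, 1])
            lon = float(np.rad2deg(np.arctan2(ww @ np.sin(rad), ww @ np.cos(rad))))
        else:
            lon = float(coords[:, 1].mean() if w is None else w @ coords[:, 1])
        return np.array([lat, lon])


def knn_predict(
    train_scores: np.ndarray,
    train_geo: GeoTable,
    test_scores: np.ndarray,
    k_neighbors: int = 10,
    train_sample_ids: Sequence[str] | None = None,
    test_sample_ids: Sequence[str] | None = None,
    weighting: str | None = None,
    power: float = 1.0,
    circular_longitude: bool = False,
) -> list[PredictionRecord]:
    """Predict coordinates for every row of ``test_scores``.

    Training rows align with ``train_sample_ids`` (default: the GeoTable's
    order). Distance ties are broken by training sample id.
    """
    if train_sample_ids is None:
        train_sample_ids = train_geo.sample_ids
    train_sample_ids = list(train_sample_ids)
    coords = train_geo.coords_for(train_sample_ids)
    reg = KNNCoordinateRegressor(
        n_neighbors=k_neighbors,
        weighting=weighting,
        power=power,
        circular_longitude=circular_longitude,
    ).fit(np.asarray(train_scores, float), coords, tie_break=train_sample_ids)
    dists, idx = reg.kneighbors(np.asarray(test_scores, float))
    preds = np.array(
        [reg._aggregate(coords[idx[i]], dists[i]) for i in range(len(idx))]
    ).reshape(-1, 2)
    if test_sample_ids is None:
        test_sample_ids = [f"test{i}" for i in range(len(preds))]
    return [
        PredictionRecord(
            sample_id=str(sid),
            predicted_lat=float(preds[i, 0]),
            predicted_lon=float(preds[i, 1]),
            neighbor_ids=[train_sample_ids[j] for j in idx[i]],
            neighbor_distances=dists[i],
        )
        for i, sid in enumerate(test_sample_ids)
    ]


def predict_from_panel(
    train_g: GenotypeMatrix,
    train_geo: GeoTable,
    test_g: GenotypeMatrix,
    panel: Panel,
    k_pcs: int = 2,
    k_neighbors: int = 10,
    weighting: str | None = None,
    circular_longitude: bool = False,
) -> list[PredictionRecord]:
    """The composed pipeline: restrict to the panel, encode/center on the
    training cohort, fit PCA, project the test cohort, k-NN average.

    Panel SNPs absent from the test cohort are dropped from both cohorts
    (the model is fitted on the intersection). All centering statistics come
    from the training cohort only.
    """
    panel_ids = panel.snp_ids
    missing_train = set(panel_ids) - set(train_g.snp_ids)
    if missing_train:
        raise ValidationError(
            f"{len(missing_train)} panel SNPs absent from training data"
        )
    shared = [s for s in panel_ids if s in set(test_g.snp_ids)]
    if not shared:
        raise ValidationError("no panel SNPs present in the test cohort")
    train_sub = train_g.subset_snp_ids(shared)
    model = fit_pca(encode_and_center(train_sub), k=k_pcs)
    train_scores = model.training_scores
    test_scores = project(model, test_g)
    return knn_predict(
        train_scores,
        train_geo,
        test_scores,
        k_neighbors=k_neighbors,
        train_sample_ids=train_g.sample_ids,
        test_sample_ids=test_g.sample_ids,
        weighting=weighting,
        circular_longitude=circular_longitude,
    )
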