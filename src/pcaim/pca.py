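"""Truncated SVD of centered genotype matrices and projection of new samples.

The decomposition is computed on the mean-imputed, column-centered dosage
matrix directly (no per-SNP variance normalization by default; a scaling
switch exists for sensitivity analysis). Component signs are canonicalized —
the largest-magnitude loading of each right singular vector is made positive
— so repeated runs are bit-reproducible. k-NN prediction downstream depends
only on pairwise distances and is provably unaffected by sign choices.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import svds
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CenteredMatrix, GenotypeMatrix, PCAModel, ValidationError

#: below this size a dense LAPACK SVD is cheaper and exact
_DENSE_LIMIT = 400


def _truncated_svd(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k SVD factors (U, s, Vt) of x, deterministic, s non-increasing."""
    n, p = x.shape
    r = min(n, p)
    if not 1 <= k <= r:
        raise ValidationError(f"k={k} out of range for a {n}x{p} matrix")
    if r <= _DENSE_LIMIT or k >= r - 1:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        # fixed start vector keeps ARPACK fully deterministic
        v0 = np.linspace(1.0, 2.0, r)
        u, s, vt = svds(x, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    s = np.maximum(s, 0.0)
    return _canonicalize_signs(u, s, vt)


def _canonicalize_signs(
    u: np.ndarray, s: np.ndarray, vt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # sign convention: the largest-|.| loading of each component is positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    return u, s, vt


class GenotypePCA(TransformerMixin, BaseEstimator):
    """Principal components of a genotype dosage matrix.

    Accepts raw dosages with NaN for missing calls; fitting mean-imputes and
    centers columns, then computes the top ``n_components`` singular triplets.

    Parameters
    ----------
    n_components : int, default 2
        Number of principal components retained. Geographic inference uses
        the top two, which track the main axes of spatial structure.
    scale : bool, default False
        If True, divide each centered column by its standard deviation
        before the SVD (unit-variance SNPs).

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
        Per-SNP means of observed dosages (imputation values).
    components_ : ndarray of shape (n_components, n_features)
        Right singular vectors, orthonormal rows, canonical signs.
    singular_values_ : ndarray of shape (n_components,)
        Non-increasing, non-negative.
    scores_ : ndarray of shape (n_samples, n_components)
        Training-sample PC coordinates U_k Sigma_k.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x SNPs)")
        n, p = X.shape
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValidationError(
                f"n_components={self.n_components} out of range for {n}x{p} data"
            )
        if np.isnan(X).all(axis=0).any():
            j = int(np.flatnonzero(np.isnan(X).all(axis=0))[0])
            raise ValidationError(f"column {j} has every entry missing")
        self.mean_ = np.nanmean(X, axis=0)
        xc = X - self.mean_
        xc[np.isnan(xc)] = 0.0
        if self.scale:
            sd = xc.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
            xc = xc / self.scale_
        else:
            self.scale_ = None
        u, s, vt = _truncated_svd(xc, self.n_components)
        self.components_ = vt
        self.singular_values_ = s
        self.scores_ = u * s
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got {X.shape}"
            )
        xc = X - self.mean_
        xc = np.where(np.isnan(xc), 0.0, xc)  # missing -> training mean -> 0
        if self.scale_ is not None:
            xc = xc / self.scale_
        return xc @ self.components_.T


# ---------------------------------------------------------------------------
# functional surface over CenteredMatrix / GenotypeMatrix containers
# ---------------------------------------------------------------------------


def fit_pca(x: CenteredMatrix, k: int = 2) -> PCAModel:
    """Fit the top-k SVD of a centered genotype matrix."""
    n, p = x.values.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValidationError(f"k={k} out of range for {n} samples x {p} SNPs")
    u, s, vt = _truncated_svd(x.values, k)
    if x.snp_ids is None:
        raise ValidationError("CenteredMatrix lacks SNP ids; fit from encode_and_center")
    return PCAModel(
        k=k,
        right_vectors=vt.T,
        singular_values=s,
        column_means=x.column_means,
        training_scores=u * s,
        snp_ids=list(x.snp_ids),
    )


def project(
    m: PCAModel, g: GenotypeMatrix, min_presence: float = 0.5
) -> np.ndarray:
    """Project a cohort into the model's PC space using training statistics.

    Model SNPs absent from ``g`` are imputed with the training mean (zero
    contribution). Fewer than ``min_presence`` of model SNPs present raises —
    the panel is unusable on such data.
    """
    lookup = {s: j for j, s in enumerate(g.snp_ids)}
    cols = np.array([lookup.get(s, -1) for s in m.snp_ids])
    present = cols >= 0
    if present.mean() < min_presence:
        raise ValidationError(
            f"only {present.sum()} of {len(m.snp_ids)} model SNPs present "
            f"(below the {min_presence:.0%} floor)"
        )
    x = np.full((g.n_samples, len(m.snp_ids)), np.nan)
    x[:, present] = g.values[:, cols[present]]
    xc = x - m.column_means
    xc = np.where(np.isnan(xc), 0.0, xc)
    return xc @ m.right_vectors


def save_pca_model(m: PCAModel, out_dir) -> None:
    """Serialize a PCAModel as a directory of tab-separated text files."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vec = pd.DataFrame(
        m.right_vectors, columns=[f"PC{i + 1}" for i in range(m.k)]
    )
    vec.insert(0, "snp_id", m.snp_ids)
    vec.insert(1, "column_mean", m.column_means)
    vec.to_csv(out / "loadings.tsv", sep="\t", index=False)
    pd.DataFrame({"singular_value": m.singular_values}).to_csv(
        out / "singular_values.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        m.training_scores, columns=[f"PC{i + 1}" for i in range(m.k)]
    ).to_csv(out / "training_scores.tsv", sep="\t", index=False)


def load_pca_model(in_dir) -> PCAModel:
    import pandas as pd
    from pathlib import Path

    src = Path(in_dir)
    vec = pd.read_csv(src / "loadings.tsv", sep="\t", dtype={"snp_id": str})
    sv = pd.read_csv(src / "singular_values.tsv", sep="\t")
    scores = pd.read_csv(src / "training_scores.tsv", sep="\t")
    k = len(sv)
    return PCAModel(
        k=k,
        right_vectors=vec[[f"PC{i + 1}" for i in range(k)]].to_numpy(float),
        singular_values=sv["singular_value"].to_numpy(float),
        column_means=vec["column_mean"].to_numpy(float),
        training_scores=scores.to_numpy(float),
        snp_ids=vec["snp_id"].tolist(),
    )
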