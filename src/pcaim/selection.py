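"""Leverage-score ranking of SNPs and greedy redundancy-pruned panel building.

A SNP's score is its leverage on the retained PC subspace: the sum of squared
entries of its row across the top-k right singular vectors. Because those
columns are orthonormal, scores over all SNPs sum to exactly k. Panels are
built by walking the top-scoring pool in rank order and accepting a SNP only
if its squared Pearson correlation with every already-accepted SNP stays at
or below a threshold — the simplest redundancy-removal procedure with a
checkable pairwise guarantee.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin

from .datatypes import CenteredMatrix, Panel, PCAModel, ValidationError
from .pca import GenotypePCA, fit_pca


def leverage_scores(right_vectors: np.ndarray, singular_values=None) -> np.ndarray:
    """Per-SNP leverage on the span of the top-k right singular vectors.

    ``right_vectors`` is (n_snps, k). With ``singular_values`` given, each
    component's squared loading is weighted by sigma_i**2 (variance-weighted
    variant); unweighted by default.
    """
    v = np.asarray(right_vectors, dtype=float)
    if singular_values is None:
        return (v**2).sum(axis=1)
    w = np.asarray(singular_values, dtype=float) ** 2
    return (v**2 * w).sum(axis=1)


def _rank_table(snp_ids: Sequence[str], scores: np.ndarray) -> pd.DataFrame:
    # descending score, ties broken lexicographically by snp id
    ids = np.asarray([str(s) for s in snp_ids])
    order = np.lexsort((ids, -scores))
    table = pd.DataFrame(
        {"snp_id": ids[order], "score": scores[order],
         "rank": np.arange(1, len(ids) + 1)}
    )
    return table[["snp_id", "score", "rank"]]


def compute_pcaim_scores(m: PCAModel, weighted: bool = False) -> pd.DataFrame:
    """Score table (snp_id, score, rank) for every SNP of a fitted model."""
    scores = leverage_scores(
        m.right_vectors, m.singular_values if weighted else None
    )
    return _rank_table(m.snp_ids, scores)


def build_pool(score_table: pd.DataFrame, pool_size: int) -> list[str]:
    """Top ``pool_size`` SNP ids by rank — the candidate pool for pruning."""
    if pool_size > len(score_table):
        raise ValidationError(
            f"pool_size {pool_size} exceeds {len(score_table)} scored SNPs"
        )
    ranked = score_table.sort_values("rank", kind="stable")
    return ranked["snp_id"].head(pool_size).tolist()


def _normalized_columns(x: np.ndarray) -> np.ndarray:
    """Unit-norm centered columns; zero-variance columns become zero vectors."""
    norms = np.linalg.norm(x, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return x / safe


def greedy_redundancy_prune(
    pool: Sequence[str],
    x: CenteredMatrix,
    r2_threshold: float = 0.8,
    target_size: int | None = None,
    scores: dict[str, float] | None = None,
) -> Panel:
    """Walk the pool in rank order, accepting SNPs whose r^2 with every
    already-accepted SNP stays <= ``r2_threshold``; stop at ``target_size``.

    A zero-variance (monomorphic) column is uncorrelated with everything by
    convention (r = 0). Emits a warning if the pool is exhausted before the
    target is reached.
    """
    if not 0 < r2_threshold <= 1:
        raise ValidationError(f"r2_threshold must lie in (0, 1], got {r2_threshold}")
    if target_size is None:
        target_size = len(pool)
    if target_size > len(pool):
        raise ValidationError(
            f"target_size {target_size} exceeds pool of {len(pool)}"
        )
    if x.snp_ids is None:
        raise ValidationError("CenteredMatrix lacks SNP ids")
    col_of = {s: j for j, s in enumerate(x.snp_ids)}
    cols = np.array([col_of[s] for s in pool])
    z = _normalized_columns(x.values[:, cols])  # n x |pool|

    accepted: list[int] = []  # indices into pool
    q = np.empty((z.shape[0], target_size))  # accepted unit columns
    for i in range(len(pool)):
        c = z[:, i]
        if accepted:
            r = q[:, : len(accepted)].T @ c
            if np.max(r**2) > r2_threshold:
                continue
        q[:, len(accepted)] = c
        accepted.append(i)
        if len(accepted) == target_size:
            break
    exhausted = len(accepted) < target_size
    if exhausted:
        warnings.warn(
            f"pool exhausted: {len(accepted)} of {target_size} SNPs accepted "
            f"at r2 <= {r2_threshold}",
            stacklevel=2,
        )
    ids = [pool[i] for i in accepted]
    return _panel_from_ids(
        ids, x, scores,
        provenance={
            "pool_size": len(pool),
            "target_size": target_size,
            "r2_threshold": r2_threshold,
            "exhausted": exhausted,
        },
    )


def _panel_from_ids(ids, x: CenteredMatrix, scores, provenance) -> Panel:
    if x.snp_meta is not None:
        meta = x.snp_meta.set_index("id")
        chrom = [meta.loc[s, "chrom"] for s in ids]
        pos = [int(meta.loc[s, "pos"]) for s in ids]
    else:
        chrom = ["un"] * len(ids)
        pos = list(range(1, len(ids) + 1))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ids) + 1),
            "snp_id": ids,
            "chrom": chrom,
            "pos": pos,
            "score": [scores.get(s, np.nan) if scores else np.nan for s in ids],
        }
    )
    return Panel(table, provenance)


def build_panels(
    x: CenteredMatrix,
    sizes: Sequence[int] = (500, 800, 1000),
    pool_size: int = 5000,
    r2_threshold: float = 0.8,
    k: int = 2,
    weighted: bool = False,
) -> list[Panel]:
    """Fit PCA, rank SNPs, prune once to max(sizes); smaller panels are
    prefixes of the largest (panels are nested)."""
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValidationError("panel sizes must be ascending")
    pool_size = min(pool_size, len(x.snp_ids or []))
    model = fit_pca(x, k=k)
    score_table = compute_pcaim_scores(model, weighted=weighted)
    pool = build_pool(score_table, pool_size)
    score_of = dict(zip(score_table["snp_id"], score_table["score"]))
    largest = greedy_redundancy_prune(
        pool, x, r2_threshold=r2_threshold, target_size=min(sizes[-1], pool_size),
        scores=score_of,
    )
    largest.provenance.update({"k": k, "pool_size": pool_size})
    panels = []
    for size in sizes:
        p = largest.head(min(size, len(largest)))
        p.provenance["target_size"] = size
        panels.append(p)
    return panels


class PCAIMSelector(SelectorMixin, BaseEstimator):
    """Select a PCA-informative SNP panel from a raw dosage matrix.

    Fitting mean-imputes/centers the data, fits the top ``n_components``
    principal components, ranks SNPs by leverage score, keeps the top
    ``pool_size`` as candidates, and greedily prunes redundant candidates at
    the ``r2_threshold`` until ``panel_size`` SNPs are accepted.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Leverage score of every SNP (sums to ``n_components``).
    panel_indices_ : ndarray
        Column indices of the selected panel, in selection (descending
        score) order.
    """

    def __init__(
        self,
        panel_size: int = 500,
        pool_size: int = 5000,
        r2_threshold: float = 0.8,
        n_components: int = 2,
        weighted: bool = False,
    ):
        self.panel_size = panel_size
        self.pool_size = pool_size
        self.r2_threshold = r2_threshold
        self.n_components = n_components
        self.weighted = weighted

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        pca = GenotypePCA(n_components=self.n_components).fit(X)
        self.scores_ = leverage_scores(
            pca.components_.T,
            pca.singular_values_ if self.weighted else None,
        )
        ids = [f"{j:09d}" for j in range(p)]  # index-lexicographic tie-break
        table = _rank_table(ids, self.scores_)
        pool = build_pool(table, min(self.pool_size, p))
        xc = X - pca.mean_
        xc = np.where(np.isnan(xc), 0.0, xc)
        cm = CenteredMatrix(
            values=xc, column_means=pca.mean_, snp_ids=ids, sample_ids=None
        )
        panel = greedy_redundancy_prune(
            pool, cm, r2_threshold=self.r2_threshold,
            target_size=min(self.panel_size, len(pool)),
        )
        self.panel_indices_ = np.array([int(s) for s in panel.snp_ids])
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.panel_indices_] = True
        return mask

    def transform(self, X):
        # keep columns in selection order and tolerate NaN (missing calls)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got {X.shape[1]}"
            )
        return X[:, self.panel_indices_]
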