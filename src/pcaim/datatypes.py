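"""Core containers for genotype-based geographic ancestry inference.

Genotypes are stored as allele-count dosages in {0, 1, 2} with ``NaN`` for
missing calls, alongside per-SNP metadata (id, chromosome, 1-based position,
alleles) and per-sample coordinates (population label, latitude, longitude in
decimal degrees, one shared location per population).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (stored as NaN in float arrays).
MISSING = np.nan

SNP_META_COLUMNS = ["id", "chrom", "pos", "ref_allele", "alt_allele"]


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class GenotypeMatrix:
    """A samples x SNPs dosage matrix with metadata.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_snps)
        Float array; each entry is 0, 1, 2 or NaN (missing).
    snp_meta : DataFrame
        One row per SNP with columns ``id, chrom, pos, ref_allele, alt_allele``.
        Positions are 1-based (VCF convention).
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    """

    values: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x SNPs array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValidationError(f"snp_meta lacks columns {sorted(missing_cols)}")
        if len(self.snp_meta) != self.values.shape[1]:
            raise ValidationError(
                f"snp_meta has {len(self.snp_meta)} rows for "
                f"{self.values.shape[1]} matrix columns"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.values.shape[0]} matrix rows"
            )
        _check_unique(self.snp_meta["id"], "SNP ids")
        _check_unique(self.sample_ids, "sample ids")
        if (self.snp_meta["pos"].astype(int) < 1).any():
            raise ValidationError("SNP positions must be 1-based (>= 1)")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][:5]
            raise ValidationError(f"non-missing genotypes must be 0/1/2, got {bad}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["id"].tolist()

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            values=self.values[index],
            snp_meta=self.snp_meta,
            sample_ids=[self.sample_ids[i] for i in index],
        )

    def take_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, index],
            snp_meta=self.snp_meta.iloc[index],
            sample_ids=self.sample_ids,
        )

    def subset_snp_ids(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given SNP ids, in the given order."""
        lookup = {s: i for i, s in enumerate(self.snp_meta["id"])}
        try:
            index = [lookup[s] for s in ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"SNP {exc.args[0]!r} not present") from exc
        return self.take_snps(index)


@dataclass
class GeoTable:
    """Sample -> (population, latitude, longitude) ground truth.

    All members of one population carry identical coordinates (the
    "capital city" convention: a sample is placed at a single reference
    point for its population). Tables holding per-sample reference
    coordinates (e.g. all-marker predictions used as surrogate truth) set
    ``population_level=False`` to lift that constraint.
    """

    table: pd.DataFrame  # columns: sample_id, population, latitude, longitude
    population_level: bool = True

    def __post_init__(self) -> None:
        required = ["sample_id", "population", "latitude", "longitude"]
        missing = set(required) - set(self.table.columns)
        if missing:
            raise ValidationError(f"GeoTable lacks columns {sorted(missing)}")
        self.table = self.table[required].reset_index(drop=True)
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        self.table["population"] = self.table["population"].astype(str)
        _check_unique(self.table["sample_id"], "sample ids in GeoTable")
        lat = self.table["latitude"].to_numpy(float)
        lon = self.table["longitude"].to_numpy(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitudes must lie in [-90, 90]")
        if ((lon < -180) | (lon >= 180)).any():
            raise ValidationError("longitudes must lie in [-180, 180)")
        if self.population_level:
            per_pop = self.table.groupby("population")[
                ["latitude", "longitude"]
            ].nunique()
            inconsistent = per_pop[(per_pop > 1).any(axis=1)].index.tolist()
            if inconsistent:
                raise ValidationError(
                    f"populations with non-unique coordinates: {inconsistent}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def coords_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Return an (n, 2) array of (latitude, longitude) for the given samples."""
        indexed = self.table.set_index("sample_id")
        try:
            sub = indexed.loc[list(sample_ids)]
        except KeyError as exc:
            raise KeyError(f"sample without coordinates: {exc.args[0]!r}") from exc
        return sub[["latitude", "longitude"]].to_numpy(float)

    def populations_for(self, sample_ids: Sequence[str]) -> list[str]:
        indexed = self.table.set_index("sample_id")["population"]
        return [indexed[s] for s in sample_ids]

    def subset(self, sample_ids: Sequence[str]) -> "GeoTable":
        keep = self.table[self.table["sample_id"].isin(set(map(str, sample_ids)))]
        return GeoTable(keep.copy(), population_level=self.population_level)


@dataclass
class CenteredMatrix:
    """Mean-imputed, column-centered genotype matrix ready for SVD.

    Missing entries of the source matrix are imputed with the per-SNP mean of
    the observed dosages and therefore equal exactly 0 after centering — a
    missing call contributes nothing to any inner product.
    """

    values: np.ndarray
    column_means: np.ndarray
    snp_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    snp_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.column_means = np.asarray(self.column_means, dtype=float)
        if self.values.ndim != 2 or self.column_means.shape != (self.values.shape[1],):
            raise ValidationError("CenteredMatrix shape mismatch")
        tol = 1e-9 * max(self.values.shape[0], 1)
        colsums = np.abs(self.values.sum(axis=0))
        if colsums.size and colsums.max() > tol:
            raise ValidationError(
                f"columns are not centered (max |sum| = {colsums.max():.3g})"
            )


@dataclass
class PCAModel:
    """Truncated SVD of a centered genotype matrix.

    ``right_vectors`` holds the top-k right singular vectors V_k (one row per
    SNP, orthonormal columns); ``training_scores`` the training-sample PC
    coordinates U_k Sigma_k; ``column_means`` the training per-SNP means used
    to impute and center any matrix projected through the model.
    """

    k: int
    right_vectors: np.ndarray  # (n_snps, k)
    singular_values: np.ndarray  # (k,)
    column_means: np.ndarray  # (n_snps,)
    training_scores: np.ndarray  # (n_samples, k)
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.right_vectors = np.asarray(self.right_vectors, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.training_scores = np.asarray(self.training_scores, dtype=float)
        p, k = self.right_vectors.shape
        if k != self.k or self.singular_values.shape != (k,):
            raise ValidationError("PCAModel factor shapes inconsistent with k")
        if len(self.snp_ids) != p or self.column_means.shape != (p,):
            raise ValidationError("PCAModel SNP dimension mismatch")
        if (self.singular_values < -1e-12).any():
            raise ValidationError("singular values must be non-negative")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValidationError("singular values must be non-increasing")
        gram = self.right_vectors.T @ self.right_vectors
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValidationError("right singular vectors are not orthonormal")


@dataclass
class Panel:
    """An ordered SNP panel with leverage scores and provenance.

    Rows are ordered by descending score (the selection order); ``provenance``
    records the parameters that produced the panel (pool_size, target_size,
    r2_threshold, k, ...).
    """

    table: pd.DataFrame  # columns: rank, snp_id, chrom, pos, score
    provenance: dict = field(default_factory=dict)

    PANEL_COLUMNS = ("rank", "snp_id", "chrom", "pos", "score")

    def __post_init__(self) -> None:
        missing = set(self.PANEL_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"Panel table lacks columns {sorted(missing)}")
        self.table = self.table[list(self.PANEL_COLUMNS)].reset_index(drop=True)
        self.table["rank"] = self.table["rank"].astype(int)
        self.table["snp_id"] = self.table["snp_id"].astype(str)
        self.table["chrom"] = self.table["chrom"].astype(str)
        self.table["pos"] = self.table["pos"].astype(int)
        self.table["score"] = self.table["score"].astype(float)
        _check_unique(self.table["snp_id"], "panel SNP ids")

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)

    def head(self, n: int) -> "Panel":
        """Prefix panel of the top-``n`` entries (panels are nested)."""
        prov = dict(self.provenance, target_size=n)
        return Panel(self.table.head(n).copy(), prov)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        if len(self) != len(other):
            return False
        a, b = self.table, other.table
        return (
            (a["rank"].to_numpy() == b["rank"].to_numpy()).all()
            and (a["snp_id"].to_numpy() == b["snp_id"].to_numpy()).all()
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["pos"].to_numpy() == b["pos"].to_numpy()).all()
            and np.array_equal(a["score"].to_numpy(), b["score"].to_numpy())
        )


@dataclass
class PredictionRecord:
    """Predicted coordinates for one sample plus its supporting neighbors."""

    sample_id: str
    predicted_lat: float
    predicted_lon: float
    neighbor_ids: list[str]
    neighbor_distances: np.ndarray

    def __post_init__(self) -> None:
        self.neighbor_distances = np.asarray(self.neighbor_distances, dtype=float)
        if len(self.neighbor_ids) != self.neighbor_distances.shape[0]:
            raise ValidationError("neighbor ids / distances length mismatch")
        if (self.neighbor_distances < 0).any():
            raise ValidationError("neighbor distances must be non-negative")
        if np.any(np.diff(self.neighbor_distances) < -1e-12):
            raise ValidationError("neighbor distances must be non-decreasing")


@dataclass
class ErrorReport:
    """Per-population mean +/- SD absolute coordinate errors, plus an overall row.

    ``per_population`` rows are sorted by population name; the standard
    deviation uses the population denominator n. Kilometre columns convert
    degrees at each population's reference latitude (1 deg lat ~ 111.32 km,
    1 deg lon ~ 111.32 * cos(lat) km).
    """

    per_population: pd.DataFrame
    overall: pd.Series

    REPORT_COLUMNS = (
        "population",
        "n_samples",
        "lat_error_mean",
        "lat_error_sd",
        "lon_error_mean",
        "lon_error_sd",
        "lat_error_km",
        "lon_error_km",
    )

    def __post_init__(self) -> None:
        missing = set(self.REPORT_COLUMNS) - set(self.per_population.columns)
        if missing:
            raise ValidationError(f"ErrorReport lacks columns {sorted(missing)}")
        self.per_population = (
            self.per_population[list(self.REPORT_COLUMNS)]
            .sort_values("population", kind="stable")
            .reset_index(drop=True)
        )
        for col in self.REPORT_COLUMNS[2:]:
            if (self.per_population[col].to_numpy(float) < 0).any():
                raise ValidationError(f"negative entries in {col}")

    @property
    def n_total(self) -> int:
        return int(self.per_population["n_samples"].sum())


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
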