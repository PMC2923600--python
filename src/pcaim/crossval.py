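"""Leave-one-out and external-holdout validation with per-population errors.

The strict leave-one-out design re-selects the marker panel from scratch on
every n-1 training subset, so the held-out sample never influences panel
selection, column means, or the PC basis. A ``reuse_panels`` mode selects
panels once on the full cohort (an optimistic, non-cross-validated design,
kept because its contrast with the strict design is informative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ErrorReport,
    GenotypeMatrix,
    GeoTable,
    Panel,
    PredictionRecord,
    ValidationError,
)
from .io import encode_and_center
from .selection import build_panels
from .predict import predict_from_panel

logger = logging.getLogger(__name__)

KM_PER_DEG_LAT = 111.32


def coordinate_error(
    pred: tuple[float, float], truth: tuple[float, float]
) -> tuple[float, float]:
    """Per-axis absolute error in degrees; longitude uses the minimal
    angular difference (wraparound-safe)."""
    lat_error = abs(pred[0] - truth[0])
    dlon = (pred[1] - truth[1] + 180.0) % 360.0 - 180.0
    return lat_error, abs(dlon)


def error_summary(
    preds: Sequence[PredictionRecord], geo: GeoTable
) -> ErrorReport:
    """Per-population mean +/- SD of per-axis absolute errors.

    SD uses the population denominator n. The overall row weights
    populations by sample count. Kilometre columns convert at each
    population's reference latitude.
    """
    rows = []
    for r in preds:
        truth = geo.coords_for([r.sample_id])[0]
        lat_e, lon_e = coordinate_error(
            (r.predicted_lat, r.predicted_lon), tuple(truth)
        )
        rows.append(
            {
                "sample_id": r.sample_id,
                "population": geo.populations_for([r.sample_id])[0],
                "truth_lat": truth[0],
                "lat_error": lat_e,
                "lon_error": lon_e,
            }
        )
    per_sample = pd.DataFrame(rows)
    out = []
    for pop, grp in per_sample.groupby("population"):
        lat = grp["lat_error"].to_numpy()
        lon = grp["lon_error"].to_numpy()
        ref_lat = grp["truth_lat"].iloc[0]
        out.append(
            {
                "population": pop,
                "n_samples": len(grp),
                "lat_error_mean": lat.mean(),
                "lat_error_sd": lat.std(ddof=0),
                "lon_error_mean": lon.mean(),
                "lon_error_sd": lon.std(ddof=0),
                "lat_error_km": lat.mean() * KM_PER_DEG_LAT,
                "lon_error_km": lon.mean()
                * KM_PER_DEG_LAT
                * np.cos(np.deg2rad(ref_lat)),
            }
        )
    table = pd.DataFrame(out)
    lat_all = per_sample["lat_error"].to_numpy()
    lon_all = per_sample["lon_error"].to_numpy()
    mean_lat_deg = per_sample["truth_lat"].mean()
    overall = pd.Series(
        {
            "n_samples": len(per_sample),
            "lat_error_mean": lat_all.mean(),
            "lat_error_sd": lat_all.std(ddof=0),
            "lon_error_mean": lon_all.mean(),
            "lon_error_sd": lon_all.std(ddof=0),
            "lat_error_km": lat_all.mean() * KM_PER_DEG_LAT,
            "lon_error_km": lon_all.mean()
            * KM_PER_DEG_LAT
            * np.cos(np.deg2rad(mean_lat_deg)),
        }
    )
    return ErrorReport(per_population=table, overall=overall)


@dataclass
class SplitDetail:
    """Audit record of one leave-one-out split (largest panel only)."""

    held_out: str
    panel_snp_ids: list[str]
    panel_scores: np.ndarray


@dataclass
class LoocvResult:
    predictions: dict[int, list[PredictionRecord]]  # panel size -> one per sample
    reports: dict[int, ErrorReport]
    details: list[SplitDetail] = field(default_factory=list)


def loocv(
    g: GenotypeMatrix,
    geo: GeoTable,
    panel_sizes: Sequence[int] = (500, 800, 1000),
    pool_size: int = 5000,
    r2_threshold: float = 0.8,
    k_pcs: int = 2,
    k_neighbors: int = 10,
    reuse_panels: bool = False,
    fixed_panels: Sequence[Panel] | None = None,
    return_details: bool = False,
    progress: bool = False,
) -> LoocvResult:
    """Leave-one-out cross-validation over every sample of the cohort.

    With ``reuse_panels=False`` (the strict design) panels are re-selected on
    each n-1 training subset; with ``reuse_panels=True`` panels come from the
    full cohort once, which leaks the held-out sample into selection and
    yields optimistic panels (prediction itself still never sees the held-out
    sample's coordinates). ``fixed_panels`` evaluates externally supplied
    panels instead of selecting any (e.g. random-panel baselines); results
    are then keyed by each panel's length.
    """
    n = g.n_samples
    if n < 2:
        raise ValidationError("leave-one-out needs at least two samples")
    geo.coords_for(g.sample_ids)  # fail fast if any sample lacks coordinates

    shared_panels: list[Panel] | None = None
    if fixed_panels is not None:
        shared_panels = list(fixed_panels)
        panel_sizes = [len(p) for p in shared_panels]
    else:
        panel_sizes = sorted(panel_sizes)
        if reuse_panels:
            shared_panels = build_panels(
                encode_and_center(g), sizes=panel_sizes,
                pool_size=pool_size, r2_threshold=r2_threshold, k=k_pcs,
            )

    preds: dict[int, list[PredictionRecord]] = {s: [] for s in panel_sizes}
    details: list[SplitDetail] = []
    for i in range(n):
        try:
            train_idx = np.r_[0:i, i + 1 : n]
            train_g = g.take_samples(train_idx)
            test_g = g.take_samples([i])
            if shared_panels is None:
                panels = build_panels(
                    encode_and_center(train_g), sizes=panel_sizes,
                    pool_size=pool_size, r2_threshold=r2_threshold, k=k_pcs,
                )
            else:
                panels = shared_panels
            for size, panel in zip(panel_sizes, panels):
                preds[size].extend(
                    predict_from_panel(
                        train_g, geo, test_g, panel,
                        k_pcs=k_pcs, k_neighbors=k_neighbors,
                    )
                )
            if return_details:
                details.append(
                    SplitDetail(
                        held_out=g.sample_ids[i],
                        panel_snp_ids=panels[-1].snp_ids,
                        panel_scores=panels[-1].scores,
                    )
                )
            if progress and (i + 1) % 50 == 0:
                logger.info("leave-one-out: %d/%d splits done", i + 1, n)
        except Exception as exc:
            raise RuntimeError(f"leave-one-out split {i} failed: {exc}") from exc

    reports = {s: error_summary(preds[s], geo) for s in panel_sizes}
    return LoocvResult(predictions=preds, reports=reports, details=details)


@dataclass
class HoldoutResult:
    predictions: list[PredictionRecord]
    report: ErrorReport
    per_sample_errors: pd.DataFrame  # sample_id, lat_error, lon_error
    excluded_samples: list[str]
    ground_truth: GeoTable


def holdout_validate(
    train_g: GenotypeMatrix,
    train_geo: GeoTable,
    test_g: GenotypeMatrix,
    panel: Panel,
    test_truth: GeoTable | None = None,
    k_pcs: int = 2,
    k_neighbors: int = 10,
    max_panel_missing: float = 0.10,
    test_population: str = "test",
) -> HoldoutResult:
    """Train-on-cohort / test-on-external validation.

    Test samples with more than ``max_panel_missing`` missing entries over
    the panel SNPs are excluded first. If no ground truth is supplied for the
    test cohort, the prediction made with *all* SNPs shared between the two
    cohorts serves as ground truth, and the panel is judged by how closely it
    reproduces the full-marker prediction.
    """
    panel_shared = [s for s in panel.snp_ids if s in set(test_g.snp_ids)]
    if not panel_shared:
        raise ValidationError("no panel SNPs present in the test cohort")
    sub = test_g.subset_snp_ids(panel_shared)
    miss_frac = sub.missing_mask().mean(axis=1)
    keep = np.flatnonzero(miss_frac <= max_panel_missing)
    excluded = [sub.sample_ids[i] for i in np.flatnonzero(miss_frac > max_panel_missing)]
    if excluded:
        logger.info(
            "excluded %d test samples with > %.0f%% panel missingness: %s",
            len(excluded), 100 * max_panel_missing, excluded[:5],
        )
    if keep.size == 0:
        raise ValidationError("no test samples survive the missingness filter")
    test_g = test_g.take_samples(keep)

    preds = predict_from_panel(
        train_g, train_geo, test_g, panel, k_pcs=k_pcs, k_neighbors=k_neighbors
    )

    if test_truth is None:
        all_shared = [s for s in train_g.snp_ids if s in set(test_g.snp_ids)]
        full_panel = Panel(
            pd.DataFrame(
                {
                    "rank": np.arange(1, len(all_shared) + 1),
                    "snp_id": all_shared,
                    "chrom": "un",
                    "pos": np.arange(1, len(all_shared) + 1),
                    "score": np.nan,
                }
            ),
            {"target_size": len(all_shared), "note": "all shared SNPs"},
        )
        ref = predict_from_panel(
            train_g, train_geo, test_g, full_panel,
            k_pcs=k_pcs, k_neighbors=k_neighbors,
        )
        test_truth = GeoTable(
            pd.DataFrame(
                {
                    "sample_id": [r.sample_id for r in ref],
                    "population": test_population,
                    "latitude": [r.predicted_lat for r in ref],
                    "longitude": [r.predicted_lon for r in ref],
                }
            ),
            population_level=False,
        )

    report = error_summary(preds, test_truth)
    rows = []
    for r in preds:
        truth = test_truth.coords_for([r.sample_id])[0]
        lat_e, lon_e = coordinate_error(
            (r.predicted_lat, r.predicted_lon), tuple(truth)
        )
        rows.append(
            {"sample_id": r.sample_id, "lat_error": lat_e, "lon_error": lon_e}
        )
    return HoldoutResult(
        predictions=preds,
        report=report,
        per_sample_errors=pd.DataFrame(rows),
        excluded_samples=excluded,
        ground_truth=test_truth,
    )
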