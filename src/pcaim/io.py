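"""Reading, filtering and encoding genotype data and coordinate tables.

Supported inputs: VCF 4.x (gzip-transparent, via cyvcf2) and a plain
tab-separated dosage matrix (rows = samples, columns = SNPs, header row of
SNP ids, first column the sample id, ``NA`` for missing). Coordinate tables
and SNP panels are tab-separated text.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CenteredMatrix,
    GenotypeMatrix,
    GeoTable,
    Panel,
    ValidationError,
)

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)}

# strand-ambiguous (palindromic) allele pairs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") in AUTOSOMES


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a tab-separated dosage file.

    VCF records that are multi-allelic or non-autosomal are skipped (the
    number skipped is logged). Diploid GT fields become dosages of the ALT
    allele; ``./.`` becomes a missing entry.

    Parameters
    ----------
    path : path to the input file (``.vcf``, ``.vcf.gz`` or ``.tsv``).
    format : ``"vcf"`` or ``"tsv"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    n_skipped = 0
    for record in vcf:
        if len(record.ALT) != 1 or not _is_autosome(record.CHROM):
            n_skipped += 1
            continue
        gts = record.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(sample_ids), dtype=float)
        for i, gt in enumerate(gts):
            alleles = [a for a in gt[:-1] if a >= 0]
            col[i] = np.nan if len(alleles) < 2 else float(sum(alleles))
        columns.append(col)
        snp_id = record.ID if record.ID not in (None, ".") else (
            f"{record.CHROM}:{record.POS}"
        )
        meta_rows.append(
            (snp_id, record.CHROM.removeprefix("chr"), record.POS,
             record.REF, record.ALT[0])
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-autosomal records", n_skipped)
    if not columns:
        values = np.empty((len(sample_ids), 0))
    else:
        values = np.column_stack(columns)
    meta = pd.DataFrame(
        meta_rows, columns=["id", "chrom", "pos", "ref_allele", "alt_allele"]
    )
    g = GenotypeMatrix(values=values, snp_meta=meta, sample_ids=sample_ids)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:
        raise ValidationError(f"cannot parse tsv {path}: {exc}") from exc
    values = frame.to_numpy(dtype=float)
    snp_ids = [str(c) for c in frame.columns]
    # plain dosage tables carry no positional metadata; synthesize placeholders
    meta = pd.DataFrame(
        {
            "id": snp_ids,
            "chrom": "un",
            "pos": np.arange(1, len(snp_ids) + 1),
            "ref_allele": "N",
            "alt_allele": "N",
        }
    )
    return GenotypeMatrix(
        values=values, snp_meta=meta, sample_ids=[str(s) for s in frame.index]
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(g.values, index=g.sample_ids, columns=g.snp_ids)
    frame.index.name = "sample_id"
    with open(path, "w") as fh:
        frame.to_csv(fh, sep="\t", na_rep="NA", float_format="%.0f")


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields (unphased, dosage-faithful)."""
    order = np.lexsort(
        (g.snp_meta["pos"].to_numpy(), g.snp_meta["chrom"].to_numpy())
    )
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j in order:
            row = g.snp_meta.iloc[j]
            calls = [
                "./." if np.isnan(v) else gt_of[v] for v in g.values[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                f"{row['ref_allele']}\t{row['alt_allele']}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_geotable(path: str | Path) -> GeoTable:
    table = pd.read_csv(path, sep="\t")
    return GeoTable(table)


def write_geotable(geo: GeoTable, path: str | Path) -> None:
    geo.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_data(
    g: GenotypeMatrix,
    snp_missing_max: float = 0.10,
    sample_missing_max: float = 0.10,
    min_pop_size: int = 40,
    geo: GeoTable | None = None,
) -> GenotypeMatrix:
    """Quality-filter a cohort: SNPs, then samples, then small populations.

    SNPs with a missing fraction above ``snp_missing_max`` are removed first;
    then samples with missing fraction above ``sample_missing_max``; then
    every sample whose population retains fewer than ``min_pop_size`` members.
    Row/column order is preserved.
    """
    for name, thr in (("snp_missing_max", snp_missing_max),
                      ("sample_missing_max", sample_missing_max)):
        if not 0 <= thr <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    if min_pop_size < 0:
        raise ValueError("min_pop_size must be >= 0")

    miss = g.missing_mask()
    keep_snps = np.flatnonzero(miss.mean(axis=0) <= snp_missing_max)
    g = g.take_snps(keep_snps)

    miss = g.missing_mask()
    if g.n_snps:
        keep_samples = np.flatnonzero(miss.mean(axis=1) <= sample_missing_max)
    else:
        keep_samples = np.arange(g.n_samples)
    g = g.take_samples(keep_samples)

    if min_pop_size > 0:
        if geo is None:
            raise ValueError("min_pop_size > 0 requires a GeoTable")
        pops = np.asarray(geo.populations_for(g.sample_ids))
        counts = pd.Series(pops).value_counts()
        big = set(counts[counts >= min_pop_size].index)
        keep = np.flatnonzero(np.isin(pops, list(big)))
        g = g.take_samples(keep)

    if g.n_samples == 0 or g.n_snps == 0:
        raise ValidationError("no data survives filters")
    return g


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def encode_and_center(g: GenotypeMatrix) -> CenteredMatrix:
    """Mean-impute missing calls and center every SNP column.

    A missing entry is set to the per-SNP mean of the observed dosages and so
    equals exactly 0 after centering. Monomorphic SNPs become all-zero
    columns and are retained.
    """
    all_missing = np.isnan(g.values).all(axis=0)
    if all_missing.any():
        bad = g.snp_meta["id"].iloc[np.flatnonzero(all_missing)[:5]].tolist()
        raise ValidationError(f"SNPs with every entry missing: {bad}")
    means = np.nanmean(g.values, axis=0)
    centered = g.values - means
    # observed entries sum to 0 per column by construction, so zeroing the
    # missing cells preserves centering and makes them contribute nothing
    centered[np.isnan(centered)] = 0.0
    return CenteredMatrix(
        values=centered,
        column_means=means,
        snp_ids=g.snp_ids,
        sample_ids=list(g.sample_ids),
        snp_meta=g.snp_meta,
    )


def orient_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns so each SNP counts its minor allele on this cohort.

    Columns whose counted-allele frequency exceeds 0.5 become ``2 - dosage``
    and their ref/alt metadata roles are swapped. The transform is affine per
    column, so centered PC geometry is unchanged.
    """
    freq = np.nanmean(g.values, axis=0) / 2.0
    flip = freq > 0.5
    values = g.values.copy()
    values[:, flip] = 2.0 - values[:, flip]
    meta = g.snp_meta.copy()
    ref = meta["ref_allele"].to_numpy().copy()
    alt = meta["alt_allele"].to_numpy().copy()
    meta["ref_allele"] = np.where(flip, alt, ref)
    meta["alt_allele"] = np.where(flip, ref, alt)
    return GenotypeMatrix(values=values, snp_meta=meta, sample_ids=g.sample_ids)


def harmonize_alleles(
    test_g: GenotypeMatrix, train_meta: pd.DataFrame
) -> GenotypeMatrix:
    """Re-orient a test cohort onto the training allele encoding.

    SNPs are matched by id. Where the test ref/alt pair is swapped relative
    to training, dosages are flipped; where the pair matches only after
    strand complementation the complement is applied first. Strand-ambiguous
    SNPs (A/T or C/G) whose orientation cannot be resolved are dropped.
    SNPs absent from training are dropped.
    """
    train = train_meta.set_index("id")
    keep: list[int] = []
    flip: list[bool] = []
    n_ambiguous = 0
    for j, row in test_g.snp_meta.iterrows():
        if row["id"] not in train.index:
            continue
        t = train.loc[row["id"]]
        ref, alt = row["ref_allele"], row["alt_allele"]
        pair = (ref, alt)
        comp = (_COMPLEMENT.get(ref, ref), _COMPLEMENT.get(alt, alt))
        palindromic = comp == (alt, ref)
        target = (t["ref_allele"], t["alt_allele"])
        swapped = (t["alt_allele"], t["ref_allele"])
        if pair == target:
            keep.append(j), flip.append(False)
        elif pair == swapped:
            if palindromic:
                n_ambiguous += 1
                continue
            keep.append(j), flip.append(True)
        elif comp == target:
            keep.append(j), flip.append(False)
        elif comp == swapped:
            if palindromic:
                n_ambiguous += 1
                continue
            keep.append(j), flip.append(True)
        # allele pairs that cannot be reconciled are dropped silently
    if n_ambiguous:
        logger.info("dropped %d strand-ambiguous SNPs", n_ambiguous)
    out = test_g.take_snps(keep)
    values = out.values.copy()
    flip_arr = np.asarray(flip, dtype=bool)
    values[:, flip_arr] = 2.0 - values[:, flip_arr]
    meta = out.snp_meta.copy()
    ref = meta["ref_allele"].to_numpy().copy()
    alt = meta["alt_allele"].to_numpy().copy()
    meta["ref_allele"] = np.where(flip_arr, alt, ref)
    meta["alt_allele"] = np.where(flip_arr, ref, alt)
    return GenotypeMatrix(values=values, snp_meta=meta, sample_ids=out.sample_ids)


# ---------------------------------------------------------------------------
# panel serialization
# ---------------------------------------------------------------------------


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel as tab-separated text: rank, snp_id, chrom, pos, score."""
    table = panel.table.copy()
    table["score"] = [repr(float(s)) for s in table["score"]]  # lossless round-trip
    table.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> Panel:
    table = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "chrom": str},
        float_precision="round_trip",
    )
    extra = set(table.columns) - set(Panel.PANEL_COLUMNS)
    if extra or set(Panel.PANEL_COLUMNS) - set(table.columns):
        raise ValidationError(
            f"panel file columns {list(table.columns)} do not match "
            f"{list(Panel.PANEL_COLUMNS)}"
        )
    if len(table):
        table["score"] = table["score"].astype(float)
    return Panel(table)


def write_predictions(records: Sequence, path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "pred_lat": r.predicted_lat,
            "pred_lon": r.predicted_lon,
            "neighbor_ids": ",".join(r.neighbor_ids),
            "neighbor_dists": ",".join(f"{d:.6g}" for d in r.neighbor_distances),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
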