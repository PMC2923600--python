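import numpy as np
import pandas as pd
import pytest

from pcaim import GenotypeMatrix, GeoTable, default_config, grid_demes, simulate_cohort


def make_genotypes(values, snp_ids=None, sample_ids=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from a plain array with default metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    snp_ids = snp_ids or [f"snp{j:04d}" for j in range(p)]
    sample_ids = sample_ids or [f"s{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "id": snp_ids,
            "chrom": chrom if chrom is not None else ["1"] * p,
            "pos": pos if pos is not None else np.arange(1, p + 1) * 100,
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    return GenotypeMatrix(values=values, snp_meta=meta, sample_ids=sample_ids)


def make_geotable(sample_ids, populations, coords):
    """coords: population -> (lat, lon)."""
    rows = [
        {
            "sample_id": s,
            "population": p,
            "latitude": coords[p][0],
            "longitude": coords[p][1],
        }
        for s, p in zip(sample_ids, populations)
    ]
    return GeoTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """3x3 deme grid, 8 samples/deme, 60 clinal + 540 noise SNPs, seeded."""
    cfg = default_config(
        seed=7,
        demes=grid_demes(3, 3, samples_per_deme=8),
        n_clinal_snps=60,
        n_noise_snps=540,
        missing_rate=0.03,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """4x4 grid, 10/deme, 200 clinal + 1800 noise SNPs — structure-rich."""
    cfg = default_config(
        seed=21,
        demes=grid_demes(4, 4, samples_per_deme=10),
        n_clinal_snps=200,
        n_noise_snps=1800,
        missing_rate=0.01,
    )
    return simulate_cohort(cfg)
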