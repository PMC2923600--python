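"""Synthetic spatially structured genotype cohorts.

Demes sit at fixed geographic coordinates; a minority of SNPs carry linear
allele-frequency clines across the map (random direction, fixed frequency
range), the remainder drift mildly around a shared frequency
(Balding-Nichols beta model), so they differ between demes without being
geographically informative. Genotypes are two independent binomial allele
draws per sample; calls are masked missing uniformly at random. Everything
is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, GeoTable, ValidationError

FREQ_FLOOR = 0.01
FREQ_CEIL = 0.99


@dataclass
class Deme:
    name: str
    latitude: float
    longitude: float
    n_samples: int


@dataclass
class SimulationConfig:
    """Study-condition knobs for the cohort generator.

    Defaults describe the standard test cohort: a 5x5 deme grid spanning
    continental-scale Europe-like coordinates, 40 samples per deme, 10% of
    SNPs clinal with a 0.4 allele-frequency range across the grid, mild
    drift on the rest, 1% missing calls.
    """

    demes: list[Deme]
    n_clinal_snps: int = 2000
    n_noise_snps: int = 18000
    cline_strength: float = 0.4  # max allele-frequency range across the grid
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    drift: float = 0.01  # Fst-like dispersion of noise-SNP deme frequencies
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.demes:
            raise ValidationError("simulation needs at least one deme")
        if any(d.n_samples < 1 for d in self.demes):
            raise ValidationError("every deme needs n_samples >= 1")
        lo, hi = self.base_freq_range
        if not (0.05 <= lo <= hi <= 0.95):
            raise ValidationError("base_freq_range must lie within [0.05, 0.95]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.cline_strength < 0 or self.drift < 0:
            raise ValidationError("cline_strength and drift must be >= 0")

    @property
    def n_snps(self) -> int:
        return self.n_clinal_snps + self.n_noise_snps

    @property
    def n_samples(self) -> int:
        return sum(d.n_samples for d in self.demes)


@dataclass
class SimulationTruth:
    """Which SNPs are clinal and with what per-degree frequency slopes."""

    clinal: pd.DataFrame  # snp_id, lat_slope, lon_slope (frequency per degree)
    deme_freqs: pd.DataFrame = field(repr=False)  # snp_id x deme frequency table

    @property
    def clinal_ids(self) -> set[str]:
        return set(self.clinal["snp_id"])


def grid_demes(
    n_lat: int = 5,
    n_lon: int = 5,
    lat_range: tuple[float, float] = (38.0, 54.0),
    lon_range: tuple[float, float] = (-6.0, 22.0),
    samples_per_deme: int = 40,
) -> list[Deme]:
    """A rectangular deme grid over a Europe-sized bounding box."""
    lats = np.linspace(*lat_range, n_lat)
    lons = np.linspace(*lon_range, n_lon)
    return [
        Deme(f"deme_{i:02d}_{j:02d}", float(lat), float(lon), samples_per_deme)
        for i, lat in enumerate(lats)
        for j, lon in enumerate(lons)
    ]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard 5x5-grid, 40-per-deme, 20,000-SNP test cohort."""
    params = dict(
        demes=grid_demes(), n_clinal_snps=2000, n_noise_snps=18000, seed=seed
    )
    params.update(overrides)
    return SimulationConfig(**params)


# Eleven demes at approximate European capital/reference coordinates with
# cohort sizes matching a well-studied 1,200-sample European reference panel.
_EUROPE_DEMES = [
    ("Belgium", 50.85, 4.35, 43),
    ("France", 48.86, 2.35, 89),
    ("Germany", 52.52, 13.40, 71),
    ("Ireland", 53.35, -6.26, 61),
    ("Italy", 41.90, 12.50, 219),
    ("Portugal", 38.72, -9.14, 128),
    ("Serbia", 44.79, 20.45, 44),
    ("Spain", 40.42, -3.70, 136),
    ("SwissFrench", 46.20, 6.15, 125),
    ("SwissGerman", 47.37, 8.54, 84),
    ("UK", 51.51, -0.13, 200),
]


def europe_like_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """Eleven European demes, 40-219 samples each, 1,200 samples total,
    ~20,000 SNPs — the shape of the cohort the method was designed around."""
    params = dict(
        demes=[Deme(*row) for row in _EUROPE_DEMES],
        n_clinal_snps=2000,
        n_noise_snps=18000,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def resample_cohort(
    truth: SimulationTruth,
    demes: Sequence[Deme],
    snp_meta: pd.DataFrame,
    missing_rate: float = 0.01,
    seed: int = 1,
    prefix: str = "ext",
) -> tuple[GenotypeMatrix, GeoTable]:
    """Draw a fresh cohort from an existing cohort's deme allele frequencies.

    This is how an external test set "from the same demes" is made: the
    population model (the per-deme frequencies in ``truth``) is identical to
    the training cohort's, only the individuals are new draws.
    """
    rng = np.random.default_rng(seed)
    freqs = truth.deme_freqs
    blocks, sample_ids, geo_rows = [], [], []
    for deme in demes:
        if deme.name not in freqs.columns:
            raise ValidationError(f"deme {deme.name!r} not in truth table")
        p = freqs[deme.name].to_numpy()
        gm = rng.binomial(2, p, size=(deme.n_samples, len(p))).astype(float)
        blocks.append(gm)
        for s in range(deme.n_samples):
            sid = f"{prefix}_{deme.name}_{s:04d}"
            sample_ids.append(sid)
            geo_rows.append(
                {
                    "sample_id": sid,
                    "population": deme.name,
                    "latitude": deme.latitude,
                    "longitude": deme.longitude,
                }
            )
    values = np.vstack(blocks)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    g = GenotypeMatrix(values=values, snp_meta=snp_meta, sample_ids=sample_ids)
    return g, GeoTable(pd.DataFrame(geo_rows))


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, GeoTable, SimulationTruth]:
    """Draw a cohort under the configured spatial allele-frequency model."""
    rng = np.random.default_rng(cfg.seed)
    demes = cfg.demes
    n_demes = len(demes)
    lat = np.array([d.latitude for d in demes])
    lon = np.array([d.longitude for d in demes])
    lat_c = lat - lat.mean()
    lon_c = lon - lon.mean()

    # --- clinal SNPs: linear frequency surface along a random direction ----
    nc = cfg.n_clinal_snps
    p0 = rng.uniform(*cfg.base_freq_range, size=nc)
    theta = rng.uniform(0, 2 * np.pi, size=nc)
    u_lat, u_lon = np.cos(theta), np.sin(theta)
    proj = np.outer(u_lat, lat_c) + np.outer(u_lon, lon_c)  # (nc, n_demes)
    span = proj.max(axis=1) - proj.min(axis=1)
    span = np.where(span > 0, span, 1.0)  # single deme: no geographic axis
    slope = cfg.cline_strength / span
    clinal_freq = p0[:, None] + slope[:, None] * proj
    clinal_freq = np.clip(clinal_freq, FREQ_FLOOR, FREQ_CEIL)

    # --- noise SNPs: Balding-Nichols drift around a shared frequency -------
    nn = cfg.n_noise_snps
    q0 = rng.uniform(*cfg.base_freq_range, size=nn)
    if cfg.drift > 0:
        f = cfg.drift
        a = q0 * (1 - f) / f
        b = (1 - q0) * (1 - f) / f
        noise_freq = rng.beta(a[:, None], b[:, None], size=(nn, n_demes))
    else:
        noise_freq = np.repeat(q0[:, None], n_demes, axis=1)
    noise_freq = np.clip(noise_freq, FREQ_FLOOR, FREQ_CEIL)

    freqs = np.vstack([clinal_freq, noise_freq])  # (n_snps, n_demes)
    snp_ids = [f"clinal{j:06d}" for j in range(nc)] + [
        f"noise{j:06d}" for j in range(nn)
    ]

    # --- genotypes: binomial(2, p) per sample, uniform missingness ---------
    blocks = []
    sample_ids: list[str] = []
    geo_rows = []
    for d_idx, deme in enumerate(demes):
        gm = rng.binomial(2, freqs[:, d_idx], size=(deme.n_samples, cfg.n_snps))
        blocks.append(gm.astype(float))
        for s in range(deme.n_samples):
            sid = f"{deme.name}_{s:04d}"
            sample_ids.append(sid)
            geo_rows.append(
                {
                    "sample_id": sid,
                    "population": deme.name,
                    "latitude": deme.latitude,
                    "longitude": deme.longitude,
                }
            )
    values = np.vstack(blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    n_snps = cfg.n_snps
    meta = pd.DataFrame(
        {
            "id": snp_ids,
            "chrom": [str(1 + j % 22) for j in range(n_snps)],
            "pos": [1000 + 100 * (j // 22) for j in range(n_snps)],
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    g = GenotypeMatrix(values=values, snp_meta=meta, sample_ids=sample_ids)
    geo = GeoTable(pd.DataFrame(geo_rows))
    truth = SimulationTruth(
        clinal=pd.DataFrame(
            {
                "snp_id": snp_ids[:nc],
                "lat_slope": slope * u_lat,
                "lon_slope": slope * u_lon,
            }
        ),
        deme_freqs=pd.DataFrame(
            freqs, index=snp_ids, columns=[d.name for d in demes]
        ),
    )
    return g, geo, truth
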