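# Methods

## Problem and model

Allele frequencies of human (and many other) populations vary smoothly in
space. When a samples × SNPs dosage matrix is column-centered and reduced by
a truncated SVD, the leading right singular vectors are dominated by SNPs
whose frequencies follow such spatial clines, and the two leading PC scores
of the samples correlate strongly with latitude and longitude. `pcaim`
exploits this twice: once to *select* a compact marker panel (the SNPs that
load most heavily on the retained PC subspace) and once to *predict* where
an unlabeled individual comes from (nearest-neighbor averaging in PC
score space).

The pipeline assumes:

* genotypes are biallelic autosomal dosages in {0, 1, 2}, missing at random
  at a low rate;
* every training sample carries population-level reference coordinates
  (all members of a population share one point — a "capital city"
  convention), so predictions are anchored to discrete reference locations;
* spatial structure is the dominant axis of variation, i.e. the top two PCs
  are geography-like. Cohorts dominated by batch effects, close
  relatedness, or strong admixture violate this premise and the method
  inherits whatever the PCs then measure.

## Encoding and PCA

Dosages are encoded as allele counts; each SNP's missing entries are imputed
with the per-SNP mean of observed calls and the column is then centered on
that mean, so a missing call contributes exactly zero to every inner
product. Monomorphic SNPs become all-zero columns and are retained. No
per-SNP variance normalization is applied by default (the PC geometry of
dosage data is already well behaved, and unscaled centering keeps imputation
and projection exactly consistent); `GenotypePCA(scale=True)` enables
unit-variance scaling for sensitivity analysis.

The SVD is exact: dense LAPACK below a 400-dimension cutoff, ARPACK
(`scipy.sparse.linalg.svds`) with a fixed start vector above it, so results
are bit-reproducible. Each component's sign is canonicalized (largest-|·|
loading positive). Sign choices and any rotation of PC space leave all
nearest-neighbor output unchanged, since only pairwise distances enter the
predictor; the canonicalization exists purely to make serialized models and
panels byte-stable.

Projection of new samples always uses the *training* column means; a model
SNP absent from the projected cohort is thereby imputed at zero. If fewer
than 50% of model SNPs are present the projection refuses to run.

## Panel selection

SNP *j*'s score is its leverage on the retained subspace,
`s_j = Σ_{i≤k} v_{ij}²` with k = 2 by default. Orthonormality of `V_k`
forces `Σ_j s_j = k`, a useful invariant. A variance-weighted variant
(`Σ σ_i² v_{ij}²`) is available behind a flag. Score ties are broken
lexicographically by SNP id for reproducibility.

The top `pool_size` SNPs (default 5,000) form the candidate pool. Redundancy
removal is greedy: candidates are visited in rank order and accepted iff
their squared Pearson correlation (on the centered training genotypes) with
every already-accepted SNP is ≤ `r2_threshold` (default 0.8), stopping at
the target size. Zero-variance columns are defined to correlate with
nothing. The procedure guarantees the pairwise r² bound on every emitted
panel — a property the tests re-check exhaustively. Panels of several sizes
(default 500/800/1,000) are produced in one pruning pass as nested prefixes,
which keeps size sweeps coherent and cheap. Other redundancy-removal
schemes exist (e.g. projection-residual updates); correlation pruning was
chosen because it is the simplest procedure with a checkable invariant, and
it is isolated behind one function so it can be swapped.

## Coordinate prediction

A test sample's coordinates are the unweighted arithmetic mean of the
latitudes and longitudes of its `k_neighbors` (default 10) nearest training
samples under Euclidean distance in top-2 PC space. Distance ties are
broken by training sample id. Inverse-distance-power weighting and larger k
are available but give no consistent advantage at continental scale;
longitude is averaged arithmetically (valid away from the ±180° meridian; a
circular mean is available as a flag). Predictions therefore always lie in
the bounding box of the neighbors' coordinates.

## Validation designs

* **Strict leave-one-out**: for each of n splits, the panel is re-selected
  from scratch on the n−1 training samples (PCA, scoring, pooling, pruning),
  the model refitted, and the held-out sample predicted. Nothing about the
  held-out sample — genotypes or coordinates — can influence selection or
  fitting; the test suite verifies this by perturbing a held-out sample's
  genotypes and checking the split's panel is unchanged. One exact SVD per
  split is simply accepted; no down-dating shortcut is used (correctness
  over speed, and at package scale the cost is seconds to minutes).
* **Reuse-panels mode**: panels selected once on the full cohort, then
  leave-one-out prediction. This leaks the held-out sample into selection
  and is optimistic; it is kept, clearly labeled, because the contrast
  between the two designs is itself informative.
* **External holdout**: train on one cohort, test on another. Test samples
  with > 10% missing entries on the panel are excluded first. When the test
  cohort has no ground-truth coordinates, the prediction made with *all*
  SNPs shared between the cohorts serves as surrogate truth, and the panel
  is judged by how well it reproduces the full-marker prediction.

Errors are per-axis absolute differences in decimal degrees (longitude via
the minimal angular difference). Reports give per-population mean ± SD with
the population denominator n (a documented, fixed choice; the alternative
n−1 convention changes SDs by < 2% at the cohort sizes involved), an
overall count-weighted row, and convenience kilometre columns
(1° lat ≈ 111.32 km, 1° lon ≈ 111.32·cos(lat) km at the population's
reference latitude).

## Synthetic cohorts

`simulate_cohort` generates demes at fixed coordinates. A configurable
minority of SNPs is clinal: frequency `p_d = clip(p₀ + s·proj_d, 0.01,
0.99)` where `proj_d` projects deme coordinates onto a random direction and
the slope is scaled so the frequency range across the grid equals
`cline_strength` (default 0.4). The remaining SNPs drift around a shared
frequency under a Balding–Nichols beta model with Fst-like dispersion
(default 0.01) — non-identical across demes but spatially uninformative.
Genotypes are binomial(2, p_d) draws; calls are masked missing uniformly at
random (default 1%). Deme coordinates are every member's truth. Everything
is reproducible bit-for-bit from the seed, and `resample_cohort` draws an
external cohort from an existing cohort's deme frequencies (same population
model, new individuals).

Defaults: 5×5 deme grid spanning 38–54° N, −6–22° E, 40 samples per deme,
2,000 clinal + 18,000 noise SNPs. `europe_like_preset()` instead places 11
demes at European capital coordinates with 43–219 samples each (1,200
total) — the shape of the reference cohort this class of method is built
around.

What the simulator deliberately omits: linkage disequilibrium between
markers, admixed individuals, related individuals, genotyping batch
effects, and non-linear frequency surfaces. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under clean spatial
structure; they do not certify accuracy on real cohorts, where LD makes
redundancy pruning more consequential and admixture blurs the PC–geography
map.

## Problem sizes used in the shipped checks

The enrichment and PC-structure checks run at the full default size (1,000
samples × 20,000 SNPs; a single SVD). The leave-one-out recovery check —
which needs one panel re-selection and SVD per split per seed — runs on a
proportionally scaled demonstration cohort chosen as the package's standard
small benchmark: 4×4 demes at 5–6° spacing, 10 samples per deme (160
splits), 4,000 SNPs of which 10% clinal, pool 1,000, panel 100, ten
simulation seeds, with ten random same-size panels per seed as baseline.
Against the grid's 15° × 18° extent, the panel recovers coordinates to
well under 20% of the extent per axis (≈ 1.8–2.2°, i.e. ~200 km) and beats
the random-panel baseline in essentially every seed.

## Numerical choices and degenerate inputs

* SVD determinism: fixed ARPACK start vector; dense path below the cutoff.
* Score ties: lexicographic by SNP id. Distance ties: by training sample id.
* A SNP with every call missing is an error (no imputation target exists).
* Pool exhausted before the target panel size: a warning, and the shorter
  panel is returned with `exhausted` recorded in its provenance.
* `k_neighbors` larger than the training set: a warning, all samples used.
* Unweighted neighbor means use `np.mean`, so a neighborhood with identical
  coordinates returns them exactly (degenerate cohorts give exactly zero
  error).

## Limitations

* Coordinates are treated as planar; fine for continental scales, wrong
  near poles or the dateline (circular longitude averaging is available,
  great-circle distances are not).
* Predictions cannot extrapolate outside the convex hull of training
  populations — an individual from an unsampled region is assigned to the
  nearest sampled ones.
* Panel transfer across genotyping platforms is supported only via allele
  harmonization (id/allele matching, strand flips, dropping ambiguous
  palindromic SNPs); no liftover of genome builds.
* With k = 2 PCs, only two axes of structure inform selection; cohorts with
  deeper structure may need larger k, set by the user (no automatic
  component-count selection is provided).
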