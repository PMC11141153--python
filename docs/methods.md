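# Methods

This note records the statistical models, the numerical choices, and the
limits of what the synthetic-data suite can demonstrate.

## Differential proteomics

The two-group comparison per protein is a pooled-variance Student t on 3 AF
vs 3 sham replicates, moderated by a fudge constant S0 added to the pooled
standard error:

    t   = (m_AF − m_sham) / SE_pooled
    d   = (m_AF − m_sham) / (SE_pooled + S0),   S0 = 0.1 by default

S0 has the units of the mean difference, i.e. log2 fold change, which is
why the volcano consumes **log2 intensities, not row Z-scores**: Z-scoring
rescales every protein to unit variance, so a protein with a negligible
fold change but tiny residual variance presents the same inflated |d| as a
genuinely regulated one, and S0's damping of small fold changes is lost.
Empirically this costs roughly 20 percentage points of planted-effect
recovery under the default study conditions. Row Z-scoring (sample SD,
n−1; zero-SD rows emitted as zeros with a warning) remains available and
is what the heatmap-clustering and correlation QC consume, matching its
role as a display normalization. A column-wise Z-score is exposed via
`axis="sample"`.

"Two-way t-test" in assay reporting is read as the two-tailed pooled
two-sample t, and "one-way" as one-tailed; this reading reproduces all four
printed assay/Western p-values from their replicate values to the printed
precision, which is the strongest available check of the convention.

### Permutation FDR

Significance uses the SAM-style symmetric cutoff on |d|. For each balanced
relabeling of the samples (all C(6,3) = 20 distinct splits when 3 vs 3;
otherwise `n_permutations` splits sampled without replacement from the
distinct balanced splits), |d| is recomputed per protein. For a candidate
cutoff c (each observed |d| is a candidate),

    FDR(c) = median over relabelings of #{|d_perm| >= c} / max(1, #{|d_obs| >= c})

monotonized by a running minimum from the loose end (so a stricter cutoff
never reports a worse FDR — the q-value convention); the smallest c with
monotonized FDR at or below the target (5%) is selected, and proteins at
or above it are significant, ties included. Direction is the sign of the
log2 fold change. NaN statistics (a protein losing its two-per-group
coverage under a relabeling) never count as exceedances; infinite ones
always do. The whole procedure is checked exactly against a loop-based
brute-force enumeration on 3-vs-3 fixtures.

The asymmetric (separate up/down cutoff) variant was considered and left
out: the symmetric rule is what the exhaustive oracle validates, and
nothing downstream needs per-side cutoffs.

Missing values are never imputed anywhere in the pipeline; proteins with
more than `max_missing` (default 2) missing cells are removed up front,
and all statistics are computed on observed values only.

## Integrated pathway enrichment

Per-gene pooled t statistics are computed within each dataset (TL, EL,
Mito proteomics; RNA transcriptomics) and rank-transformed (ascending
mid-ranks; the largest rank is the most AF-up gene). Zero-SE genes carry
signed-infinity sentinels and rank to the extremes. The missing-data
policy during ranking:

* a gene quantified in at least one proteomics dataset but missing in
  another proteomics dataset joins a shared bottom block there
  ("ranked last"); the whole block carries one mid-rank so rank sums stay
  exact and the variance formula below remains valid;
* a gene observed only in the transcriptome is excluded from all
  proteomics rankings;
* the RNA ranking covers exactly the genes with transcript statistics.

For a pathway with k_d ranked members among n_d ranked genes in dataset d,
the mean member rank is standardized with the exact variance of a mean
rank under sampling without replacement,

    z_d = (R̄_d − (n_d+1)/2) / sqrt((n_d − k_d)(n_d + 1) / (12 k_d)),

and the joint statistic is T² = zᵀ Ĉ⁻¹ z with Ĉ the Spearman correlation
of the full rank columns over genes ranked in both datasets (memoized per
ranking; ridge-regularized with ε = 1e−6 if singular). p comes from χ²
with one degree of freedom per dataset. With a single dataset this reduces
exactly to the two-sided normal-approximation Wilcoxon rank-sum test, and
being rank-based it is invariant to any monotone transform of the
underlying statistics. The χ² approximation is validated two ways: against
a permutation oracle (random categories) on small instances, and by null
calibration — on a simulated null study the p-values of 2,000 random
categories are uniform within KS distance 0.05, with the 5% type-I rate
inside [0.03, 0.07].

A pathway enters the test only if it has at least `min_per_side = 2`
ranked members — and at least 2 ranked non-members — in every dataset;
pathways failing the floor are reported with a skip reason rather than a
p-value. The normalized per-dataset score

    score_d = (2 / n_d) (R̄_d − (n_d+1)/2)   ∈ (−1, 1)

is reported alongside T² as the pathway's enrichment profile; the full
gene universe scores exactly 0.

q-values are Benjamini–Hochberg step-up by default — deterministic and
exactly testable — with a Storey π₀-adjusted variant behind a flag;
significance is q < 0.01, and confidence tiers (the gray/black/red coding)
default to non-confident q ≥ 0.01, confident 0.001 ≤ q < 0.01, highly
confident q < 0.001, both cutoffs configurable.

The variance-stabilizing transform is the generalized log
glog(x) = log2((x + √(x²+c²))/2) after scaling each sample so its median
matches the across-sample mean median; c defaults to the 5th percentile of
the calibrated positive values (c = 0 reduces to log2; glog(0) =
log2(c/2)). Homolog harmonization consumes a two-column ID map
(one-to-many expanded, many-to-one collapsed elementwise by median or
max-abs); sample-outlier screening projects the row-standardized stacked
data onto PC1/PC2 and flags samples farther than `threshold_mad` (default
5) MADs from their group's component-wise **median** center — a median
rather than a mean because with 3 samples per group a mean center is
dragged toward the outlier, halving its apparent distance.

## Glycogen counting

Crop (0-based, half-open rectangles) → Gaussian blur (σ, default 1 px) →
square minimum filter (default 3 px, odd) → binarize strictly below a
threshold (foreground = dark; fixed value or Otsu) → 8-connected
components → discard area < `min_area` → count each component as
max(1, floor(area / `single_granule_area`)). The area-quotient rule is the
deterministic reading of "how many granules fit in a merged blob";
geometric packing is out of scope. Density = count / (area_px · nm_per_px²),
reported per nm² or per µm².

Otsu is reliable only when granules occupy an appreciable area fraction;
on sparse images it splits the background texture instead. The default
config therefore uses a fixed threshold, and
`GranuleConfig.for_image_spec` derives all parameters from a known
synthetic geometry (threshold halfway into the granule darkness; single
granule area = 1.6π(r̄ + 2σ_r + dilation)², the min-filter dilation being
(size−1)/2; minimum area a quarter of the mean disk). On real micrographs
these are starting points to be tuned by inspection, not claims.

## The synthetic-data generator

The generator encodes the study design — 3 vs 3 biological replicates,
three proteomics fractions plus one transcriptome — with distributional
stand-ins chosen to be realistic for label-free data:

* log2 intensities ~ Normal(μ_f, σ_f), μ_f ~ N(23, 2), σ_f ~ U(0.2, 0.8)
  (values stored on the raw 2^x scale so the log2 step is exercised);
* regulated features (fraction and signed log2 effect configurable,
  defaults 10% at ±2) are shared across all datasets of one study, drawn
  from the config seed alone;
* missingness either uniform or left-censoring-like: P(missing) logistic
  in −log2 intensity, midpoint solved by bisection so the overall rate
  matches the target — left-censoring is the dominant missingness
  mechanism in label-free data and stresses the filter rule;
* transcript counts negative binomial (variance μ + μ²/dispersion,
  default dispersion 10) with log-normal library factors (15% CV);
* micrographs: textured background (smoothed Gaussian field), bright
  elliptical organelle blobs, anti-aliased dark disks (radius ~ N(4, 0.5)
  px at 2 nm/px) placed non-overlapping and outside blobs by rejection
  sampling, plus pixel noise; generated ROIs avoid the blobs, mirroring
  manual box selection that avoids organelles;
* assay plates: linear 4-MU response with configurable slope/intercept/
  noise; at zero noise, back-calculation recovers the true activities
  exactly.

Everything is deterministic under a fixed integer seed (NumPy Generator;
per-stage seeds derived by CRC32 hashing of stage names so stages re-run
reproducibly in isolation).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: peptide-level quantification and protein
inference, correlated protein co-regulation outside planted pathways,
batch effects, heavy-tailed intensity noise, granules that touch or
overlap organelles, or nonlinear standard curves. Problem sizes in the
test and acceptance suites (50–2,000 features, 100 pathways, up to 200
granules per 512×512 image, 10 replicate studies) were chosen so every
suite exercises the asymptotics that matter while remaining quick to run.

## Known limitations

* The permutation FDR with 3 vs 3 has only 20 distinct relabelings; the
  FDR estimate is correspondingly coarse, and single-study estimates of
  the flagged fraction under the null are quantized.
* The χ² enrichment p-value is an approximation whose accuracy degrades
  for very small pathways in very small universes; the membership floor
  (≥ 2 per side per dataset) is the guard.
* Density units follow the configured calibration; counts "per nm²" from
  published work can be physically implausible for ~20 nm granules
  (per µm² is the likely intent), so both units are supported and explicit.
* The printed AF β-galactosidase summary (2.57 ± 0.31) is inconsistent
  with its own printed replicates (2.64, 3.02, 3.26 → mean 2.97); the
  package always computes summaries from replicates and makes no attempt
  to reproduce the inconsistent figure.
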