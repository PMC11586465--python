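# Methods

This note records the models, the defaults and why, the numerical
choices, and what the synthetic study does and does not establish.

## Regional case–control model

Each region's GMV is modelled by OLS with additive age, sex, TIV and
group terms; the group coefficient's t (df = n − 5) and two-sided p are
the map. GMV is z-normalized per region across subjects before fitting;
the group t statistic is invariant to any positive affine rescaling of
the response, so this affects presentation only (tested). The design
matrix is shared across regions, so all 322 fits reduce to one
pseudo-inverse and a matrix product; statsmodels OLS reproduces the
per-region t and p exactly and serves as the cross-check in the tests.

The covariates enter additively. A multiplicative age×sex interaction
without main effects was considered and rejected: an interaction-only
adjustment is not a meaningful covariate model, and the covariates are
standard confounders of brain volume.

FDR is Benjamini–Hochberg with the family defined as all regions within
one contrast. Default α = 0.05; a stricter post-hoc threshold (0.017,
i.e. Bonferroni over three group contrasts) is exposed as
`RunConfig.posthoc_alpha` for subgroup comparisons. The pooled-patient
contrast ("TLE") combines both patient groups; patient-vs-patient is an
ordinary contrast with `control_group="FBTCS-"`. FBTCS+ subgroups are
split by recency of the last bilateral seizure at a strict 2-year
boundary: strictly more than 2 years = remote, otherwise current.

## Expression preprocessing

Real-mode input is an already donor-aggregated regions×genes matrix;
probe reannotation, probe selection and sample-to-region matching are
upstream concerns. In-package steps:

* **Intensity filter** — keep genes detected above background in ≥ 50%
  of regions (inclusive boundary).
* **Scaled robust sigmoid** — s(x) = 1/(1+exp(−(x−median)/(IQR/1.35)))
  then min–max to [0, 1]. The IQR/1.35 factor makes the width a
  normal-consistent SD estimate. Applied across regions within gene,
  then across genes within region; each pass can be disabled. Zero-IQR
  genes fall back to min–max with a warning. The transform is bounded,
  order-preserving and invariant to positive affine input maps.
* **Left-hemisphere restriction** — donor coverage of the right
  hemisphere is too sparse in the source expression atlas, so the PLS
  stage runs on the 159 left regions of the default parcellation.

## PLS1 and bootstrap gene inference

For a single response the first PLS weight vector has the closed form
w = Xᵀy/‖Xᵀy‖; scores are Xw and explained variance is corr(Xw, y)²,
sign-fixed so scores correlate non-negatively with y. Only the first
component is used anywhere; nothing iterative is needed, and
scikit-learn's PLS is the independent oracle in the tests.

The permutation test reindexes y by spatial spins by default (plain
shuffling is available for non-spatial responses and is what the
calibration tests exercise); p uses +1 smoothing and hence never falls
below 1/(n_perm+1).

The bootstrap resamples regions with replacement and refits. A PLS
component's sign is arbitrary, so each bootstrap weight vector is
aligned to the original (flipped when its inner product with the
original weights is negative) before the per-gene SE is taken; without
alignment the SEs absorb the sign indeterminacy and z collapses toward
zero. z = original weight / bootstrap SE, two-sided normal p, BH across
all modeled genes. PLS+/PLS− lists are ranked by |z| with a
lexicographic gene-id tie-break. Default n_boot = 1000; fewer than 100
resamples is rejected as too unstable for an SE.

## Enrichment ratio

ER standardizes the observed median weight of a list∩set intersection
against medians of equal-size draws without replacement from the full
modeled-gene universe (default 10,000 draws; one-sided upper-tail p).
Sampling from the universe rather than from within the thresholded list
is deliberate: the within-list null cannot produce ER magnitudes beyond
~1 and would make every reported enrichment vanish. A structural
consequence, visible in `examples/04_enrichment_ratio.py`, is that any
set intersecting a weight-thresholded list carries a mildly positive
baseline ER; genuine enrichment must stand out against that baseline,
and the FDR battery is run within each PLS list (so a single-set battery
has q = p). Empty intersections yield a flagged NaN result, not an
error. ER is invariant under positive affine transforms of all weights.
Cell-type enrichment assigns the PLS+ list (the default; PLS− by
argument) to seven canonical classes: astrocytes, endothelial cells,
excitatory neurons, inhibitory neurons, microglia, oligodendrocytes,
OPCs. Gene-list overlaps report containment in both directions plus
Jaccard, because "percent overlap" is ambiguous about its denominator.

## Spin null

Per permutation: one Haar-random rotation (QR of a Gaussian matrix,
determinant forced positive) applied to left-hemisphere centroids and
its x-mirrored twin to the right hemisphere; each rotated parcel takes
the identity of the nearest original centroid within its hemisphere,
assigned greedily in random order so every row is a bijection
(hemisphere closure is asserted on construction). Subcortical parcels
have no spherical coordinates and rotation is meaningless for them; they
are shuffled uniformly among themselves, and a cortex-only scope is
available by subsetting the atlas. p-values are two-sided on |r| with +1
smoothing. The test permutes the first map and holds the second fixed;
p is therefore not guaranteed symmetric in its arguments. With coarse
parcellations the rotational null only partially absorbs smoothness
(example 03 shows the naive analytic p rejecting twice as often as the
spin p on independent smooth maps); the correction sharpens with
resolution.

## Synthetic study

The generators are pure functions of (arguments, seed). Defaults define
the study conditions: 322 regions (152 left + 156 right cortical on
deterministic Fibonacci half-sphere lattices, 7+7 subcortical without
centroids), cohorts of 60 controls, 37 and 89 patients, atrophy of 2.0
noise-SD on 10 left cortical regions in both patient groups, 2,000 genes
with 100 aligned to the patient t-map at mixing weight 0.6, one gene set
with half its 60 members drawn from the aligned genes, and a receptor
map at expected Spearman 0.24 with the t-map. Noise and gene fields
share an exponential covariance exp(−θ/0.3) on inter-centroid angle
(a valid kernel on the sphere); subcortical noise is independent, which
matches the spin null's inability to rotate subcortex. Covariate effects
(age −0.03, sex 0.4, TIV 0.002 per unit, in noise-SD units), age uniform
on 18–45, TIV log-normal around 1500 cm³, onset age uniform on 5–25,
frequent-seizure probability 0.54 and last-bilateral-seizure recency
uniform on 0–6 years are loosely matched to published cohort summaries;
they are confounder plumbing, not quantities under test. The receptor
generator mixes the reference map's standardized ranks with Gaussian
noise at Pearson weight 2·sin(π·ρ/6) — the Gaussian-copula inversion —
so the expected Spearman equals the target.

What passing the synthetic study shows: the pipeline recovers planted
regional, gene-level and set-level structure at realistic sizes, and
each permutation machinery holds its type-I error. What it does not
show: robustness to the things real data add — segmentation error,
site effects, donor-specific expression structure, non-Gaussian noise,
and genuine biological coupling between covariates and atrophy.

## Numerical and scale choices

Deterministic seeding throughout: each pipeline stage's seed is a SHA-256
hash of (master seed, stage name) reduced below 2³¹, so adding stages
never perturbs earlier ones, and identical configurations produce
byte-identical tabular outputs (fixed column order, 6-significant-digit
formatting). Spearman uses average ranks for ties; chi-square is the
uncorrected Pearson statistic (the only variant that reproduces the
reference cohort table's printed p-values); z-normalization uses the
sample (ddof = 1) SD. Permutation p-values are never zero by
construction. The test suite scales Monte-Carlo sizes to what the
properties need — calibrations run 500–1,000 replicates against bands
centred on the exact attainable level of a B-permutation test,
(⌈α(B+1)⌉−1)/(B+1), and the end-to-end recovery check runs the full
pipeline 50 times at reduced permutation counts (100 spins, 1,000 ER
draws, 200 bootstraps), which leaves the planted effects' detectability
untouched.

## Known limitations

* Real-mode AHBA preprocessing (probe handling, donor aggregation) is
  out of scope; feed an aggregated matrix.
* Voxel/vertex-level analysis, cortical thickness, variogram-matching
  surrogate nulls and multi-component or regularized PLS are not
  implemented.
* Pathway annotation (GO/KEGG) is delegated to external services; the
  package exports ranked gene lists only.
* The ER's baseline-positivity under thresholded lists (above) means ER
  p-values across sets should be compared within a battery, not read as
  absolute calibrated tests of "any enrichment".
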