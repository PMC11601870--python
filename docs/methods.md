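# Methods

`lipidflow` implements a complete analysis chain for a multi-tissue,
two-sex, five-group (sedentary + 1/2/4/8 weeks of endurance training)
rodent lipidomics study: untargeted feature-table QC and normalization,
internal-standard semi-quantification, empirical-Bayes moderated
differential statistics, rank-based lipid-set enrichment, fuzzy c-means
trajectory clustering, and correlation / co-expression network analysis.
Because the pipeline is exercised on synthetic data with known ground
truth, this note describes both the analysis models and the generative
model, and states explicitly what the passing tests do and do not show
about real data.

## Lipid nomenclature

Shorthand names are parsed with a small deterministic grammar: a class
token from a 43-entry controlled vocabulary (editable configuration,
RefMet-style granularity, with CE and SiE kept separate so cholesteryl and
sitosteryl esters retain their distinct biological origins), then either a
sum composition (`PC 40:6`) or chain-resolved composition with `/`
(sn-position known) or `_` (unknown) separators. `O-`/`P-` chain prefixes
mark ether linkages and promote the class (`PE O-18:1_22:5` is an `O-PE`);
`d`/`t` prefixes mark sphingoid bases (a single `d`-prefixed token in a
multi-chain sphingolipid class, as in `SM d42:2`, is a base-containing sum
composition); `Cer C16:0`-style names are N-acyl shorthand with the d18:1
base left implicit, and their totals are recorded acyl-only with a flag;
`(d7)`/`(d9)` suffixes are deuterium labels identifying spiked internal
standards. Unknown class tokens raise; there is no fallback class.

TAG species are binned by total carbons into closed chain-length classes
(short C30–48, medium C49–52, long C53–55, very-long C56–60; outside
30–60 → "other", flagged) and by double bonds into saturated (0),
monounsaturated (1) and polyunsaturated (≥2). The ω-3/ω-6 selection takes
chain-resolved PC or PE species carrying one anchor chain (16:0, 16:1,
18:0 or 18:1) plus, on a different chain, 22:6 (DHA) or 20:4 (ARA);
sum-composition-only species cannot be evaluated and are reported as
skipped rather than guessed from total composition.

## Untargeted preprocessing

* **Drift correction** — per feature, an OLS line of pooled-QC area
  against injection order; every area is rescaled by `fit(ref)/fit(order)`
  with `ref` the median observed QC injection order (this keeps the
  corrected scale near the raw scale; the reference point is a package
  choice). Features with fewer than 3 QC observations, or a fitted line
  that is nonpositive anywhere, pass through unchanged and are flagged.
* **Feature filters** — a feature is removed when its mean study area is
  below 5× the blank background (mean blank area, missing treated as 0),
  when it appears in fewer than 50% of pooled QCs, or when its QC
  coefficient of variation (on raw areas) exceeds 30%. Annotated features
  detected in both ESI modes keep the occurrence with the lower QC CV,
  ties resolving to positive mode (flagged).
* **Normalization** — log2, then per-feature standardization (median 0,
  sd 1; zero-variance features get sd 1 and a flag), then per-sample
  median subtraction, per mode; modes are then row-concatenated. Sample
  medians are exactly zero on observed cells after centering.
* **Outlier screen** — report-only: a sample is suspect if its median
  Pearson correlation to the other samples on raw intensities falls below
  0.75, or if any of its first three principal-component scores (each PC
  kept only when explaining ≥ 7.5% of variance) lies outside 3×IQR
  fences. The PCA runs on log2 feature-standardized data *before* sample
  centering: centering removes exactly the uniform sample shift the screen
  exists to catch.
* **Cross-tissue PCA** — lipids present in ≥ 5 tissues, on log2 data
  without feature standardization (feature scale is part of a tissue's
  identity), minimum-imputed per lipid and sample-median-centered.
  One-way variance components (method of moments with the
  unbalanced-design group-size correction) quantify how much of each PC is
  between-tissue.

## Semi-quantification

Concentrations are peak-area ratios to the class- and mode-matched spiked
internal standard times its known concentration, scaled by extraction
geometry (10 mg tissue / 400 µL solvent; 25 µL plasma / 75 µL), giving
µg/mg tissue or µg/µL plasma. Classes without their own standard borrow
the closest same-mode one through an explicit catalog. Class-level sample
outliers are removed on the class-sum scale at 5 unscaled MADs from the
median (15 for subcutaneous white adipose, whose TAG dominance makes the
class sums intrinsically noisier); a zero MAD with any deviation marks
the deviating samples. Remaining holes are filled by NIPALS-PCA
imputation: missing cells start at the feature mean and are refined by
alternating a NIPALS principal-component fit of the completed matrix with
re-filling from the rank-k reconstruction (rank 2 by default, tolerance
1e-9 on the fills, ≤ 500 sweeps). The alternating form is used because a
single greedy NIPALS deflation over observed cells does not reach exact
completion on rank-2 data, while this fixed-point iteration recovers
exactly-low-rank matrices to numerical precision. Negative fills are
replaced by the feature's observed mean on the concentration scale (the
rule is disabled for signed log-scale inputs). Standard-curve calibration
for the targeted assay fits area = a·conc + b by OLS, rejects curves with
R² < 0.9, and floors negative back-calculations at 0 with a flag.

## Differential statistics

Per-lipid OLS with a shared design (cell-means coding for contrasts;
mean-reference coding available), followed by empirical-Bayes variance
moderation: residual variances are modelled as scaled chi-square draws
around a prior (d0, s0²), estimated by method of moments on log s² via
digamma/trigamma identities (trigamma inverted by bracketed root
finding); non-positive excess dispersion degenerates to d0 = ∞. The
moderated t uses the posterior variance (d0·s0² + d·s²)/(d0 + d) with
d0 + d degrees of freedom; the moderated F over k independent contrasts is
the quadratic form in the inverse contrast covariance divided by k·s̃²,
equal to the mean of squared moderated t over an orthogonalized contrast
set, and exactly t² for k = 1. Contrast families: per-timepoint contrasts
against sex-matched sedentary controls (fitted separately per sex), the
overall-training F combining all timepoints, and a joint two-sex
cell-means fit providing naive per-timepoint sex differences and
difference-of-differences interaction contrasts. BH adjustment is applied
within each contrast family; the standalone implementation is verified
against the reference empirical-Bayes implementation (limma via Rscript)
in the test suite.

**Power note.** Calibration and power experiments run at the differential
stage's input contract (log2 matrix = group means + Gaussian noise,
sample-median-centered): planted standardized effects of 3.0 at n = 5 are
recovered with median sensitivity ≈ 0.93 at ≈ 5% empirical FDR. Pushing
the same effects through feature standardization first costs substantial
power: standardization forces every feature's total variance to 1, so
affected lipids end up with *smaller* scaled residual variances than the
null majority, and the empirical-Bayes prior — correctly, under its
exchangeability assumption — shrinks them back up, deflating their t
statistics. This is a real property of the standardize-then-moderate
workflow, not an implementation artifact, and should be kept in mind when
interpreting sensitivity on standardized data.

## Enrichment

LSEA is the GSEA-style weighted running-sum statistic (weight exponent 1):
hits advance by |metric|/Σ|metric|, misses retreat uniformly, ES is the
extremum (exact positive/negative ties resolve to the positive extremum).
Rankings use the moderated F (positive-only scoring) or signed −log10 p.
The null is the ES of random same-size sets (plain permutation estimator,
default 10,000 draws, one shared random stream per call for
reproducibility; the adaptive multilevel refinement of the reference
procedure is not implemented). NES divides ES by the mean |null ES| of
matching sign; the p-value is the add-one estimator counting all
permutations at least as extreme in |ES| — counting only same-sign
permutations over the full denominator would be anti-conservative when
the null sign frequencies are asymmetric. ORA is the one-sided
hypergeometric tail, BH-adjusted across sets; queries are cluster cores
(membership ≥ 0.5) or module hubs (|kME| ≥ 0.7) against all named lipids,
with a minimum set size of 10.

## Trajectory clustering and concordance

Cluster inputs are z-scored group (sex × timepoint) means of the
normalized data. Fuzzy c-means uses fuzzifier m = 1.5, k-means++-style
seeding, 10 restarts keeping the best objective, and the standard
alternating updates; a point coinciding with a centroid takes membership
1 there. The cluster count is chosen from the minimum pairwise
centroid-distance curve at its point of maximum concave curvature
(2d(c) − d(c−1) − d(c+1)) — the c after which additional clusters stop
being separated; a curvature small relative to the median point norm
flags the choice as low-confidence, and the full curve is returned for
visual override (c = 9 is the documented full-scale default). Sex and
tissue concordance of training responses uses the 5-point Pearson
correlation of each lipid's logFC trajectory (0 prepended at baseline);
all-zero trajectories are flagged missing rather than scored 0.

## Networks and modules

Sample-level networks correlate every (tissue, lipid) pair over animals
matched across tissues by id within one sex, Bonferroni-corrected over
all tested pairs at adjusted p < 0.05, split into intra-/inter-tissue
scopes with degree and tissue-pair summaries. Co-expression modules use
the signed soft adjacency ((1+r)/2)^β (β = 6 default; per-tissue
overrides are configuration) and the topological overlap matrix
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij). Lipids are
average-linkage clustered on 1 − TOM and the tree is cut at the height
maximizing weighted modularity of the TOM graph over a candidate grid — a
deliberate replacement for dynamic tree cutting, whose internals live in
the reference package; modules below the minimum size join a grey pool,
and modules whose eigen-profiles (first PC of the standardized module
submatrix, unit norm, oriented positively with the module mean) correlate
above 1 − 0.15 are merged. Pearson correlation is the single kernel
throughout (the biweight-midcorrelation option of the reference workflow
is noted as configuration, not implemented). Note that the topological
overlap of two identical profiles equals exactly 1 only when their shared
neighbourhood weights are binary (e.g. a perfectly correlated table);
in a generic background it is close to but below 1. kME is the
lipid-eigenprofile correlation, hubs at |kME| ≥ 0.7 (closed threshold).
Module eigen-profiles correlate against phenotypes per sex at raw
p < 0.05; the role-based pairing of storage-lipid modules with adiposity
measures and membrane-lipid modules with fitness markers is exposed as an
optional configuration mapping, not hard-coded.

## The synthetic study generator

The generator emulates the study design: 9 compartments (8 tissues +
plasma), 2 sexes × 5 groups × 5 animals, ~570 annotated lipids per
tissue across ~19 classes plus an MSI-4 tail and 11 spiked internal
standards, two ESI modes with class-appropriate polarity. The abundance
model is lognormal: log2 area = class-by-tissue baseline (TAG dominating
the adipose depots; ether-PE and HexCer enriched in hippocampus) +
lipid-specific offset (sd 2.5 log2, clipped at ±4 — a several-order-of-
magnitude spread, which is what makes raw-intensity inter-sample
correlations sit above the 0.75 screening threshold, as in real feature
tables) + planted effects + per-animal latent block factors + Gaussian
noise. Per-feature noise is intensity-dependent (sd scaled 0.5–1× by a
logistic in baseline abundance): abundant peaks are measured more
precisely, as on a real instrument; the same factor scales the latent
block loadings so the standardized-scale co-expression structure is
intensity-invariant.

Planted structure, all recorded in a `GroundTruth` object regenerable
from (design, effects, seed):

* **Effects** in units of the residual noise SD: sex baselines, timewise
  responses vs SED, and sex-restricted (dimorphic) responses, selected by
  class or id. The default conditions plant early TAG depletion with
  partial rebound in the adipose depots and muscle, an acylcarnitine rise
  in heart and liver, a late hippocampal HexCer decline, a female-higher
  ether-PE/SM baseline, and a male-only heart phospholipid response.
* **Co-expression blocks** — a TAG block and a phospholipid block per
  tissue driven by per-animal latent factors (loading 0.5 by default;
  the `module_strength` knob trades module detectability against the
  animal-level variance it adds to block lipids' group means).
* **Phenotypes** — body weight, %fat, %lean, NEFA (rise-then-fall),
  glycerol, glucose, leptin, VO2max, max run speed, adipocyte area/count,
  with sex-specific temporal templates plus a linear link from the
  subcutaneous-adipose TAG block's latent factor to %fat, leptin,
  adipocyte area and NEFA, so module-phenotype correlations have known
  sign.
* **QC structure** — pooled-QC injections at least every 10th position,
  blanks, per-feature linear drift (slope sd 0.08), intensity-dependent
  missingness (logistic in abundance, calibrated to the target rate,
  internal standards exempt), planted blank-contaminated and
  high-QC-CV features, cross-mode degenerate twins (noisier in positive
  mode), and optional planted outlier samples (uniform +20 SD shifts).
* **Targeted assay** — ~20 oxylipin/NAE analytes per tissue with QC
  concentration and retention-time replicates, planted CV/RT failures and
  one analyte pushed past the 20% missingness filter.

A lighter generator (`simulate_normalized_matrix`) produces matrices
directly at the differential stage's input contract (group means + noise,
sample-median-centered) for calibration and power experiments at
arbitrary lipid counts.

**What the generator does not emulate**: retention-time structure, adduct
and isotope patterns, batch blocks within a tissue (exposed as a future
knob, default one batch), heavy-tailed or correlated technical noise
beyond the intensity-dependent SD, and compositional closure of real
peak areas. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated model, not robustness to
every artifact of real LC-MS data.

**A deliberate tension worth knowing about**: the default study plants
class-wide one-directional TAG effects covering ~38% of positive-mode
features in the adipose depots. Median-based sample centering partially
absorbs such broad shifts and redistributes them onto unaffected lipids,
which inflates the full-study empirical FDR well above nominal — the same
compositional limitation global normalization has on real data with bulk
lipid loss. The calibration experiments use sparse, direction-balanced
effects where median centering is valid.

## Problem sizes and determinism

The packaged end-to-end run uses 9 tissues × ~570 lipids, 1,000 LSEA
permutations (the standalone `lsea` default stays at 10,000), c = 9
clusters and 2 × ~5,400-node networks; all randomness flows from a single
integer seed through `numpy.random.default_rng`, and repeated runs with
the same seed produce byte-identical output files (fixed column order and
`%.6g` float formatting).

## Known limitations

* Moderated statistics assume a shared residual df across lipids; the
  pipeline therefore completes the normalized matrix by NIPALS imputation
  (rank 2) before model fitting instead of per-lipid missing-data fits.
* The modularity-scored static tree cut can split or merge differently
  from dynamic tree cutting near module boundaries.
* Elbow selection for c is a heuristic; the curve is always returned and
  the full-scale default (c = 9) is configuration.
* The permutation LSEA p-value is floored at 1/(n_perm+1); deeply
  significant sets need more permutations for tight p-values.
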