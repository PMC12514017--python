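# Methods

This note documents the models implemented in `protectomap`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data can and cannot establish about real cohorts.

## Synthetic study design

`synthdata` generates every input of the pipeline as a pure function of
(config, seed).

**Geometry.** Region centroids are a Fibonacci lattice over the full unit
sphere — the surface-registration sphere of one cortical hemisphere, the
space the spin test rotates. (Surface pipelines map each hemisphere onto an
entire sphere; restricting centroids to a half-sphere breaks the spin
test's calibration, because 3-D rotations leave an uncovered cap whose
nearest-neighbour reassignment over-smooths the null maps.) A stand-in MNI
coordinate is the sphere coordinate at 100 mm radius; it is used only for
donor-sample assignment, which is internally consistent with it. The
default region count is 499, the left-hemisphere half of a 1000-parcel
atlas, because donor expression data are predominantly left-hemispheric.

**Cohort.** Defaults mirror a male-predominant patient group: 49 F / 294 M
patients vs 131 F / 213 M controls, nine sites assigned round-robin, ages
uniform on [55, 80] years with thinning `age_slope = −0.01` mm/yr around a
smooth ~2.5 mm regional baseline. Site effects are additive offsets
(centered multiples of `site_shift = 0.05` mm) and multiplicative noise
scales interpolating from 1 to `site_scale = 1.2`. Patients additionally
lose thickness in `atrophy_regions` (default: region ids 1–75): the peak
loss is −0.3 mm for males and −0.1 mm for females, ramped linearly from
20% to 100% severity across the sorted atrophic regions
(`atrophy_gradient = (0.2, 1.0)`). The gradient models graded regional
vulnerability — observed atrophy t-ranges in such cohorts span roughly −2
to −12, which a uniform effect cannot produce — and it is what makes the
male/female detection asymmetry structural: with ~1 W of per-patient noise,
the weak end of the ramp stays undetectable in the smaller female group
while males (larger n, 3× the amplitude) saturate. Residual noise is
`noise_sd = 0.1` mm. Thickness values that would fall below 0.1 mm are
clipped with a warning.

**Expression.** Gene maps are zero-mean Gaussian random fields with
exponential covariance `exp(−θ/ℓ)` in angular distance, `ℓ = 0.3` rad by
default — strong spatial autocorrelation, as in real transcriptomic maps.
A planted set (default 20 genes) mixes the standardized interaction map
with weight `c = planted_coupling` and independent smoothed noise with
weight `√(1−c²)`; all columns are z-scored across regions. `c = 0.8` is the
recoverability regime the acceptance suite tests.

**Donor bundles.** Each of the (default 6, minimum 2) donors samples ~90%
of regions once, at MNI coordinates jittered by 2 mm around centroids, plus
deliberately unassignable far-off samples. Genes carry 1–3 probes: one
high-fidelity probe tracking the true profile, optionally a noisy probe and
a background-failing probe whose above-background call rate (~35%) falls
under the 50% rule. Donors differ by a global intensity scale that
normalization must remove.

**Tissue table.** 54 tissues (13 brain), log-normal baseline TPM;
brain-enriched genes get an 8-fold TPM boost in brain tissues.

What the generator does **not** emulate: vertex-level data, cortical
geometry and parcel adjacency, realistic MRI noise spectra, hemispheric
asymmetries, ontology structure among gene sets, and donor-specific
anatomical sampling bias. Passing tests therefore establish that the
statistical machinery behaves correctly under the assumed generative
model — not that real cohorts satisfy those assumptions.

## Harmonization (ComBat)

Parametric empirical Bayes, fitted jointly on patients and controls with
group, age and sex protected. Per region: OLS on site indicators plus
covariates; standardization by the count-weighted grand mean and pooled
residual variance (divisor N); per-site location `γ̂` and scale `δ̂²`
(divisor n_site) on the standardized residuals; normal prior on γ,
inverse-gamma on δ² with moment-matched hyperpriors; fixed-point iteration
(γ then δ) to 1e-6, max 500 iterations. With a single site (or no spread
across regions) shrinkage is skipped and the model is an exact identity.
The divisor-n convention makes that identity exact; it differs from the
n−1 convention of the reference R implementation by n/(n−1), which the
cross-validation test absorbs in its 0.02 mm tolerance. Degenerate
zero-variance regions and rank-deficient designs raise rather than pass
silently. Non-parametric EB, reference-batch mode and GAM variants are out
of scope.

Two caveats the tests document: per-region post-adjustment site gaps retain
sampling noise (shrinkage deliberately does not chase it), so removal is
asserted on across-region means; and multiplicative harmonization
necessarily rescales Cohen's d denominators, so covariate-preservation is
defined within sites under additive site effects.

## Normative modeling and regional tests

Per-region OLS `thickness ~ 1 + age + sex` on controls only (≥ 10
required), residual SD with denominator n − 3. Sex is coded female = 1 /
male = 0 throughout, so positive coefficients mean "greater in females" —
the interaction estimate `β_r` equals the female−male W-mean difference
exactly (asserted to 1e-12). Atrophy tests are one-sample t against 0 with
BH-FDR across regions, computed within the tested subset (per hemisphere /
per sex), matching how counts are reported. Control W-scores are available
for diagnostics; patient W-scores are the analysis object.

Note that the one-sample t treats the control reference as fixed: with
finite controls, the normative-model estimation error is shared by all
patients within a region, which widens the per-region null spread of mean
W beyond 1/√n_patients. This is a property of the W-score method itself
and is visible in the synthetic results (significant regions beyond the
planted set at large n).

## PLS, spin test, bootstrap

Univariate-outcome PLS by deflation (NIPALS-equivalent): `w_k ∝ X'y` on
deflated matrices, unit-normalized; scores `t_k = Xw_k` mutually
orthogonal; per-component statistic is the fraction of outcome variance
explained (regression of y on t_k), whose sum over all rank components
equals the OLS R² (tested against a least-squares oracle). Signs are fixed
so corr(t_k, y) ≥ 0. X columns are z-scored by default so weights are
comparable across genes.

**Spin nulls** draw uniform rotations (QR of a Gaussian matrix, det +1),
rotate the registration-sphere centroids and reassign each region to the
nearest rotated centroid (duplicates permitted; coverage is logged).
P-values use the add-one rule and are never zero; the k = 1 path is fully
vectorized and asserted equal to the generic loop. Calibration under
smooth null maps is part of the acceptance suite (rejection ≈ 5% at
α = 0.05).

**Bootstrap ratios** resample regions with replacement, jointly for X rows
and y; each replicate's components are sign-aligned to the empirical
scores; SE is the replicate SD. The resampled statistic is the
*unnormalized* salience (X'y on deflated matrices): bootstrapping the
unit-norm direction would understate the SE, because resampling noise
pooled over all genes inflates the replicate norm and shrinks every
normalized coordinate's spread (measured null tail at |ratio| > 3 of 3.9%
instead of the normal-tail 0.3%; with raw saliences, 0.2%). Ratios are
read like z-scores and rank the genes for enrichment. Replicates with a
degenerate resampled outcome are redrawn and counted.

A structural limitation worth knowing: the first weight vector is
proportional to (X'X)w* under a linear generative model, and with fewer
regions than genes the sample covariance rotates any dense ground-truth
vector substantially — even noiseless recovery of a random w* caps near
corr ≈ 0.6 at 499 × 1000. In the planted-coupling design the spatially
autocorrelated background genes acquire chance correlations with the
(smooth) outcome map, capping corr(w₁, planted indicator) around 0.65–0.75
at coupling 0.8. Recovery of the planted *set* through enrichment is
nevertheless reliable, which is why the acceptance suite phrases
recoverability at the gene-set level.

## Enrichment

Weighted running-sum ES with p = 1 weighting (hits add |score|/Σ|score|,
misses subtract 1/(N−n)); the extremum by absolute value is the ES, and
the leading edge is the hit prefix (positive ES) or suffix (negative).
Ranks are deterministic: ties break by gene id. Null ES per term samples
hit positions uniformly (equivalent in law to gene-label permutation for a
single term), vectorized over permutations. NES divides ES by the mean
|null ES| of matching sign; the permutation p is the add-one tail *within
the sign-matched null stratum* — the tail over all nulls in the
data-chosen direction would be anti-conservative by ~2× — and BH-FDR is
applied separately to positive and negative NES. Set sizes are evaluated
after intersection with the ranked universe; the 5–2000 filter boundaries
are inclusive/exclusive exactly as stated. Redundancy reduction is a
greedy weighted set cover: gain = (−log10 p) × newly covered leading-edge
genes, ties by larger coverage then term id, at most k = 10 terms.

Note on permutation counts: with P permutations the smallest attainable
sign-stratified p is ≈ 2/P, and BH multiplies it by the number of
same-sign terms; at P = 1000 and ~25 positive terms the q floor sits just
above 0.05, so the pipeline default is P = 2000.

## Expression assembly

Fixed stage order, enforced by flags: background filter (≥ 50% of samples
pooled across donors, boundary inclusive) → nearest-centroid sample
assignment (Euclidean MNI; default tolerance 2× the median
nearest-centroid spacing; opposite-hemisphere samples dropped when the
geometry is one-sided) → probe selection by differential stability (mean
across donor pairs of the Pearson correlation between regional mean log2
profiles; ties to the lowest probe id) → gene consistency filter (DS ≥
0.1 by default; 0 disables) → normalization and aggregation. Normalization
is scaled robust sigmoid per gene across each donor's samples, rescaled to
[0, 1] (zero-IQR rows map to 0.5), then means within region within donor,
then across donors, then gene-wise z-scoring across regions. A linear
(`zscore`) alternative sits behind the same function because the sigmoid
is a bounded monotone compression: on Gaussian-distributed profiles it
caps per-gene recovery correlation near 0.96 regardless of amplitude
(SRS is affine-invariant), so exact linear recovery (r > 0.999) is only
asserted under the linear option.

## Elementary statistics

2×2 chi-squared in closed form with the continuity correction
caller-controlled — published tables mix conventions, and both are
reproduced exactly from printed counts (uncorrected 50.3; Yates 9.23 and
30.30). Cohen's d and the two-sample t are computed from printed group
summaries (mean, SD, n) with pooled variance by default; Welch optional.
Mann-Whitney uses the tie-corrected normal approximation. BH-FDR
delegates to statsmodels and is checked against an independent step-up
oracle. (BH is not idempotent under re-application — p = (0.1, 0.5) gives
q = (0.2, 0.5) and re-applying gives (0.4, 0.5) — so the tests assert
monotonicity and domination instead.)

## Pipeline and determinism

`run_pipeline` executes simulate → harmonize → wscore → interaction →
atrophy → pls → gsea → tissue, writing TSVs with provenance headers
(stage, seed, config hash) and a JSON manifest with per-stage wall time.
Per-stage seeds are fixed offsets from the global seed. Rerunning with the
same seed reproduces every TSV byte for byte (asserted in the acceptance
suite). Default problem sizes for the pipeline configuration — 499
regions, 2000 genes, 1000 spins, 500 bootstrap replicates, 2000 GSEA
permutations — are the package's chosen synthetic study scale: large
enough for every statistical property to be measurable, small enough that
the full run completes in well under a minute. Module-level defaults keep
the larger canonical values (10000 spins, 5000 bootstrap replicates) for
callers who want them.

## Known limitations

- The spin test assumes the outcome map lives on a (registration) sphere
  with approximately stationary autocorrelation; parcel size heterogeneity
  and medial-wall effects of real atlases are not modeled.
- Bootstrap ratios inherit the usual caveats of resampling normalized
  multivariate models; they rank genes well but are not exact z-scores in
  finite samples.
- The GSEA null treats terms independently; correlations between
  overlapping gene sets are handled only by the FDR, not by the null.
- ComBat assumes exchangeable region effects within a site; spatially
  structured scanner artifacts violate the prior.
- Nearest-centroid sample assignment ignores parcel volumes and boundaries;
  the real toolchain assigns by parcel geometry.
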