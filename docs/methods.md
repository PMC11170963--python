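# Methods

This note documents the statistical procedures, the synthetic-cohort
model behind the test suite, the defaults that matter, and the known
limitations. Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Design model

All analyses operate on a paired design: each subject has a baseline
(day-0) sample and one post-treatment sample at a caller-chosen day.
Cohorts with several post-treatment days (e.g. sampling at days 28, 56
and 84) are supported by building the pairing at any single post day;
the package does not prescribe how to reduce a multi-day series because
intervention studies differ in which day they report. Subjects missing
either timepoint are excluded from the pairing and listed explicitly.
Pairing always goes through `subject_id` + `timepoint_day`; sample IDs
are opaque.

## Compositional treatment

Species tables are closed to relative abundances (total-sum scaling) and
analysed on the centered log-ratio (CLR) scale. Zeros are replaced by a
single pseudocount applied table-wide: half the smallest non-zero relative
abundance (`"half-min"`). A table-wide constant, rather than a per-sample
one, keeps CLR values comparable across samples; the choice is exposed
because no universal convention exists. Two consequences worth knowing:

* CLR values are invariant to per-sample scaling before closure, and each
  CLR column sums to zero.
* The CLR mean-centering couples features: a large shared shift in a few
  dominant species (especially species crossing the detection limit,
  where `ln(p + c)` swings by many log units) moves the per-sample mean
  and therefore shifts *every* feature's CLR value in the opposite
  direction. With many paired samples this closure artifact can make
  genuinely unchanged species test significant, and in extreme cases can
  flip the apparent direction of a weakly shifted species. This is a
  known property of CLR-based differential abundance, not of this
  implementation; the synthetic calibration cohort balances planted
  effects (below) precisely so that recovery statistics measure the test,
  not the artifact.

## Rank tests

The Wilcoxon signed-rank test drops zero differences and mid-ranks ties.
For ≤ 25 effective pairs the exact two-sided p-value is computed by a
convolution over doubled mid-ranks — equivalent to enumerating all 2^n
sign assignments, including tie patterns, at O(n·Σranks) cost; the null
distribution of W⁺ is symmetric for any tie pattern, so the two-sided p
is P(|W − M/2| ≥ |w − M/2|). Above 25 pairs a tie-corrected normal
approximation with continuity correction is used. Effect sizes follow
`r = Z/√n` with Z the uncorrected normal deviate, so the sign of r tracks
the direction of the shift; the rank-sum analogue uses `r = Z/√(n₁+n₂)`.
Rank-sum p-values are exact (via `scipy.stats.mannwhitneyu`) when the
pooled sample is tie-free and both groups have ≤ 25 observations.
Benjamini–Hochberg adjustment is applied across all features tested in
one call; species and gene panels form separate families because they are
reported separately.

## Dissimilarities, PERMANOVA, fingerprints

The four metrics and their ranges: Bray–Curtis [0, 1]; Hellinger [0, 1]
(after re-closure); Spearman dissimilarity `(1 − ρ)/2` in [0, 1] — note
this rescaling halves the common `1 − ρ` values but changes no ranking;
Jensen–Shannon divergence in nats, [0, ln 2], reported as the divergence,
not its square root.

PERMANOVA uses the standard decomposition `SS_total = Σ_{i<j} d²_ij / n`,
within-label sums analogously, `R² = SS_between/SS_total`, and
`pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a))`. The p-value is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` under seeded free relabeling
(default 999 permutations); an exact mode enumerates all distinct binary
relabelings for small cohorts. Permutations are free, not restricted
within subject; a subject-restricted scheme is a defensible alternative
for paired designs but changes the null hypothesis being tested.

Fingerprint classification assigns each post-treatment sample to the
subject of its nearest *baseline* sample (top-1). Ties are broken by
lexicographic subject ID and flagged. A variant assigning against all
other samples (leave-self-out) is available via `candidates="all"`. The
top-1-against-baselines rule is the default because the scientific
question is whether the post-treatment sample still looks like its
owner's baseline.

## Co-occurrence networks

Defaults: prevalence filter 0.2, Spearman correlation on CLR values,
edge rule |ρ| ≥ 0.3 AND BH-adjusted correlation p < 0.05. These are
conventional choices, config-exposed, since network-construction details
vary widely between studies. Properties: density `2E/(N(N−1))`,
connectivity = mean degree `2E/N`, clustering coefficient = global
transitivity, modularity from greedy modularity maximisation on the
unsigned skeleton (node order sorted for determinism), and the fraction
of positive-signed edges. An edgeless graph reports zeros with a
degenerate flag. Differential network analysis permutes timepoint labels
*within* subject (each subject's pre/post swapped with probability ½),
rebuilding both networks per permutation — this preserves the paired
structure, unlike free relabeling.

## Response layer

Responses are percentage changes of a glycemic measure; high responders
(HR) are strictly below the median change (greater reduction), with
exact-median ties deterministically assigned to LR. The partial Spearman
screen rank-transforms feature, response *and* covariates, residualises
the first two on the covariate ranks, and correlates the residuals, with
a t-test on `n − 2 − k` degrees of freedom; significance requires both
|ρ| > 0.3 (strict) and p < 0.05. Ranking the covariates makes the
adjustment remove monotone, not just linear, confounding; the residual
shared-curvature bias of rank partialling can still leave |partial ρ|
around 0.1 in a minority of strongly mediated replicates (this matches
reference implementations such as pingouin exactly and is inherent to the
construction).

Variance explained is a two-stage fit: elastic net (mixing 0.5, penalty
by seeded 5-fold cross-validation) selects features; an OLS refit on the
selection gives the reported in-sample R², with the elastic net's
cross-validated R² reported alongside because in-sample refits are
optimistic when selections are large relative to n. The penalty defaults
to the 1-SE rule (sparsest model within one standard error of the CV
minimum); the CV-minimum rule is available but tends to dense selections.
When covariates are supplied, response and features are residualised on
them first (partialling out). Responder odds ratios come from
maximum-likelihood logistic regression of HR/LR on the (per-SD
standardised, optionally) feature plus covariates, with Wald 95%
intervals; complete separation is detected (runaway coefficients or
standard errors, or solver failure) and flagged rather than reported as a
huge finite OR. GEE uses Gaussian family, identity link, exchangeable
working correlation and robust sandwich errors clustered by subject; with
one observation per cluster it reduces to OLS, which the tests verify.

## Synthetic cohort generator

The generator is the package's ground-truth testbed. Log-scale model per
species i, subject s, timepoint t:

    x_ist = μ_i + a_is + δ_i·1[t = post, arm affected] + ε_ist

* `μ_i ~ N(0, base_mean_sd²)` with `base_mean_sd = 2.5`: a heavy-tailed
  rank-abundance curve spanning several orders of magnitude, as in real
  gut metagenomes.
* `a_is ~ N(0, subject_sd²)`, `subject_sd = 2`: the stable per-subject
  fingerprint, constant across timepoints. Five blocks of four species
  share a per-subject factor at correlation 0.7 — baseline co-occurrence
  guilds, without which co-occurrence networks would be empty.
* `ε ~ N(0, noise_sd²)`, `noise_sd = 0.3`: within-subject sampling noise.
* Affected species are drawn with probability ∝ `exp(1.5·μ_i)`: drugs
  like alpha-glucosidase inhibitors act preferentially on the dominant
  saccharolytic fraction, and it is perturbation of dominant taxa that
  erases fingerprints. Effects are `±effect_sd·(0.25 + |N(0,1)|)` — the
  floor makes "affected" a meaningful label — and, when the sign balance
  is even, increased and decreased species receive magnitude-matched
  effects so the planted shifts sum to zero (treatment redistributes
  log-abundance; this keeps the CLR closure artifact from contaminating
  recovery statistics). An unbalanced `negative_fraction` deliberately
  breaks the balance to emulate depletion-dominated drugs, which is also
  what drives the planted richness decline.
* Structural zeros: the lowest 20% of each species' values are truncated
  to zero before closure, so richness responds to treatment and CLR
  pseudocounts face realistic sparsity.
* Optional post-only "co-response" guilds (blocks sharing a per-subject
  factor only in post samples) strengthen post-treatment co-occurrence —
  the planted signal for differential network analysis. Small blocks are
  used because a community-wide shared factor is largely removed by the
  CLR centering.
* Gene RPKM = (sparse non-negative link matrix)ᵀ × species relative
  abundances × 1000, plus half-normal noise; clinical post values =
  pre + shift + linear function of baseline CLR features + noise, with
  the percentage-change ground truth `(post − pre)/pre × 100`.

Identical seeds give bit-identical tables.

What the generator does *not* emulate: sequencing count noise
(compositions are continuous; a Dirichlet-multinomial layer is out of
scope), strain-level variation, longitudinal drift beyond the configured
timepoints, batch effects between studies, and covariate-microbiome
confounding (age/sex/BMI are independent of the community). Passing tests
therefore demonstrate correctness of the statistical machinery under a
realistic compositional model, not robustness to every failure mode of
real metagenomic data.

## Calibration and problem sizes

The suite's simulation checks use cohorts of 40–50 subjects with 30–100
species and 10–20 seeds per condition, sizes at which each check runs in
seconds while leaving clear margins: null fingerprint accuracy averages
≈ 0.98 against the ≥ 0.9 requirement, the strongly perturbed arm ≈ 0.28
against ≤ 0.5, planted differential-abundance sensitivity ≥ 0.9 per seed,
and the null type-I rate sits near 0.04 in a [0.03, 0.07] band (the
continuity-corrected approximation is slightly conservative). Monotone
degradation of fingerprint accuracy is asserted on means over 10 seeds
because single-seed accuracy fluctuates by ±0.15. The planted recovery
check runs on one fixed-seed cohort; across many seeds the CLR closure
artifact described above can occasionally flip a floor-magnitude planted
effect, which is a property of CLR differential abundance worth knowing
when interpreting real data.

## Numerical choices and degenerate inputs

Exact signed-rank enumeration switches to the normal approximation above
25 pairs; permutation p-values always include the identity (`(1+k)/(1+N)`)
so they are never zero; distance matrices are symmetrised against float
round-off and validated (zero diagonal, non-negativity, metric-specific
upper bounds); all-zero samples, zero-variance features, empty responder
classes, sub-minimum group sizes and absent timepoints raise errors
naming the offending sample/feature/day; greedy modularity ties are
stabilised by sorting nodes. TSV writers emit `repr`-precision floats so
write→read round-trips are bit-exact.
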