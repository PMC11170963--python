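# microshift

Paired pre/post-intervention analysis of gut-microbiome cohorts, built for
studies in which each subject contributes a baseline and a post-treatment
metagenomic profile — the design used to compare how oral antidiabetic
drugs (metformin, acarbose, berberine, vildagliptin, glipizide, placebo
arms) reshape the gut microbiota and how the baseline microbiota predicts
treatment response. It is aimed at microbiome bioinformaticians who want
the whole analysis chain — compositional transforms, dissimilarity-based
community statistics, per-feature testing, co-occurrence networks, and
response modelling — as one tested, scriptable package, exercised against
a synthetic cohort generator with known ground truth.

## What it computes

**Compositional preliminaries.** Species profiles are closed to relative
abundances and transformed with the centered log-ratio,
`y_i = ln(p_i + c) − mean_j ln(p_j + c)`, using a single table-wide
pseudocount `c` (default: half the smallest non-zero relative abundance).
Alpha diversity is species richness and the Shannon index `H = −Σ p ln p`
(nats); per-arm pre/post changes are tested with the two-sided Wilcoxon
signed-rank test (exact null distribution for ≤ 25 pairs, tie-corrected
normal approximation with continuity correction above).

**Community shifts.** Four sample dissimilarities: Bray–Curtis
`Σ|p−q| / Σ(p+q)`, Hellinger `(1/√2)·||√p − √q||`, Spearman dissimilarity
`(1 − ρ)/2`, and the Jensen–Shannon divergence (natural log, in
`[0, ln 2]`). PERMANOVA partitions the squared-distance sum of squares
between pre/post labels (`R² = SS_between/SS_total`, pseudo-F with
`a − 1` and `n − a` degrees of freedom) with a seeded permutation p-value,
or exact enumeration on small cohorts.

**Individual fingerprints.** Each post-treatment sample is assigned to the
subject whose *baseline* sample is nearest in the distance matrix; the
assignment accuracy measures whether treatment erased the subject-specific
compositional fingerprint. Drugs with strong microbiota impact drive this
accuracy far below the near-perfect level seen in placebo-like arms.

**Differential features.** Per-species paired signed-rank tests on CLR
values (genes: on raw RPKM), with effect size `r = Z/√n`,
Benjamini–Hochberg adjustment across the tested panel, and direction calls
at adjusted p < 0.05. Cross-arm comparisons of post-treatment samples use
Wilcoxon rank-sum tests with `r = Z/√(n₁+n₂)` and the conventional
|r| ≥ 0.3 effect-size line.

**Co-occurrence networks.** Per group and timepoint: prevalence-filtered
species, pairwise Spearman correlation of CLR values, edges at |ρ| ≥ 0.3
with BH-adjusted p < 0.05. Summaries: edge count, density, connectivity
(mean degree), global clustering coefficient, greedy-partition modularity,
positive-edge fraction. Pre-vs-post property changes get permutation
p-values from subject-respecting pre/post swaps.

**Treatment response.** Response = percentage change
`(post − pre)/pre × 100` of a glycemic measure (HbA1c, FPG, PPG, HOMA-IR).
The layer provides a partial Spearman screen (significant iff |ρ| > 0.3
and p < 0.05, adjusted for age, sex, BMI and the baseline measure),
elastic-net feature selection with an OLS refit whose R² is the variance
explained, median-split high/low responder logistic odds ratios, and GEE
(exchangeable, robust errors) longitudinal associations.

**Synthetic cohorts.** `simulate_cohort` generates paired cohorts from a
log-scale model `x_ist = μ_i + a_is + δ_i·1[post, affected] + ε_ist` with
per-subject fingerprints, arm-specific planted effects, co-occurrence
guilds, species-linked gene RPKM, and clinical responses driven by
baseline CLR features — so every stage can be tested against known ground
truth.

## Worked example

```python
from microshift import *

config = SyntheticConfig(
    n_subjects=40, n_species=60, seed=7,
    arm_effects={"acarbose": ArmEffect(0.3, 2.0), "placebo": ArmEffect(0.0, 0.0)},
)
species, genes, meta, truth = simulate_cohort(config)
design = build_paired_design(meta, post_day=90)

dm = distance_matrix(species, "bray_curtis")
for arm in ("acarbose", "placebo"):
    fp = fingerprint_assignment(dm, design.for_arm(arm))
    print(f"{arm}: fingerprint accuracy = {fp.accuracy:.2f} over {fp.n_assessed} subjects")

arm_design = design.for_arm("acarbose")
labels = {s: "pre" for s in arm_design.pre_sample_ids()}
labels |= {s: "post" for s in arm_design.post_sample_ids()}
res = permanova(dm.subset(arm_design.all_sample_ids()), labels, n_perm=999, seed=1)
print(f"acarbose PERMANOVA: R2 = {res.r_squared:.3f}, p = {res.p_value:.3f}")

hits = paired_feature_tests(species, arm_design)
flagged = hits[hits.direction != "ns"]
planted = {s for s, _ in truth.affected_species["acarbose"]}
print(f"differential species: {len(flagged)} flagged, "
      f"{len(set(flagged.feature_id) & planted)} of {len(planted)} planted recovered")
```

prints

```
acarbose: fingerprint accuracy = 0.50 over 20 subjects
placebo: fingerprint accuracy = 0.95 over 20 subjects
acarbose PERMANOVA: R2 = 0.084, p = 0.003
differential species: 18 flagged, 18 of 18 planted recovered
```

The acarbose-like arm (30% of species shifted at log-scale 2) loses half
of its subject fingerprints and shows a clear pre/post composition shift,
while the placebo-like arm keeps subjects identifiable; every planted
differential species is recovered. A command-line interface mirrors the
library — `microshift simulate | diversity | dissimilarity | permanova |
fingerprint | diffab | diffab-cross | network | network-diff | respond` —
with `--seed` on every stochastic step and TSV/JSON outputs that are
bit-identical across runs at the same seed.

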