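"""Synthetic paired pre/post microbiome cohorts with known ground truth.

The generator emulates the structure of a multi-arm oral-antidiabetic-drug
intervention: each subject contributes a baseline (day-0) and one or more
post-treatment stool profiles; arms differ in how strongly treatment
perturbs the community (strong for acarbose/berberine-like arms, null for
a placebo-like arm); functional-gene abundances are linear mixtures of the
species they are encoded by; and clinical responses are partially driven
by baseline microbial features.

Species model, on the log scale where the CLR operates::

    x_ist = mu_i + a_is + delta_i * 1[t = post, arm affected] + eps_ist

with per-species base levels ``mu_i ~ N(0, base_mean_sd^2)`` (the default
base_mean_sd of 2.5 gives the heavy-tailed rank-abundance curve of real
gut metagenomes, spanning several orders of magnitude), per-subject
fingerprints ``a_is ~ N(0, subject_sd^2)`` (constant across timepoints —
the premise of fingerprint classification), and sampling noise
``eps ~ N(0, noise_sd^2)``. Treatment effects are shared by all subjects
of an arm: the affected species are drawn with probability proportional
to ``exp(effect_abundance_bias * mu_i)`` — drugs such as
alpha-glucosidase inhibitors act preferentially on the dominant
saccharolytic fraction of the community, and it is perturbation of
dominant taxa that erases individual fingerprints — and each receives
``delta_i = sign * effect_sd * (effect_floor + |N(0, 1)|)``. The
magnitude floor makes "affected" a meaningful label: no planted species
carries a vanishing effect. When the sign balance is even, increased and
decreased species receive magnitude-matched effects so the planted shifts
sum to zero — treatment redistributes log-abundance rather than changing
total community log-biomass, keeping the planted signal compositionally
coherent (an unbalanced ``negative_fraction`` deliberately breaks this,
producing the relative-abundance seesaw a mass depletion causes in
closed data). Abundances are ``exp(x)`` closed to
relative abundances per sample. Structural zeros are injected by
truncating the lowest ``zero_quantile`` fraction of each species' values
to 0 before closure, so richness, pseudocounts and the Hellinger metric
face realistic sparsity.

Gene RPKM = (gene-link matrix)^T x species relative abundances x scale,
plus non-negative noise. Clinical post values = pre + shift + linear
function of baseline CLR features + noise; the response "percentage
change" ground truth is (post - pre) / pre * 100.

The same seed always reproduces bit-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AbundanceTable, CohortMetadata
from .diversity import clr_transform

__all__ = [
    "ArmEffect",
    "ResponseSpec",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_cohort",
    "planted_signal_report",
]


@dataclass(frozen=True)
class ArmEffect:
    """Treatment effect of one arm: which fraction of species shifts, how much."""

    affected_fraction: float = 0.0
    effect_sd: float = 0.0            # scale of the per-species log-scale shift
    negative_fraction: float = 0.5    # probability an affected species is depleted
    coresponse_blocks: int = 0        # post-only co-responding guilds (strengthen networks)
    coresponse_block_size: int = 4
    coresponse_sd: float = 0.0        # per-subject guild-factor loading, log scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.effect_sd < 0 or self.coresponse_sd < 0:
            raise ValueError("effect_sd and coresponse_sd must be >= 0")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.coresponse_blocks < 0 or self.coresponse_block_size < 2:
            raise ValueError("coresponse_blocks must be >= 0 with block size >= 2")


@dataclass(frozen=True)
class ResponseSpec:
    """Linear dependence of one clinical response on baseline CLR features."""

    selected_species: tuple[int, ...]   # indices into the species axis
    coefficients: tuple[float, ...]
    noise_sd: float = 0.3
    shift: float = -1.0                 # mean post-minus-pre change
    baseline_mean: float = 8.0
    baseline_sd: float = 0.8

    def __post_init__(self) -> None:
        if len(self.selected_species) != len(self.coefficients):
            raise ValueError("selected_species and coefficients must have equal length")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("sd parameters must be >= 0")


def _default_arm_effects() -> dict[str, ArmEffect]:
    # strong perturbation for acarbose/berberine-like arms, weak for
    # metformin-like, none for placebo-like
    return {
        "acarbose": ArmEffect(0.3, 2.0, coresponse_blocks=3, coresponse_sd=1.5),
        "berberine": ArmEffect(0.3, 2.0, coresponse_blocks=3, coresponse_sd=1.5),
        "metformin": ArmEffect(0.05, 0.8),
        "placebo": ArmEffect(0.0, 0.0),
    }


def _default_response_models() -> dict[str, ResponseSpec]:
    return {
        "hba1c": ResponseSpec((0, 1, 2), (-0.4, 0.3, -0.2), noise_sd=0.4,
                              shift=-1.3, baseline_mean=7.8, baseline_sd=0.7),
        "fpg": ResponseSpec((3, 4), (-0.5, 0.4), noise_sd=0.6,
                            shift=-1.5, baseline_mean=8.5, baseline_sd=1.2),
    }


@dataclass
class SyntheticConfig:
    """All knobs of the cohort generator; defaults give a realistic mid-size study."""

    n_subjects: int = 40
    n_species: int = 100
    n_genes: int = 30
    arm_effects: dict[str, ArmEffect] = field(default_factory=_default_arm_effects)
    subject_sd: float = 2.0
    noise_sd: float = 0.3
    base_mean_sd: float = 2.5
    effect_abundance_bias: float = 1.5  # affected-species sampling weight exp(bias * mu)
    effect_floor: float = 0.25          # minimum |effect| in units of effect_sd
    zero_quantile: float = 0.2
    n_corr_blocks: int = 5        # baseline co-occurrence guilds
    corr_block_size: int = 4
    corr_block_rho: float = 0.7   # within-guild correlation of subject effects
    gene_link_k: int = 3          # species feeding each gene ("random(k)" sparsity)
    gene_scale: float = 1000.0
    gene_noise_sd: float = 5.0    # half-normal additive RPKM noise
    response_models: dict[str, ResponseSpec] = field(default_factory=_default_response_models)
    timepoint_days: tuple[int, ...] = (0, 90)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for name, val in (
            ("subject_sd", self.subject_sd), ("noise_sd", self.noise_sd),
            ("base_mean_sd", self.base_mean_sd), ("gene_noise_sd", self.gene_noise_sd),
            ("effect_floor", self.effect_floor),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.zero_quantile < 1.0:
            raise ValueError("zero_quantile must lie in [0, 1)")
        if not 0.0 <= self.corr_block_rho < 1.0:
            raise ValueError("corr_block_rho must lie in [0, 1)")
        if self.n_corr_blocks * self.corr_block_size > self.n_species:
            raise ValueError("correlation blocks exceed the species count")
        if self.timepoint_days[0] != 0 or len(self.timepoint_days) < 2:
            raise ValueError("timepoint_days must start at 0 and include a post day")
        for spec in self.response_models.values():
            if any(i >= self.n_species for i in spec.selected_species):
                raise ValueError("response model references a species index out of range")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    affected_species: dict[str, list[tuple[str, float]]]      # arm -> [(species, delta)]
    response_coefficients: dict[str, dict[str, float]]        # measure -> species -> coef
    subject_effects: pd.DataFrame                             # species x subjects


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[AbundanceTable, AbundanceTable, CohortMetadata, GroundTruth]:
    """Generate one paired cohort: species table, gene table, metadata, truth.

    Subjects are assigned to arms cyclically in the order the arms appear
    in ``config.arm_effects``. An arm whose affected fraction rounds to
    zero species while its effect SD is positive is demoted to a null arm
    with a warning.
    """
    rng = np.random.default_rng(config.seed)
    n_sp, n_sub = config.n_species, config.n_subjects
    species = [f"sp{i:04d}" for i in range(n_sp)]
    genes = [f"gene{i:03d}" for i in range(config.n_genes)]
    subjects = [f"S{i:04d}" for i in range(n_sub)]
    arm_names = list(config.arm_effects)
    arm_of = {s: arm_names[i % len(arm_names)] for i, s in enumerate(subjects)}

    mu = rng.normal(0.0, config.base_mean_sd, size=n_sp)
    # subject fingerprints, with correlated blocks (co-occurring guilds):
    # within a block, a_is shares a per-subject factor with weight sqrt(rho)
    z = rng.standard_normal((n_sp, n_sub))
    subject_eff = config.subject_sd * z
    block_members: list[np.ndarray] = []
    if config.n_corr_blocks > 0 and config.corr_block_size >= 2 and config.corr_block_rho > 0:
        pool = rng.permutation(n_sp)[: config.n_corr_blocks * config.corr_block_size]
        rho = config.corr_block_rho
        for b in range(config.n_corr_blocks):
            members = np.sort(pool[b * config.corr_block_size:(b + 1) * config.corr_block_size])
            factor = rng.standard_normal(n_sub)
            subject_eff[members] = config.subject_sd * (
                np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * z[members]
            )
            block_members.append(members)

    affected: dict[str, list[tuple[str, float]]] = {}
    deltas: dict[str, np.ndarray] = {}
    for arm in arm_names:
        eff = config.arm_effects[arm]
        n_affected = int(round(eff.affected_fraction * n_sp))
        delta = np.zeros(n_sp)
        if eff.effect_sd > 0 and n_affected < 1:
            warnings.warn(f"arm {arm!r}: affected fraction selects no species; treating as null")
            affected[arm] = []
        elif eff.effect_sd == 0 or n_affected < 1:
            affected[arm] = []
        else:
            weights = np.exp(config.effect_abundance_bias * mu)
            weights /= weights.sum()
            idx = rng.choice(n_sp, size=n_affected, replace=False, p=weights)
            n_neg = int(round(eff.negative_fraction * n_affected))
            n_pos = n_affected - n_neg
            n_pair = min(n_neg, n_pos)
            pair_mags = eff.effect_sd * (
                config.effect_floor + np.abs(rng.standard_normal(n_pair))
            )
            surplus = n_affected - 2 * n_pair
            surplus_sign = -1.0 if n_neg > n_pos else 1.0
            surplus_mags = eff.effect_sd * (
                config.effect_floor + np.abs(rng.standard_normal(surplus))
            )
            d_vals = np.concatenate([pair_mags, -pair_mags, surplus_sign * surplus_mags])
            delta[idx] = d_vals[rng.permutation(n_affected)]
            affected[arm] = [(species[i], float(delta[i])) for i in sorted(idx)]
        deltas[arm] = delta

    # coordinated post-treatment response: small guilds of species share a
    # per-subject factor in post samples only, strengthening co-occurrence
    # after treatment (small blocks leave the CLR centering nearly untouched)
    coresponse: dict[str, list[np.ndarray]] = {}
    for arm in arm_names:
        eff = config.arm_effects[arm]
        if eff.coresponse_sd > 0 and eff.coresponse_blocks > 0:
            pool = rng.permutation(n_sp)[: eff.coresponse_blocks * eff.coresponse_block_size]
            coresponse[arm] = [
                np.sort(pool[b * eff.coresponse_block_size:(b + 1) * eff.coresponse_block_size])
                for b in range(eff.coresponse_blocks)
            ]

    days = list(config.timepoint_days)
    sample_ids = [f"{s}_d{d}" for s in subjects for d in days]
    log_abund = np.empty((n_sp, len(sample_ids)))
    col = 0
    for si, subj in enumerate(subjects):
        arm = arm_of[subj]
        eff = config.arm_effects[arm]
        factors = (
            rng.standard_normal(len(coresponse[arm])) if arm in coresponse else None
        )
        for d in days:
            x = mu + subject_eff[:, si] + rng.normal(0.0, config.noise_sd, size=n_sp)
            if d > 0:
                x = x + deltas[arm]
                if factors is not None:
                    for b, members in enumerate(coresponse[arm]):
                        x[members] = x[members] + eff.coresponse_sd * factors[b]
            log_abund[:, col] = x
            col += 1

    raw = np.exp(log_abund)
    if config.zero_quantile > 0:
        thresholds = np.quantile(raw, config.zero_quantile, axis=1, keepdims=True)
        raw = np.where(raw <= thresholds, 0.0, raw)
    col_sums = raw.sum(axis=0)
    if np.any(col_sums == 0):  # pragma: no cover - astronomically unlikely
        raise RuntimeError("zero-truncation emptied a sample; lower zero_quantile")
    rel = raw / col_sums
    species_table = AbundanceTable(
        pd.DataFrame(rel, index=species, columns=sample_ids), kind="relative_abundance"
    )

    # gene RPKM as sparse non-negative mixtures of species abundances
    link = np.zeros((n_sp, config.n_genes))
    for g in range(config.n_genes):
        src = rng.choice(n_sp, size=min(config.gene_link_k, n_sp), replace=False)
        link[src, g] = rng.uniform(0.5, 1.5, size=src.size)
    rpkm = link.T @ rel * config.gene_scale
    rpkm = rpkm + np.abs(rng.normal(0.0, config.gene_noise_sd, size=rpkm.shape))
    gene_table = AbundanceTable(
        pd.DataFrame(rpkm, index=genes, columns=sample_ids), kind="rpkm"
    )

    # host covariates
    age = np.clip(rng.normal(52.0, 8.0, size=n_sub), 30, 75).round(1)
    sex = rng.choice(["male", "female"], size=n_sub)
    bmi = np.clip(rng.normal(26.0, 3.0, size=n_sub), 18, 42).round(1)

    # baseline CLR features drive the clinical responses
    pre_ids = [f"{s}_d0" for s in subjects]
    clr_pre = clr_transform(species_table).loc[:, pre_ids].to_numpy()
    clinical: dict[str, dict[str, float]] = {m: {} for m in config.response_models}
    response_coefs: dict[str, dict[str, float]] = {}
    for measure, spec in config.response_models.items():
        response_coefs[measure] = {
            species[i]: float(c) for i, c in zip(spec.selected_species, spec.coefficients)
        }
        pre_vals = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_sub)
        micro = np.zeros(n_sub)
        for i, c in zip(spec.selected_species, spec.coefficients):
            micro += c * clr_pre[i]
        for si, subj in enumerate(subjects):
            clinical[measure][f"{subj}_d0"] = float(pre_vals[si])
            for d in days[1:]:
                post = pre_vals[si] + spec.shift + micro[si] + rng.normal(0.0, spec.noise_sd)
                clinical[measure][f"{subj}_d{d}"] = float(post)

    meta_rows = []
    for si, subj in enumerate(subjects):
        for d in days:
            sid = f"{subj}_d{d}"
            row = {
                "sample_id": sid,
                "subject_id": subj,
                "arm": arm_of[subj],
                "timepoint_day": d,
                "age": float(age[si]),
                "sex": str(sex[si]),
                "bmi": float(bmi[si]),
            }
            for measure in config.response_models:
                row[measure] = clinical[measure][sid]
            meta_rows.append(row)
    meta = CohortMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))

    truth = GroundTruth(
        affected_species=affected,
        response_coefficients=response_coefs,
        subject_effects=pd.DataFrame(subject_eff, index=species, columns=subjects),
    )
    return species_table, gene_table, meta, truth


def planted_signal_report(truth: GroundTruth) -> pd.DataFrame:
    """Flat per-arm table of planted species effects (empty for null arms)."""
    rows = [
        {"arm": arm, "species": sp, "effect": eff,
         "direction": "increased" if eff > 0 else "decreased"}
        for arm, entries in sorted(truth.affected_species.items())
        for sp, eff in entries
    ]
    return pd.DataFrame(rows, columns=["arm", "species", "effect", "direction"])
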