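"""Differential abundance of species (CLR) and genes (RPKM).

Within one treatment arm, each feature's per-subject post-minus-pre delta
is tested with the two-sided Wilcoxon signed-rank test; across two arms,
post-treatment samples are compared feature-by-feature with the Wilcoxon
rank-sum test. Effect sizes use the r = Z / sqrt(N) convention (N = number
of pairs for the signed-rank test, n1 + n2 for the rank-sum test), so r
lies in [-1, 1] and its sign follows the direction of the shift. P-values
are Benjamini-Hochberg adjusted across all features tested in one call;
species and gene panels form separate adjustment families.

Species are tested on CLR-transformed relative abundances; functional
genes are tested on raw RPKM values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._ranktests import rank_sum_test, signed_rank_test
from .core_io import AbundanceTable, CohortMetadata, PairedDesign
from .diversity import clr_transform

__all__ = [
    "bh_adjust",
    "paired_feature_tests",
    "crossarm_posttreatment_tests",
]

RESULT_COLUMNS = [
    "feature_id", "n_pairs", "statistic", "z_value", "effect_size",
    "direction", "p_raw", "p_bh",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(p_bh: float, alpha: float, median_delta: float, z: float) -> str:
    if p_bh >= alpha:
        return "ns"
    sign = median_delta if median_delta != 0 else z
    return "increased" if sign > 0 else "decreased"


def paired_feature_tests(
    table: AbundanceTable,
    design: PairedDesign,
    transform: str = "clr",
    alpha: float = 0.05,
    pseudocount: float | str = "half-min",
) -> pd.DataFrame:
    """Per-feature paired signed-rank tests of post vs pre within a design.

    ``transform="clr"`` CLR-transforms the (species) table first;
    ``transform="rpkm_raw"`` tests the raw values (gene RPKM). Returns one
    row per feature with statistic, z, effect size r = Z/sqrt(n_pairs),
    raw and BH-adjusted p, and a direction call (``increased`` /
    ``decreased`` at ``p_bh < alpha``, else ``ns``) signed by the median
    delta. Features whose deltas are all zero get p = 1, r = 0, ns.
    """
    if transform not in ("clr", "rpkm_raw"):
        raise ValueError("transform must be 'clr' or 'rpkm_raw'")
    if design.n_pairs < 3:
        raise ValueError(f"need >= 3 pairs, got {design.n_pairs}")
    if transform == "clr":
        matrix = clr_transform(table, pseudocount=pseudocount)
    else:
        matrix = table.data
    pre = matrix[design.pre_sample_ids()].to_numpy(dtype=float)
    post = matrix[design.post_sample_ids()].to_numpy(dtype=float)
    deltas = post - pre
    rows = []
    for i, feature in enumerate(table.feature_ids):
        out = signed_rank_test(deltas[i])
        rows.append(
            {
                "feature_id": feature,
                "n_pairs": design.n_pairs,
                "statistic": out.statistic,
                "z_value": out.z,
                "effect_size": out.effect_size,
                "median_delta": float(np.median(deltas[i])),
                "p_raw": out.p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["direction"] = [
        _direction(r.p_bh, alpha, r.median_delta, r.z_value) for r in df.itertuples()
    ]
    return df[RESULT_COLUMNS + ["median_delta"]]


def crossarm_posttreatment_tests(
    table: AbundanceTable,
    meta: CohortMetadata,
    arm_a: str,
    arm_b: str,
    post_day: int,
    alpha: float = 0.05,
    transform: str = "rpkm_raw",
    pseudocount: float | str = "half-min",
    effect_size_line: float = 0.3,
) -> pd.DataFrame:
    """Per-feature rank-sum comparison of post-treatment samples of two arms.

    Effect size r = Z / sqrt(n_a + n_b) is positive when the feature is
    higher in ``arm_a``. Two significance tiers are flagged the way the
    figure marks them: ``flag_bh`` ("*") at BH-adjusted p < alpha and
    ``flag_raw`` ("#") at raw p < 0.05; ``abs_effect_ge_line`` marks
    |r| >= ``effect_size_line`` (the 0.3 dashed line).
    """
    samples_a = meta.samples_at(post_day, arm=arm_a)
    samples_b = meta.samples_at(post_day, arm=arm_b)
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError(
            f"need >= 3 post-treatment samples per arm; got {len(samples_a)} ({arm_a}), "
            f"{len(samples_b)} ({arm_b}) at day {post_day}"
        )
    if transform == "clr":
        matrix = clr_transform(table, pseudocount=pseudocount)
    else:
        matrix = table.data
    a = matrix[samples_a].to_numpy(dtype=float)
    b = matrix[samples_b].to_numpy(dtype=float)
    rows = []
    for i, feature in enumerate(table.feature_ids):
        out = rank_sum_test(a[i], b[i])
        rows.append(
            {
                "feature_id": feature,
                "n_a": len(samples_a),
                "n_b": len(samples_b),
                "statistic": out.statistic,
                "z_value": out.z,
                "effect_size": out.effect_size,
                "p_raw": out.p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["flag_bh"] = df["p_bh"] < alpha
    df["flag_raw"] = df["p_raw"] < 0.05
    df["abs_effect_ge_line"] = df["effect_size"].abs() >= effect_size_line
    df["direction"] = [
        "ns" if not r.flag_bh else ("increased" if r.effect_size > 0 else "decreased")
        for r in df.itertuples()
    ]
    return df
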