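"""Compositional transforms and alpha diversity with paired pre/post testing.

Species tables are closed to relative abundances, CLR-transformed for all
downstream compositional statistics, and summarised per sample as richness
(count of detected species) and Shannon entropy (nats). Per-arm changes
between paired pre- and post-treatment samples are tested with the
two-sided Wilcoxon signed-rank test.

Zero handling: the CLR needs strictly positive inputs, and profile tables
contain structural zeros. The default pseudocount policy is ``"half-min"``
— half the smallest non-zero relative abundance of the whole table, one
constant applied table-wide so that CLR values stay comparable across
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ranktests import signed_rank_test
from .core_io import AbundanceTable, PairedDesign

__all__ = [
    "to_relative",
    "clr_transform",
    "richness",
    "shannon",
    "alpha_diversity",
    "paired_delta_test",
    "ArmDeltaResult",
]


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to sum 1 (total-sum scaling).

    Idempotent on already-relative tables. An all-zero sample column is an
    error naming the sample.
    """
    values = table.values
    sums = values.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample column(s): {[table.sample_ids[i] for i in zero]}")
    closed = values / sums
    return AbundanceTable(
        pd.DataFrame(closed, index=table.feature_ids, columns=table.sample_ids),
        kind="relative_abundance",
    )


def _resolve_pseudocount(values: np.ndarray, pseudocount: float | str) -> float:
    if isinstance(pseudocount, str):
        if pseudocount != "half-min":
            raise ValueError(f"unknown pseudocount policy {pseudocount!r}")
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("cannot derive half-min pseudocount from an all-zero table")
        return float(positive.min() / 2.0)
    c = float(pseudocount)
    if c <= 0:
        raise ValueError("explicit pseudocount must be > 0")
    return c


def clr_transform(table: AbundanceTable, pseudocount: float | str = "half-min") -> pd.DataFrame:
    """Centered log-ratio transform of a relative-abundance table.

    Per sample, ``y_i = ln(p_i + c) - mean_j ln(p_j + c)``; every output
    column sums to zero. ``c`` is either an explicit positive constant or
    the ``"half-min"`` table-wide policy (see module docstring).

    Returns a features x samples DataFrame of CLR values.
    """
    rel = to_relative(table) if table.kind != "relative_abundance" else table
    values = rel.values
    c = _resolve_pseudocount(values, pseudocount)
    logged = np.log(values + c)
    centered = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=table.feature_ids, columns=table.sample_ids)


def richness(sample: np.ndarray, detection_threshold: float = 0.0) -> int:
    """Number of features with abundance strictly above the detection threshold."""
    if detection_threshold < 0:
        raise ValueError("detection_threshold must be >= 0")
    sample = np.asarray(sample, dtype=float)
    return int(np.sum(sample > detection_threshold))


def shannon(sample: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) over the positive entries.

    The sample is re-closed over its positive entries, so the input may be
    counts, RPKM or relative abundances.
    """
    sample = np.asarray(sample, dtype=float)
    positive = sample[sample > 0]
    if positive.size == 0:
        raise ValueError("all-zero sample has no Shannon entropy")
    p = positive / positive.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable, detection_threshold: float = 0.0) -> pd.DataFrame:
    """Per-sample richness and Shannon index.

    Returns a DataFrame indexed by sample ID with columns ``richness`` and
    ``shannon``.
    """
    rows = {}
    for sid in table.sample_ids:
        vec = table.sample(sid)
        rows[sid] = {
            "richness": richness(vec, detection_threshold),
            "shannon": shannon(vec),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


@dataclass(frozen=True)
class ArmDeltaResult:
    """Per-arm paired change summary for one scalar per-sample quantity."""

    arm: str
    n_pairs: int
    mean_delta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool


def paired_delta_test(
    values: pd.Series,
    design: PairedDesign,
    alpha: float = 0.05,
) -> list[ArmDeltaResult]:
    """Test post - pre changes of a per-sample quantity within each arm.

    ``values`` is indexed by sample ID. Per arm, subject deltas are tested
    with the two-sided Wilcoxon signed-rank test (exact for <= 25 pairs,
    normal approximation with continuity correction above); the mean delta
    gets a t-based 95% confidence interval. Arms with fewer than 3 pairs
    are an error.
    """
    results = []
    for arm in design.arms:
        arm_design = design.for_arm(arm)
        deltas = np.array(
            [values[p.post_sample_id] - values[p.pre_sample_id] for p in arm_design.pairs],
            dtype=float,
        )
        n = deltas.size
        if n < 3:
            raise ValueError(f"arm {arm!r} has {n} pairs; need >= 3")
        outcome = signed_rank_test(deltas)
        mean = float(deltas.mean())
        se = float(deltas.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        tcrit = float(stats.t.ppf(0.975, n - 1))
        results.append(
            ArmDeltaResult(
                arm=arm,
                n_pairs=n,
                mean_delta=mean,
                se=se,
                ci_low=mean - tcrit * se,
                ci_high=mean + tcrit * se,
                p=outcome.p,
                significant=bool(outcome.p < alpha),
            )
        )
    return results
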