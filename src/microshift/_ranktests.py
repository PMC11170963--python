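"""Wilcoxon rank-test machinery shared by the diversity and differential stages.

The signed-rank exact null distribution is computed by a convolution over
(doubled) mid-ranks, which is equivalent to full enumeration of the 2^n
sign assignments but costs O(n * sum-of-ranks). Doubling the ranks keeps
the support integral even when ties produce half-integer mid-ranks, and
zero differences are dropped before ranking (Wilcoxon's treatment). Above
``EXACT_MAX_N`` pairs the tie-corrected normal approximation with a
continuity correction is used instead.

Effect sizes follow the r = Z / sqrt(N) convention, with Z taken from the
(uncorrected) normal approximation so that its sign tracks the direction
of the shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

EXACT_MAX_N = 25


@dataclass(frozen=True)
class RankTestOutcome:
    statistic: float  # W+ (signed-rank) or U of the first group (rank-sum)
    z: float          # signed, no continuity correction; feeds r = z/sqrt(N)
    p: float          # two-sided
    n: int            # pairs used (signed-rank) or n1+n2 (rank-sum)
    method: str       # "exact" | "approx" | "degenerate"

    @property
    def effect_size(self) -> float:
        if self.n == 0:
            return 0.0
        return float(self.z / np.sqrt(self.n))


def _signed_rank_exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ by convolution over doubled mid-ranks.

    The null distribution of W+ is symmetric about M/2 (M = sum of ranks)
    for any tie pattern, so the two-sided p is P(|W - M/2| >= |w - M/2|).
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = 2 * w_plus
    dev = abs(w2 - total / 2)
    support = np.arange(total + 1)
    # tolerance guards float mid-rank doubling round-off
    p = counts[np.abs(support - total / 2) >= dev - 1e-9].sum()
    return float(min(1.0, p))


def signed_rank_test(deltas: np.ndarray) -> RankTestOutcome:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties receive mid-ranks. Exact p for
    n <= 25 effective pairs, tie-corrected continuity-corrected normal
    approximation above. All-zero differences give p = 1, z = 0.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 1:
        raise ValueError("deltas must be 1-D")
    nonzero = deltas[deltas != 0]
    n = nonzero.size
    if n == 0:
        return RankTestOutcome(statistic=0.0, z=0.0, p=1.0, n=0, method="degenerate")
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie correction: sum over tie groups of (t^3 - t) / 48
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = np.sqrt(var) if var > 0 else 0.0
    z = (w_plus - mean) / sd if sd > 0 else 0.0
    if n <= EXACT_MAX_N:
        p = _signed_rank_exact_two_sided(ranks, w_plus)
        method = "exact"
    else:
        # continuity correction toward the mean
        num = w_plus - mean
        num_cc = np.sign(num) * max(0.0, abs(num) - 0.5)
        p = 2 * stats.norm.sf(abs(num_cc / sd)) if sd > 0 else 1.0
        p = float(min(1.0, p))
        method = "approx"
    return RankTestOutcome(statistic=w_plus, z=float(z), p=float(p), n=n, method=method)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> RankTestOutcome:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two groups.

    Exact p when there are no ties and both groups have <= 25 values,
    asymptotic with continuity correction otherwise; z is the signed
    tie-corrected normal deviate of U (positive when x tends larger).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankTestOutcome(statistic=n1 * n2 / 2.0, z=0.0, p=1.0, n=n1 + n2, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(n1, n2) <= EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    mean = n1 * n2 / 2.0
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(ranks, return_counts=True)
    n = n1 + n2
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sd = np.sqrt(var) if var > 0 else 0.0
    z = (u1 - mean) / sd if sd > 0 else 0.0
    return RankTestOutcome(statistic=u1, z=float(z), p=float(res.pvalue), n=n,
                           method="exact" if method == "exact" else "approx")
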