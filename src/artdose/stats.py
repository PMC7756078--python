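"""Exact Wilcoxon signed-rank test for small paired samples.

Cohort comparisons here involve n = 10 patients, where the exact null
distribution of the signed-rank statistic is cheap: zero differences are
dropped, tied |differences| receive mid-ranks, and the distribution of the
positive-rank sum W+ over all 2^n equally likely sign assignments is built
by dynamic programming (mid-ranks doubled to integers).  Above n = 25 the
normal approximation with tie correction takes over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank"]

_EXACT_LIMIT = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    pvalue: float  # two-sided
    n_used: int  # pairs remaining after dropping zero differences

    def __iter__(self):  # allow tuple unpacking (stat, p)
        return iter((self.statistic, self.pvalue))


def _exact_two_sided_p(double_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """P-value from the exact W+ distribution via DP convolution.

    ``double_ranks`` are 2×(mid-ranks), integers; each rank enters W+ with
    probability 1/2.  Two-sided p = min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w))).
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w_plus_doubled + 1].sum()
    p_ge = counts[w_plus_doubled:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Pass differences directly, or two paired arrays.  Returns the positive
    rank sum W+ and the exact two-sided p (n ≤ 25), handling ties by
    mid-ranks and dropping zero differences.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("no nonzero pairs: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= _EXACT_LIMIT:
        double_ranks = np.rint(2.0 * ranks).astype(int)
        w2 = int(np.rint(2.0 * w_plus))
        p = _exact_two_sided_p(double_ranks, w2)
    else:
        # normal approximation with tie correction
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n)
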