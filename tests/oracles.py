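"""Independent brute-force oracles used to cross-check the metric stack.

Everything here is deliberately naive (explicit loops, repeated-max
selection, extended precision) so that it shares no code path with the
implementations it checks.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def dose_at_volume_bruteforce(doses, x: float) -> float:
    """k-th hottest dose via heapq selection, k = ceil(x·N/100)."""
    ds = [float(v) for v in np.ravel(doses)]
    k = math.ceil(x / 100.0 * len(ds))
    k = max(k, 1)
    return heapq.nlargest(k, ds)[-1]


def volume_at_dose_bruteforce(doses, d: float) -> float:
    ds = [float(v) for v in np.ravel(doses)]
    count = 0
    for v in ds:
        if v >= d:
            count += 1
    return 100.0 * count / len(ds)


def geud_bruteforce(doses, a: float) -> float:
    """Power mean in 80-bit extended precision, explicit accumulation."""
    ds = np.ravel(doses).astype(np.longdouble)
    acc = np.longdouble(0.0)
    for v in ds:
        acc += v ** np.longdouble(a)
    return float((acc / len(ds)) ** (np.longdouble(1.0) / np.longdouble(a)))


def conformity_index_bruteforce(ptv_values, dose_values, piv_dose) -> float:
    """Voxel-by-voxel set counting."""
    n_ptv = n_piv = n_both = 0
    for p, d in zip(np.ravel(ptv_values), np.ravel(dose_values)):
        inside_piv = d >= piv_dose
        if p:
            n_ptv += 1
        if inside_piv:
            n_piv += 1
        if p and inside_piv:
            n_both += 1
    if n_piv == 0:
        return 0.0
    return n_both**2 / (n_ptv * n_piv)


def margin_expand_bruteforce(values, spacing, margin_mm):
    """O(N·M) enumeration: output voxel iff within margin of an input voxel."""
    values = np.asarray(values, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    src = np.argwhere(values)
    out = np.zeros_like(values)
    for idx in np.ndindex(values.shape):
        d2 = ((np.asarray(idx) - src) * sp) ** 2
        if np.any(d2.sum(axis=1) <= margin_mm**2 + 1e-9):
            out[idx] = True
    return out


def wilcoxon_enumeration(diffs) -> tuple[float, float]:
    """Exact two-sided p by full 2^n sign enumeration (mid-ranks, drop zeros)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero pairs")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for bits in range(2**n):
        signs = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        ws.append(ranks[signs].sum())
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(w_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))
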