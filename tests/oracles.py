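"""Independent reference implementations used only as test oracles.

Each function here is deliberately naive (per-base boolean arrays,
exhaustive enumeration, double loops) so that it shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, List, Sequence, Tuple

import numpy as np


def perbase_cover(intervals: Iterable[Tuple[int, int]], length: int) -> np.ndarray:
    """Boolean per-base occupancy array for intervals on one toy chromosome."""
    arr = np.zeros(length, dtype=bool)
    for s, e in intervals:
        arr[s:e] = True
    return arr


def perbase_merge(intervals: Iterable[Tuple[int, int]],
                  length: int) -> List[Tuple[int, int]]:
    """Merged intervals recovered by scanning the per-base boolean array."""
    arr = perbase_cover(intervals, length)
    padded = np.concatenate([[False], arr, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def perbase_overlap(a: Iterable[Tuple[int, int]], b: Iterable[Tuple[int, int]],
                    length: int) -> int:
    return int((perbase_cover(a, length) & perbase_cover(b, length)).sum())


def poisson_upper_tail(k: int, lam: float, terms: int = 500) -> float:
    """P(X >= k) by direct series summation of the Poisson pmf."""
    pmf = np.exp(-lam)
    total_below = 0.0
    for i in range(k):
        total_below += pmf
        pmf *= lam / (i + 1)
    return 1.0 - total_below


def brute_force_islands(counts: Sequence[int], l0: int,
                        gap_windows: int) -> List[Tuple[int, int]]:
    """Island (first, last eligible window) pairs by explicit scanning."""
    eligible = [i for i, c in enumerate(counts) if c >= l0]
    runs: List[Tuple[int, int]] = []
    for i in eligible:
        if runs and i - runs[-1][1] - 1 <= gap_windows:
            runs[-1] = (runs[-1][0], i)
        else:
            runs.append((i, i))
    return runs


def bh_by_hand(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up computed from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def ranksum_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = _midranks(pooled)
    observed = sum(ranks[:n1])
    sums = [sum(ranks[i] for i in combo)
            for combo in combinations(range(len(pooled)), n1)]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-9)
    return extreme / len(sums)


def _midranks(values: Sequence[float]) -> List[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman_by_definition(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank transform (mid-ranks) then Pearson correlation."""
    rx = np.array(_midranks(list(x)))
    ry = np.array(_midranks(list(y)))
    return float(np.corrcoef(rx, ry)[0, 1])


def tmm_naive(counts: np.ndarray, trim_m: float = 0.30,
              trim_a: float = 0.05) -> np.ndarray:
    """Straightforward double-loop TMM implementation (genes x samples)."""
    lib = counts.sum(axis=0).astype(float)
    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                    for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                fo, fr = o / lib[j], r / lib[ref]
                m_vals.append(np.log2(fo / fr))
                a_vals.append(0.5 * np.log2(fo * fr))
                w_vals.append(1.0 / ((lib[j] - o) / (lib[j] * o)
                                     + (lib[ref] - r) / (lib[ref] * r)))
        m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
        n = len(m_vals)
        lo_m = np.floor(n * trim_m / 2) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a / 2) + 1
        hi_a = n + 1 - lo_a
        rm = _midranks(m_vals.tolist())
        ra = _midranks(a_vals.tolist())
        keep = [(lo_m <= rm[i] <= hi_m) and (lo_a <= ra[i] <= hi_a)
                for i in range(n)]
        keep = np.array(keep)
        f = 2 ** (np.sum(w_vals[keep] * m_vals[keep]) / np.sum(w_vals[keep]))
        factors.append(float(f))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def welch_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Welch's t statistic and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t_stat = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t_stat), df)
    return float(t_stat), float(p)
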