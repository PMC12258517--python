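"""Independent brute-force / closed-form reference implementations.

These never call the library paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bh_reference(p_values) -> np.ndarray:
    """BH step-up straight from the definition, quadratic and explicit."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    out = np.empty(m)
    order = np.argsort(p, kind="stable")
    for pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(pos, m + 1)
        ]  # all j >= i in sorted order
        out[idx] = min(1.0, min(candidates))
    return out


def hypergeom_sf_enumeration(k: int, m: int, n_a: int, n_b: int) -> float:
    """P(overlap >= k) by enumerating every size-n_b draw from an m-universe."""
    marked = set(range(n_a))
    hits = total = 0
    for draw in combinations(range(m), n_b):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def signed_rank_exact_p(diffs) -> float:
    """Two-sided one-sample signed-rank p by enumerating all 2^n sign flips.

    Zero differences dropped; average ranks for tied magnitudes.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    absd = np.abs(d)
    # average ranks of magnitudes
    order = np.argsort(absd)
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    count = 0
    for mask in range(2**n):
        w = sum(ranks[b] for b in range(n) if (mask >> b) & 1)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return min(1.0, count / 2**n)


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Yates-corrected Pearson statistic for [[a, b], [c, d]]."""
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    stat = 0.0
    for obs, r, cc in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        exp = r * cc / n
        stat += (abs(obs - exp) - 0.5) ** 2 / exp
    return stat


def pearson_chi2(table) -> float:
    """Textbook sum of (O - E)^2 / E, no correction."""
    arr = np.asarray(table, dtype=float)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    return float(((arr - expected) ** 2 / expected).sum())


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score interval from the closed form."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def hazen_ranks(values) -> np.ndarray:
    """(rank - 0.5)/N with average ranks for ties, by explicit counting."""
    x = np.asarray(values, dtype=float)
    n = x.size
    out = np.empty(n)
    for i, v in enumerate(x):
        below = np.sum(x < v)
        equal = np.sum(x == v)
        avg_rank = below + (equal + 1) / 2
        out[i] = (avg_rank - 0.5) / n
    return out


def spearman_reference(x, y) -> float:
    """Pearson correlation of hand-computed average ranks."""
    rx = hazen_ranks(x)  # affine in rank, so correlation is unchanged
    ry = hazen_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
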