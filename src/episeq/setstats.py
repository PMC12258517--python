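"""Gene-set overlap enrichment and multiple-testing correction.

The overlap test asks: drawing ``|B|`` genes from a universe of ``M`` genes
of which ``|A|`` are marked, how probable is an intersection at least as
large as the one observed?  That upper-tail hypergeometric probability is
computed through the survival function evaluated at ``k - 1`` — the form
that avoids the off-by-one the ">= k" formulation invites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Counts and upper-tail p for one set-overlap test."""

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_raw: float
    p_adj: float | None = None
    fold_enrichment: float = float("nan")

    @property
    def expected_overlap(self) -> float:
        return self.n_a * self.n_b / self.n_universe


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-tailed (upper) hypergeometric overlap test of two gene sets.

    Members outside the universe are dropped with a logged count.  The
    p-value is ``P(X >= k)`` for ``X ~ Hypergeom(M, |A|, |B|)``, computed as
    ``sf(k - 1)``.
    """
    uni = set(universe)
    if not uni:
        raise ParameterError("empty universe")
    a, b = set(set_a), set(set_b)
    dropped = len(a - uni) + len(b - uni)
    if dropped:
        logger.info("hypergeom_overlap: dropped %d members outside universe", dropped)
    a &= uni
    b &= uni
    k = len(a & b)
    m, n_a, n_b = len(uni), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, m, n_a, n_b))
    expected = n_a * n_b / m
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(m, n_a, n_b, k, min(p, 1.0), None, fold)


def overlap_batch(
    pairs: Sequence[tuple[Iterable[str], Iterable[str]]], universe: Iterable[str]
) -> list[OverlapResult]:
    """Run several overlap tests as one BH family (one analysis batch)."""
    uni = set(universe)
    results = [hypergeom_overlap(a, b, uni) for a, b in pairs]
    padj = adjust_bh([r.p_raw for r in results])
    return [
        OverlapResult(r.n_universe, r.n_a, r.n_b, r.n_overlap, r.p_raw, q, r.fold_enrichment)
        for r, q in zip(results, padj)
    ]


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN) pass through as NaN and do not count toward the
    family size m.  q_i = min_{j >= i} (m * p_(j) / j), capped at 1, mapped
    back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ParameterError("p-values outside [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    out[ok] = adj
    return out


def set_fraction(
    target_set: Iterable[str], annotation_set: Iterable[str]
) -> tuple[float, int, int]:
    """Fraction of ``target_set`` members carrying the annotation.

    Returns ``(fraction, n_target, n_overlap)``.
    """
    target = set(target_set)
    if not target:
        raise ParameterError("empty target set")
    k = len(target & set(annotation_set))
    return k / len(target), len(target), k
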