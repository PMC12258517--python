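"""Cell-cycle-phase percentile-rank enrichment.

Each gene's log2 fold change (WT/KO) is converted to a percentile rank over
all expressed genes, and each phase set's ranks are compared against the
all-gene anchor of 0.5 with a two-sided one-sample Wilcoxon signed-rank test,
BH-corrected across the phases tested in one call.  A phase whose median rank
sits above 0.5 contains genes the perturbed factor downregulates (WT/KO
orientation), i.e. the factor normally promotes that phase's program.

Percentile definition: Hazen, r_i = (rank_i - 0.5) / N with average ranks for
ties, chosen because it makes the all-gene median exactly 0.5 — the anchor
the test is built around.  Percent-rank ((rank - 1)/(N - 1)) is available
behind the ``method`` switch for comparison with other codebases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError
from .setstats import adjust_bh
from .tables import DETable, GeneSetCollection

#: canonical display order when phase labels match the standard five
CANONICAL_PHASE_ORDER = ("G1/S", "S", "G2", "M", "M/G1")

#: exact signed-rank distribution is used up to this many nonzero differences
EXACT_MAX_N = 25


@dataclass(frozen=True)
class PhaseEnrichmentResult:
    """Per-phase rank summary and signed-rank test."""

    phase: str
    n_genes_tested: int
    median_rank: float
    iqr: tuple[float, float]
    p_raw: float  # NaN when untestable (< 2 usable members)
    p_adj: float

    @property
    def testable(self) -> bool:
        return not np.isnan(self.p_raw)


def percentile_rank(values, method: str = "hazen") -> np.ndarray:
    """Percentile ranks in (0, 1), order-preserving, average ranks for ties.

    ``hazen``: (rank - 0.5) / N.  ``percentrank``: (rank - 1) / (N - 1),
    which pins the extremes to 0 and 1 (degenerate to 0.5 for N = 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ParameterError("percentile_rank: empty vector")
    if not np.isfinite(x).all():
        raise ParameterError("percentile_rank: non-finite values")
    ranks = stats.rankdata(x, method="average")
    if method == "hazen":
        return (ranks - 0.5) / x.size
    if method == "percentrank":
        if x.size == 1:
            return np.array([0.5])
        return (ranks - 1.0) / (x.size - 1.0)
    raise ParameterError(f"unknown percentile method {method!r}")


def signed_rank_test(diffs: np.ndarray) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value.

    Zero differences are dropped (classical convention).  Exact distribution
    for n <= EXACT_MAX_N nonzero differences without tied magnitudes; normal
    approximation with tie and continuity correction otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n < 1:
        return 1.0
    absd = np.abs(d)
    has_ties = np.unique(absd).size < n
    if n <= EXACT_MAX_N and not has_ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(min(res.pvalue, 1.0))


def phase_enrichment(
    table: DETable,
    phases: GeneSetCollection,
    anchor: float = 0.5,
    method: str = "hazen",
) -> list[PhaseEnrichmentResult]:
    """Percentile-rank enrichment of each phase set in a DE table.

    Ranks are computed over ALL genes in the table with a finite log2fc (the
    expressed universe), not just phase members.  Each phase is then tested
    against ``anchor`` and BH correction is applied across the phases tested
    in this call (one family per dataset/panel).  Phases with fewer than two
    usable members are reported with missing p-values rather than dropped.

    Results follow the canonical phase order (G1/S, S, G2, M, M/G1) when the
    collection's labels match it, else the collection's own order.
    """
    usable = table.usable()
    if usable.empty:
        raise ParameterError("DE table has no usable log2fc values")
    ranks = percentile_rank(usable["log2fc"].to_numpy(), method=method)
    rank_by_gene = dict(zip(usable["gene"], ranks))

    names = phases.names()
    if set(names) <= set(CANONICAL_PHASE_ORDER):
        names = [n for n in CANONICAL_PHASE_ORDER if n in names]

    rows: list[tuple[str, int, float, tuple[float, float], float]] = []
    any_overlap = False
    for name in names:
        member_ranks = np.array(
            [rank_by_gene[g] for g in phases[name] if g in rank_by_gene]
        )
        n = member_ranks.size
        if n == 0:
            rows.append((name, 0, float("nan"), (float("nan"), float("nan")), float("nan")))
            continue
        any_overlap = True
        q1, med, q3 = np.percentile(member_ranks, [25, 50, 75])
        if n < 2:
            p = float("nan")  # untestable, flagged not dropped
        else:
            p = signed_rank_test(member_ranks - anchor)
        rows.append((name, n, float(med), (float(q1), float(q3)), p))

    if not any_overlap:
        raise ParameterError("no phase set intersects the table's genes")

    p_adj = adjust_bh([r[4] for r in rows])
    return [
        PhaseEnrichmentResult(name, n, med, iqr, p, float(q))
        for (name, n, med, iqr, p), q in zip(rows, p_adj)
    ]
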