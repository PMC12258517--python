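"""Statistics for EdU proliferation counts.

The fraction of EdU-positive cells per genotype measures S-phase entry within
the labeling window.  Genotypes are compared with a chi-squared test of
homogeneity on the genotype x {EdU+, EdU-} table, followed by post-hoc
pairwise 2x2 chi-squared tests with Benjamini-Hochberg correction.  Per-group
95% CIs on the EdU+ proportion use the Wilson score interval, which stays
inside [0, 1] and behaves at observed proportions of 0% and 100% (Wald is
available behind the ``method`` switch).

Continuity (Yates) correction is applied to 2x2 tables only, never to larger
ones — the convention of R's chisq.test, so p-values line up with pipelines
built on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, DegenerateTableError, ParameterError
from .setstats import adjust_bh


@dataclass(frozen=True)
class EdUCountTable:
    """Genotype x EdU-status counts."""

    groups: tuple[str, ...]
    edu_pos: tuple[int, ...]
    edu_neg: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise DataError("EdU count table needs at least 2 groups")
        if not (len(self.groups) == len(self.edu_pos) == len(self.edu_neg)):
            raise DataError("EdU count table columns have unequal lengths")
        if len(set(self.groups)) != len(self.groups):
            raise DataError("duplicate group labels")
        for k, n in zip(self.edu_pos, self.edu_neg):
            if k < 0 or n < 0:
                raise DataError("negative counts")
            if k + n < 1:
                raise DataError("each group needs a total of at least 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EdUCountTable":
        df = pd.read_csv(path)
        for col in ("group", "edu_pos", "edu_neg"):
            if col not in df.columns:
                raise DataError(f"EdU counts CSV missing column {col!r}")
        return cls(
            tuple(df["group"].astype(str)),
            tuple(int(v) for v in df["edu_pos"]),
            tuple(int(v) for v in df["edu_neg"]),
        )

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.edu_pos, self.edu_neg])

    def totals(self) -> np.ndarray:
        return self.to_array().sum(axis=1)

    def proportions(self) -> np.ndarray:
        return np.asarray(self.edu_pos) / self.totals()


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adj: float
    degenerate: bool = False


def chisq_homogeneity(table: EdUCountTable) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity; (statistic, df, p).

    Yates continuity correction for 2x2 tables only.
    """
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    correction = arr.shape[0] == 2
    stat, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), int(df), float(p)


def posthoc_pairwise(table: EdUCountTable) -> list[PairwiseResult]:
    """All unordered group pairs as Yates-corrected 2x2 tests, BH-adjusted.

    A degenerate pair (zero EdU+ or EdU- margin across both groups) is
    flagged and excluded from the BH family; the others are still reported.
    """
    raw: list[tuple[str, str, float, float, bool]] = []
    for i, j in combinations(range(len(table.groups)), 2):
        sub = EdUCountTable(
            (table.groups[i], table.groups[j]),
            (table.edu_pos[i], table.edu_pos[j]),
            (table.edu_neg[i], table.edu_neg[j]),
        )
        try:
            stat, _, p = chisq_homogeneity(sub)
            raw.append((sub.groups[0], sub.groups[1], stat, p, False))
        except DegenerateTableError:
            raw.append((sub.groups[0], sub.groups[1], float("nan"), float("nan"), True))
    p_adj = adjust_bh([r[3] for r in raw])
    return [
        PairwiseResult(a, b, s, p, float(q), deg)
        for (a, b, s, p, deg), q in zip(raw, p_adj)
    ]


def proportion_ci(
    edu_pos: int, total: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion (Wilson score default)."""
    if not 0 < level < 1:
        raise ParameterError(f"level must be in (0, 1), got {level}")
    if total < 1 or not 0 <= edu_pos <= total:
        raise ParameterError(
            f"need 0 <= edu_pos <= total with total >= 1, got {edu_pos}/{total}"
        )
    if method not in ("wilson", "wald"):
        raise ParameterError(f"unknown CI method {method!r}")
    method_name = "wilson" if method == "wilson" else "normal"
    lo, hi = proportion_confint(edu_pos, total, alpha=1 - level, method=method_name)
    return float(lo), float(hi)
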