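"""Cross-dataset fold-change concordance and attenuation-slope modeling.

Given two perturbation DE tables merged by gene, three questions are asked
about a selected (dependent) gene set:

1. How concordant are the two datasets' fold changes on that set?
   Spearman rho, with significance calibrated against an empirical null of
   equally sized gene sets sampled from all merged genes — each draw without
   replacement within itself, independent across draws.  The observed rho is
   converted to a Z-score against the null mean/SD and to a one-sided
   upper-tail normal probability reported on the natural-log scale (never
   exponentiated internally, so |Z| > 8 does not underflow).
2. How strongly attenuated is one perturbation's effect relative to the
   other?  OLS of the response dataset's log2fc on the predictor dataset's
   log2fc over the selected genes; a slope in (0, 1) means the response
   perturbation retains a fraction of the predictor perturbation's program.
   The 95% CI uses the t distribution with n - 2 df.  Note that with noise
   on the predictor, OLS estimates the slope times the predictor reliability
   ratio; no errors-in-variables correction is applied because plain OLS is
   the estimand here.
3. Are the two datasets' fold changes on a small group statistically
   similar?  Paired two-sided Wilcoxon signed-rank on the per-gene
   differences (a paired t-test is available behind ``method``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateNullError,
    InsufficientDataError,
    ParameterError,
    SingularFitError,
)
from .tables import MergedTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceResult:
    n_selected: int
    rho: float
    null_mean: float
    null_sd: float
    n_null_draws: int
    z_score: float
    log_p_one_sided: float  # natural log of the upper-tail normal probability
    seed: int


@dataclass(frozen=True)
class AttenuationFit:
    beta0: float
    beta_upstream: float
    ci95: tuple[float, float]
    n: int
    r_squared: float


@dataclass(frozen=True)
class PairedComparisonResult:
    n: int
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    all_zero: bool


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation; incomplete pairs are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("spearman_rho: unequal lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"spearman_rho: only {int(ok.sum())} complete pairs (need >= 3)"
        )
    rho, _ = stats.spearmanr(x[ok], y[ok])
    return float(rho)


def _complete_pairs(merged: MergedTable) -> pd.DataFrame:
    df = merged.data
    a = df[f"log2fc_{merged.label_a}"].to_numpy(dtype=float)
    b = df[f"log2fc_{merged.label_b}"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    return pd.DataFrame({"gene": df["gene"][ok], "a": a[ok], "b": b[ok]}).reset_index(
        drop=True
    )


def _null_rhos(
    a: np.ndarray,
    b: np.ndarray,
    k: int,
    n_iter: int,
    rng: np.random.Generator,
    chunk: int = 10_000,
) -> np.ndarray:
    """Spearman rho for ``n_iter`` random k-subsets of the gene universe.

    Vectorized: per chunk, a uniform matrix is argpartitioned to draw each
    row's k indices without replacement, subsets are average-ranked along
    the row axis and correlated via the Pearson formula.
    """
    n = a.size
    out = np.empty(n_iter)
    done = 0
    while done < n_iter:
        c = min(chunk, n_iter - done)
        u = rng.random((c, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        ra = stats.rankdata(a[idx], axis=1)
        rb = stats.rankdata(b[idx], axis=1)
        ra = ra - ra.mean(axis=1, keepdims=True)
        rb = rb - rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            out[done : done + c] = (ra * rb).sum(axis=1) / denom
        done += c
    return out


def bootstrap_null_concordance(
    merged: MergedTable,
    selected: Iterable[str],
    n_iter: int = 100_000,
    seed: int = 0,
) -> ConcordanceResult:
    """Spearman concordance of a gene set against a random-gene-set null.

    ``selected`` must be a subset of the merged genes with at least 3
    complete fold-change pairs.  Null draws sample ``|selected|`` genes from
    all merged genes (the selected set is not excluded from the pool).
    """
    if n_iter < 100:
        raise ParameterError(f"n_iter must be >= 100, got {n_iter}")
    pairs = _complete_pairs(merged)
    sel = set(selected)
    extra = sel - set(merged.genes)
    if extra:
        raise ParameterError(
            f"selected contains {len(extra)} genes absent from the merged table"
        )
    mask = pairs["gene"].isin(sel).to_numpy()
    k = int(mask.sum())
    if k < 3:
        raise InsufficientDataError(
            f"selected set has only {k} complete pairs (need >= 3)"
        )
    a = pairs["a"].to_numpy()
    b = pairs["b"].to_numpy()
    rho = spearman_rho(a[mask], b[mask])
    if k >= a.size:
        raise DegenerateNullError(
            "selected set equals the merged universe; the null has zero spread"
        )
    rng = np.random.default_rng(seed)
    null = _null_rhos(a, b, k, n_iter, rng)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        raise DegenerateNullError("bootstrap null has zero standard deviation")
    z = (rho - null_mean) / null_sd
    log_p = float(stats.norm.logsf(z))
    return ConcordanceResult(k, rho, null_mean, null_sd, n_iter, float(z), log_p, seed)


def attenuation_fit(
    merged: MergedTable,
    selected: Iterable[str],
    response: str,
    predictor: str,
) -> AttenuationFit:
    """OLS of response-dataset log2fc on predictor-dataset log2fc.

    Fit over the selected (dependent) genes only; 95% CI on the slope from
    the t distribution with n - 2 degrees of freedom.
    """
    import statsmodels.api as sm

    if response == predictor:
        raise ParameterError("response and predictor labels must differ")
    df = merged.data.set_index("gene")
    sel = [g for g in set(selected) if g in df.index]
    y = df.loc[sel, f"log2fc_{response}"].to_numpy(dtype=float)
    x = df.loc[sel, f"log2fc_{predictor}"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"attenuation_fit: {n} complete pairs (need >= 3)")
    if np.ptp(x) == 0.0:
        raise SingularFitError("attenuation_fit: zero predictor variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return AttenuationFit(
        beta0=float(model.params[0]),
        beta_upstream=float(model.params[1]),
        ci95=(float(lo), float(hi)),
        n=n,
        r_squared=float(model.rsquared),
    )


def paired_group_comparison(
    merged: MergedTable, group: Iterable[str], method: str = "wilcoxon"
) -> PairedComparisonResult:
    """Two-sided paired test of the two datasets' fold changes on a group.

    Default is the paired Wilcoxon signed-rank test on per-gene differences;
    ``method='ttest'`` switches to a paired t-test.  If every difference is
    zero the result is p = 1 with the ``all_zero`` flag set.
    """
    if method not in ("wilcoxon", "ttest"):
        raise ParameterError(f"unknown method {method!r}")
    pairs = _complete_pairs(merged)
    mask = pairs["gene"].isin(set(group)).to_numpy()
    a = pairs["a"].to_numpy()[mask]
    b = pairs["b"].to_numpy()[mask]
    n = a.size
    if n < 5:
        raise InsufficientDataError(
            f"paired_group_comparison: {n} complete pairs (need >= 5)"
        )
    d = a - b
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if np.all(d == 0.0):
        return PairedComparisonResult(n, 0.0, 1.0, med_a, med_b, True)
    if method == "wilcoxon":
        nz = d[d != 0.0]  # classical zero-drop convention
        exact = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
        res = stats.wilcoxon(
            nz,
            alternative="two-sided",
            method="exact" if exact else "approx",
            correction=not exact,
        )
    else:
        res = stats.ttest_rel(a, b)
    return PairedComparisonResult(
        n, float(res.statistic), float(min(res.pvalue, 1.0)), med_a, med_b, False
    )
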