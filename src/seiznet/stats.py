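"""Statistical toolbox: t-tests, normality gate, Holm–Bonferroni,
effect sizes.

Group comparisons use two-tailed Student t-tests (pooled variance by
default, Welch as an option) with Cohen's d on the pooled SD and a 95%
CI of the mean difference. Parametric testing is gated on the
D'Agostino–Pearson omnibus normality test at p > 0.05, and families of
comparisons are corrected with the Holm step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "two_sample_t",
    "paired_t",
    "cohens_d",
    "dagostino_pearson",
    "holm_bonferroni",
]


@dataclass
class StatResult:
    """Outcome of a t-test comparison."""

    t: float
    df: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    cohen_d: float
    kind: str  # "two-sample-pooled" | "two-sample-welch" | "paired"
    degenerate: bool = False  # zero-variance corner cases


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the classic pooled SD (ddof=1 per group)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def two_sample_t(x, y, kind: str = "pooled") -> StatResult:
    """Two-tailed two-sample t-test with effect size and difference CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if kind not in ("pooled", "welch"):
        raise ValueError("kind must be 'pooled' or 'welch'")
    equal_var = kind == "pooled"
    diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = x.size + y.size - 2
        if diff == 0:
            return StatResult(0.0, df, 1.0, 0.0, 0.0, 0.0, 0.0,
                              f"two-sample-{'pooled' if equal_var else 'welch'}",
                              degenerate=True)
        t = np.inf if diff > 0 else -np.inf
        return StatResult(t, df, 0.0, diff, diff, diff, cohens_d(x, y),
                          f"two-sample-{'pooled' if equal_var else 'welch'}",
                          degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return StatResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_diff=diff,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        cohen_d=cohens_d(x, y),
        kind=f"two-sample-{'pooled' if equal_var else 'welch'}",
    )


def paired_t(x, y) -> StatResult:
    """Paired t-test: one-sample t on the differences, df = n − 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    n = d.size
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return StatResult(0.0, n - 1, 1.0, 0.0, 0.0, 0.0, 0.0, "paired",
                              degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return StatResult(t, n - 1, 0.0, float(d.mean()), float(d.mean()),
                          float(d.mean()), np.inf * np.sign(d.mean()), "paired",
                          degenerate=True)
    res = sps.ttest_rel(x, y)
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    dz = float(d.mean() / d.std(ddof=1))
    return StatResult(
        t=float(res.statistic),
        df=float(n - 1),
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
        ci_low=float(d.mean() - tcrit * se),
        ci_high=float(d.mean() + tcrit * se),
        cohen_d=dz,
        kind="paired",
    )


def dagostino_pearson(x) -> float:
    """D'Agostino–Pearson omnibus K² normality test; returns the p-value.

    The omnibus statistic combines the skewness and kurtosis z-scores;
    it is unreliable below n = 8, which is rejected.
    """
    x = np.asarray(x, float)
    if x.size < 8:
        raise ValueError("D'Agostino-Pearson requires n >= 8")
    return float(sps.normaltest(x).pvalue)


def holm_bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down multiple-comparison correction.

    Returns ``(reject, p_adjusted)`` aligned with the input order.
    Sorted ascending, p(i) is compared against alpha/(m − i + 1) and
    the procedure stops at the first failure; adjusted p-values are the
    monotone cumulative maxima of the step-down scaling.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject, p_adj
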