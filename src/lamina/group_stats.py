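"""Shared statistical tests used across the toolkit.

Thin, defensively-checked wrappers around :mod:`scipy.stats` exposing the
tests the downstream analyses need: Student's t (paired/unpaired), one-way
ANOVA with Tukey's HSD, the Mann-Whitney U / Wilcoxon rank-sum test (exact
by enumeration for small tie-free samples), and Pearson correlation.

Degenerate inputs (zero variance, empty samples) are resolved here with
explicit flags instead of propagating NaNs out of scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["TestResult", "ttest", "anova_tukey", "mann_whitney", "wilcoxon_rank_sum", "pearson"]

#: total sample size at or below which the Mann-Whitney p-value is exact
EXACT_MW_LIMIT = 16


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (t, F, or U depending on ``method``).
    pvalue : float
        Two-sided p-value in [0, 1].
    method : str
        Human-readable name of the test performed.
    df : float or None
        Degrees of freedom where the test has them.
    exact : bool
        True only when the p-value was computed by exact enumeration.
    degenerate : bool
        Set when the inputs were degenerate (e.g. zero variance with
        unequal means) and the reported p-value is a convention.
    pairwise : dict
        Tukey-adjusted p-values per group pair (ANOVA only), keyed by
        ``(i, j)`` group indices.
    """

    statistic: float
    pvalue: float
    method: str
    df: float | None = None
    exact: bool = False
    degenerate: bool = False
    pairwise: dict = field(default_factory=dict)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ttest(x, y, paired: bool = False, welch: bool = False) -> TestResult:
    """Two-tailed Student's t-test.

    Unpaired uses the pooled-variance form by default (``welch=True``
    switches to Welch's unequal-variance form); paired is the one-sample
    t on within-pair differences.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if paired:
        if x.size != y.size:
            raise ValueError("paired t-test requires equal sample sizes")
        if x.size < 2:
            raise ValueError("paired t-test requires n >= 2")
        d = x - y
        if np.std(d, ddof=1) == 0:
            # constant difference: direction is certain, p undefined
            equal = np.allclose(d, 0)
            return TestResult(
                statistic=0.0 if equal else np.inf * np.sign(d[0]),
                pvalue=1.0 if equal else 0.0,
                method="paired t-test",
                df=x.size - 1,
                degenerate=not equal,
            )
        t, p = stats.ttest_rel(x, y)
        return TestResult(float(t), float(p), "paired t-test", df=x.size - 1)

    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired t-test requires n >= 2 per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return TestResult(0.0, 1.0, "unpaired t-test", df=x.size + y.size - 2)
        sign = np.sign(x.mean() - y.mean())
        return TestResult(
            float(sign * np.inf), 0.0, "unpaired t-test",
            df=x.size + y.size - 2, degenerate=True,
        )
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    df = x.size + y.size - 2 if not welch else None
    name = "Welch t-test" if welch else "unpaired t-test"
    return TestResult(float(t), float(p), name, df=df)


def anova_tukey(groups) -> TestResult:
    """One-way ANOVA followed by Tukey's HSD multiple-comparison test.

    ``pairwise`` on the result maps ``(i, j)`` group-index pairs to
    Tukey-adjusted p-values (studentized-range distribution).
    """
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("ANOVA requires at least two groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    k = len(arrs)
    n_total = sum(g.size for g in arrs)
    if all(np.var(g, ddof=1) == 0 for g in arrs) and all(
        np.isclose(g.mean(), arrs[0].mean()) for g in arrs
    ):
        pairwise = {(i, j): 1.0 for i in range(k) for j in range(i + 1, k)}
        return TestResult(0.0, 1.0, "one-way ANOVA + Tukey HSD",
                          df=(k - 1, n_total - k), pairwise=pairwise)
    f, p = stats.f_oneway(*arrs)
    hsd = stats.tukey_hsd(*arrs)
    pairwise = {
        (i, j): float(hsd.pvalue[i, j]) for i in range(k) for j in range(i + 1, k)
    }
    return TestResult(float(f), float(p), "one-way ANOVA + Tukey HSD",
                      df=(k - 1, n_total - k), pairwise=pairwise)


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U test (a.k.a. the Wilcoxon rank-sum test).

    The two-sided p-value is exact (2 x the smaller tail probability of
    the null U distribution, capped at 1) whenever the combined sample
    size is at most ``EXACT_MW_LIMIT``: via the null U distribution for
    tie-free data, and by exact conditional permutation enumeration of
    the observed values when ties are present (the normal approximation
    is unreliable at these sizes). Larger samples use the normal
    approximation with tie correction.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = pooled.size <= EXACT_MW_LIMIT
    if not use_exact:
        method = "asymptotic"
    elif has_ties:
        method = stats.PermutationMethod(n_resamples=20_000, rng=0)
    else:
        method = "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "Mann-Whitney U", exact=use_exact)


# same test, two names in common use
wilcoxon_rank_sum = mann_whitney


def pearson(x, y) -> tuple[float, int]:
    """Pearson correlation coefficient; returns ``(r, n)``."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson is undefined for constant input")
    r, _ = stats.pearsonr(x, y)
    return float(r), int(x.size)
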