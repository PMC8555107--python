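"""Statistical primitives used across the pipeline.

Two-sample pooled-variance (Student) t-test, Benjamini-Hochberg step-up
FDR adjustment (supporting adjustment of the k smallest p-values against
a larger family of m tests), tie-corrected Kruskal-Wallis, a one-sample
z-test, and power of the two-sided two-sample t-test via the noncentral
t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    q: float | None = None
    degenerate: bool = False


def student_t_two_sample(x, y) -> TestResult:
    """Pooled-variance two-sample t-test, two-sided.

    Degenerate inputs (zero pooled variance) return p = 1 when the means
    are equal and p = 0 otherwise, with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    df = n1 + n2 - 2
    diff = x.mean() - y.mean()
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    pooled_var = ss / df
    if pooled_var == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, degenerate=True)
        return TestResult(math.copysign(math.inf, diff), df, 0.0, degenerate=True)
    t = diff / math.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), df, float(min(p, 1.0)))


def t_test_rows(values: pd.DataFrame, groups: pd.Series | dict, group_a: str, group_b: str) -> pd.DataFrame:
    """Vectorized row-wise pooled t-test (``group_a`` minus ``group_b``).

    Returns a DataFrame indexed like ``values`` with ``t``, ``df``, ``p``
    columns. Zero-variance rows follow the same degenerate convention as
    :func:`student_t_two_sample`.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    a = values[groups.index[groups == group_a].intersection(values.columns)].to_numpy(dtype=float)
    b = values[groups.index[groups == group_b].intersection(values.columns)].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    zero = pooled_var == 0
    t[zero] = np.where(diff[zero] == 0, 0.0, np.sign(diff[zero]) * np.inf)
    p[zero] = np.where(diff[zero] == 0, 1.0, 0.0)
    return pd.DataFrame({"t": t, "df": df, "p": np.minimum(p, 1.0)}, index=values.index)


def bh_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    ``m`` defaults to ``len(pvals)``; passing ``m > len(pvals)`` adjusts
    the provided p-values as the ``len(pvals)`` smallest members of a
    family of ``m`` tests (the absent, larger p-values cannot lower any
    step-up minimum).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m must be >= len(pvals)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def kruskal_wallis(groups: list) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    total = np.concatenate(arrays)
    if total.size < 3:
        raise ValueError("need total N >= 3")
    df = len(arrays) - 1
    if np.all(total == total[0]):
        # All observations identical: H = 0 by convention (the tie
        # correction denominator vanishes).
        return TestResult(0.0, df, 1.0, degenerate=True)
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), df, float(p))


def one_sample_z(
    value: float, null_mean: float, null_sd: float, alternative: str = "greater"
) -> TestResult:
    """z-test of a single value against a normal null."""
    if null_sd <= 0:
        raise ValueError("null_sd must be positive")
    z = (value - null_mean) / null_sd
    if alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return TestResult(float(z), math.inf, float(min(p, 1.0)))


def power_two_group(
    n_per_group: int,
    effect_log2: float,
    sd_log2: float,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sided pooled t-test for a given log2 effect.

    A "two-fold" group difference corresponds to ``effect_log2 = 1.0``.
    Computed from the noncentral t distribution with noncentrality
    ``(effect/sd) * sqrt(n/2)`` and ``2n - 2`` degrees of freedom.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if effect_log2 < 0 or sd_log2 <= 0:
        raise ValueError("effect must be >= 0 and sd positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    nc = (effect_log2 / sd_log2) * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    return float(power)


def pooled_sd_log2(values: pd.DataFrame, groups: pd.Series | dict, group_a: str, group_b: str) -> float:
    """Median per-peptide pooled standard deviation of a log2 matrix.

    Helper for supplying the variance term of :func:`power_two_group`
    from data.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    a = values[groups.index[groups == group_a].intersection(values.columns)]
    b = values[groups.index[groups == group_b].intersection(values.columns)]
    df = a.shape[1] + b.shape[1] - 2
    ss = ((a.sub(a.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    ss += ((b.sub(b.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    return float(np.sqrt(ss / df).median())
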