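"""Baseline-table ("table one") comparison machinery.

Continuous variables are gated through a one-sample Kolmogorov–Smirnov
test against a normal distribution with the sample's estimated mean and
standard deviation at α = 0.05; variables normal in both cohorts are
summarised as mean ± SD and compared by Student's t-test, otherwise as
median (IQR) and compared by the Wilcoxon rank-sum test. Categorical
variables are summarised as count (%) and compared by Pearson's
chi-square without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSummary",
    "normality_gate",
    "compare_continuous",
    "compare_categorical",
    "table_one",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class VariableSummary:
    variable: str
    summary_a: str
    summary_b: str
    test: str
    p_value: float


def normality_gate(sample, alpha: float = NORMALITY_ALPHA) -> bool:
    """True iff a KS test against N(mean, sd) (estimated) does not reject.

    Samples with n < 3 or zero variance are treated as non-normal (logged),
    so they fall through to rank-based handling rather than crash.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        logger.info("normality gate: n=%d < 3, treated as non-normal", x.size)
        return False
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("normality gate: degenerate constant sample, treated as non-normal")
        return False
    p = stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue
    return bool(p >= alpha)


def compare_continuous(a, b) -> tuple[str, float]:
    """(test name, two-sided p): t-test iff both samples pass the gate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_continuous needs n ≥ 2 in both samples")
    if normality_gate(a) and normality_gate(b):
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
        return "t-test", float(p)
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return "wilcoxon-rank-sum", float(p)


def compare_categorical(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2×k count table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def _fmt_continuous(x: np.ndarray, normal: bool, decimals: int) -> str:
    if normal:
        return f"{x.mean():.{decimals}f} ± {x.std(ddof=1):.{decimals}f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.{decimals}f} ({q1:.{decimals}f}, {q3:.{decimals}f})"


def table_one(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Variable-by-variable comparison of two cohorts.

    Continuous variables print mean ± SD when normal in both cohorts, else
    median (IQR); categorical (0/1) variables print count (%).
    """
    rows: list[VariableSummary] = []
    for var in continuous or []:
        a = cohort_a[var].dropna().to_numpy(dtype=float)
        b = cohort_b[var].dropna().to_numpy(dtype=float)
        normal = normality_gate(a) and normality_gate(b)
        test, p = compare_continuous(a, b)
        rows.append(VariableSummary(
            var, _fmt_continuous(a, normal, decimals), _fmt_continuous(b, normal, decimals),
            test, p,
        ))
    for var in categorical or []:
        a = cohort_a[var].astype(bool)
        b = cohort_b[var].astype(bool)
        tab = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
        stat, p = compare_categorical(tab)
        fmt = lambda s: f"{int(s.sum())} ({100 * s.mean():.{decimals}f})"
        rows.append(VariableSummary(var, fmt(a), fmt(b), "chi-square", p))
    return pd.DataFrame([r.__dict__ for r in rows])
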