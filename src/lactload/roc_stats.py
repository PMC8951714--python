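"""ROC analysis: nonparametric AUC, DeLong inference, Youden cutoffs and
operating characteristics.

The AUC is the Mann–Whitney two-sample statistic: the probability that a
randomly chosen positive (death) scores higher than a randomly chosen
negative, with ties given half credit. Variances and covariances of AUCs
use DeLong's structural components ("placements"): for positive i,
V10_i is the fraction of negatives it beats (half credit for ties), and
symmetrically V01_j for negatives. Then

    var(AUC) = S10/m + S01/n

with S10, S01 the sample variances of the placements over the m positives
and n negatives. Paired comparisons of two markers on the same patients
additionally use the sample covariances of the paired placements; unpaired
comparisons (disjoint cohorts) set the covariance to zero.

Throughout, higher score ⇒ predicted death ("positive if score ≥ cutoff");
there is no automatic orientation detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "DelongComponents",
    "DelongComparison",
    "OperatingPoint",
    "auc_mann_whitney",
    "delong_components",
    "delong_ci",
    "delong_paired_test",
    "independent_auc_test",
    "roc_curve",
    "youden_cutoff",
    "operating_characteristics",
]


class SingleClassError(ValueError):
    """Raised when an inference needs both outcome classes and got one."""


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("single-class cohort: both outcomes must be present")
    return pos, neg


def _check_groups(pos, neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("single-class cohort: both outcomes must be present")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("scores must be finite")
    return pos, neg


@dataclass(frozen=True)
class DelongComponents:
    """Structural components of one marker's AUC."""

    v10: np.ndarray  # placements of positives, length m
    v01: np.ndarray  # placements of negatives, length n
    auc: float

    @property
    def m(self) -> int:
        return int(self.v10.size)

    @property
    def n(self) -> int:
        return int(self.v01.size)

    def variance(self) -> float:
        if self.m < 2 or self.n < 2:
            raise ValueError("DeLong variance needs ≥ 2 observations in each class")
        s10 = float(np.var(self.v10, ddof=1))
        s01 = float(np.var(self.v01, ddof=1))
        return s10 / self.m + s01 / self.n


@dataclass(frozen=True)
class DelongComparison:
    """Inference on a difference of two AUCs."""

    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z: float
    p_two_sided: float
    paired: bool


@dataclass(frozen=True)
class RocResult:
    """ROC curve with DeLong AUC inference.

    ``thresholds`` are the observed score values in decreasing order, under
    the convention "positive if score ≥ threshold"; sensitivities and
    specificities are the curve coordinates at those thresholds.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int


def auc_mann_whitney(pos_scores, neg_scores) -> float:
    """Tie-corrected Mann–Whitney AUC: P(pos > neg) + P(pos == neg)/2."""
    pos, neg = _check_groups(pos_scores, neg_scores)
    m, n = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def delong_components(pos_scores, neg_scores) -> DelongComponents:
    """Placements of each observation, computed with midranks (O(N log N)).

    mean(v10) == mean(v01) == AUC exactly, ties included.
    """
    pos, neg = _check_groups(pos_scores, neg_scores)
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    rpos = stats.rankdata(pos)
    rneg = stats.rankdata(neg)
    v10 = (ranks[:m] - rpos) / n            # fraction of negatives each positive beats
    v01 = 1.0 - (ranks[m:] - rneg) / m      # fraction of positives each negative is beaten by
    auc = float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))
    return DelongComponents(v10=v10, v01=v01, auc=auc)


def delong_ci(components: DelongComponents, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the probability scale, truncated to [0, 1].

    A zero-variance (perfectly separated) marker yields the degenerate
    interval (auc, auc).
    """
    var = components.variance()
    if var <= 0:
        return (components.auc, components.auc)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (max(0.0, components.auc - half), min(1.0, components.auc + half))


def delong_paired_test(scores_a, scores_b, labels) -> DelongComparison:
    """Compare two markers measured on the same patients (correlated AUCs)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired comparison needs equal-length scores and one label vector")
    ca = delong_components(scores_a[labels], scores_a[~labels])
    cb = delong_components(scores_b[labels], scores_b[~labels])
    m, n = ca.m, ca.n
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs ≥ 2 observations in each class")
    cov = (
        float(np.cov(ca.v10, cb.v10, ddof=1)[0, 1]) / m
        + float(np.cov(ca.v01, cb.v01, ddof=1)[0, 1]) / n
    )
    return _compare(ca.auc, cb.auc, ca.variance(), cb.variance(), cov, paired=True)


def independent_auc_test(
    comp_a: DelongComponents, comp_b: DelongComponents
) -> DelongComparison:
    """Compare AUCs estimated on two disjoint cohorts (zero covariance)."""
    return _compare(
        comp_a.auc, comp_b.auc, comp_a.variance(), comp_b.variance(), 0.0, paired=False
    )


def _compare(auc_a, auc_b, var_a, var_b, cov, *, paired) -> DelongComparison:
    denom2 = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if denom2 <= 0:
        if diff == 0:
            z, p = 0.0, 1.0
        else:
            raise ValueError("degenerate zero-variance comparison with unequal AUCs")
    else:
        z = diff / np.sqrt(denom2)
        p = 2 * stats.norm.sf(abs(z))
    return DelongComparison(
        auc_a=float(auc_a), auc_b=float(auc_b), variance_a=float(var_a),
        variance_b=float(var_b), covariance=float(cov), z=float(z),
        p_two_sided=float(p), paired=paired,
    )


def _sens_spec_at(pos, neg, thresholds) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity (pos ≥ c) and specificity (neg < c) at each threshold,
    via sorted-array counting so the cost is O(N log N) not O(N·thresholds)."""
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    return sens, spec


def roc_curve(scores, labels, level: float = 0.95) -> RocResult:
    """Empirical ROC curve at the observed thresholds, with DeLong CI."""
    pos, neg = _split(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    sens, spec = _sens_spec_at(pos, neg, thresholds)
    comp = delong_components(pos, neg)
    ci = delong_ci(comp, level) if min(comp.m, comp.n) >= 2 else (comp.auc, comp.auc)
    return RocResult(
        thresholds=thresholds, sensitivities=sens, specificities=spec,
        auc=comp.auc, auc_ci=ci, n_pos=pos.size, n_neg=neg.size,
    )


def youden_cutoff(scores, labels) -> float:
    """Observed score maximising J = sensitivity + specificity − 1.

    Convention: predicted positive iff score ≥ cutoff; ties in J are broken
    toward the smallest cutoff.
    """
    pos, neg = _split(scores, labels)
    candidates = np.unique(np.concatenate([pos, neg]))
    sens, spec = _sens_spec_at(pos, neg, candidates)
    j = sens + spec - 1.0
    # first (smallest) candidate at the maximum wins ties
    return float(candidates[np.argmax(np.isclose(j, j.max(), rtol=0, atol=1e-12))])


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


@dataclass(frozen=True)
class OperatingPoint:
    """Operating characteristics of the rule "score ≥ cutoff ⇒ positive"."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    lr_pos: float
    lr_pos_ci: tuple[float, float]
    lr_neg: float
    lr_neg_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]


def _lr_ci(lr: float, var_log: float, level: float) -> tuple[float, float]:
    if not np.isfinite(lr) or lr <= 0 or not np.isfinite(var_log):
        return (np.nan, np.nan)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var_log)
    return (float(lr * np.exp(-half)), float(lr * np.exp(half)))


def operating_characteristics(
    scores, labels, cutoff: float, level: float = 0.95
) -> OperatingPoint:
    """2×2-table summary at a fixed cutoff.

    Sensitivity/specificity and predictive values get Clopper–Pearson
    (exact binomial) intervals; likelihood ratios get log-method intervals.
    An undefined likelihood ratio (zero denominator) is reported as
    infinite with an undefined upper/lower bound and logged.
    """
    pos, neg = _split(scores, labels)
    tp = int((pos >= cutoff).sum())
    fn = pos.size - tp
    fp = int((neg >= cutoff).sum())
    tn = neg.size - fp

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)

    if spec < 1.0:
        lr_pos = sens / (1 - spec)
        var_pos = (
            (1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn)) if tp > 0 else np.nan
        )
        lr_pos_ci = _lr_ci(lr_pos, var_pos, level)
    else:
        lr_pos, lr_pos_ci = np.inf, (np.nan, np.inf)
        logger.info("LR+ undefined at cutoff %g (no false positives); reported as inf", cutoff)
    if spec > 0.0:
        lr_neg = (1 - sens) / spec
        var_neg = (
            (1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn)) if fn > 0 else np.nan
        )
        lr_neg_ci = _lr_ci(lr_neg, var_neg, level)
    else:
        lr_neg, lr_neg_ci = np.inf, (np.nan, np.inf)
        logger.info("LR− undefined at cutoff %g (no true negatives); reported as inf", cutoff)

    n_pred_pos = tp + fp
    n_pred_neg = tn + fn
    ppv = tp / n_pred_pos if n_pred_pos else np.nan
    npv = tn / n_pred_neg if n_pred_neg else np.nan

    return OperatingPoint(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, sensitivity_ci=_clopper_pearson(tp, tp + fn, level),
        specificity=spec, specificity_ci=_clopper_pearson(tn, tn + fp, level),
        lr_pos=float(lr_pos), lr_pos_ci=lr_pos_ci,
        lr_neg=float(lr_neg), lr_neg_ci=lr_neg_ci,
        ppv=float(ppv) if n_pred_pos else np.nan,
        ppv_ci=_clopper_pearson(tp, n_pred_pos, level) if n_pred_pos else (np.nan, np.nan),
        npv=float(npv) if n_pred_neg else np.nan,
        npv_ci=_clopper_pearson(tn, n_pred_neg, level) if n_pred_neg else (np.nan, np.nan),
    )
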