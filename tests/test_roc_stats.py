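"""ROC/AUC machinery against brute-force and library oracles."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from lactload import (
    SingleClassError,
    auc_mann_whitney,
    delong_ci,
    delong_components,
    delong_paired_test,
    independent_auc_test,
    operating_characteristics,
    roc_curve,
    youden_cutoff,
)


def pairwise_auc(pos, neg):
    """Exhaustive half-credit oracle."""
    pos = np.asarray(pos)[:, None]
    neg = np.asarray(neg)[None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


class TestAuc:
    def test_examples(self):
        assert auc_mann_whitney([3, 1, 2], [2, 0]) == pytest.approx(4.5 / 6)
        assert auc_mann_whitney([1, 1, 1], [1, 1]) == 0.5
        assert auc_mann_whitney([5, 6, 7], [1, 2]) == 1.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(50):
            m, n = rng.integers(1, 40, 2)
            # integer scores force ties
            pos = rng.integers(0, 6, m).astype(float)
            neg = rng.integers(0, 6, n).astype(float)
            assert auc_mann_whitney(pos, neg) == pytest.approx(
                pairwise_auc(pos, neg), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        scores[labels] += 0.8
        assert auc_mann_whitney(scores[labels], scores[~labels]) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc_mann_whitney([], [1.0])


class TestDelongComponents:
    def test_placement_means_equal_auc(self, rng):
        for _ in range(20):
            pos = rng.integers(0, 8, 30).astype(float)
            neg = rng.integers(0, 8, 50).astype(float)
            c = delong_components(pos, neg)
            auc = auc_mann_whitney(pos, neg)
            assert np.mean(c.v10) == pytest.approx(auc, abs=1e-12)
            assert np.mean(c.v01) == pytest.approx(auc, abs=1e-12)

    def test_perfect_separation_zero_variance(self):
        c = delong_components([5.0, 6.0, 7.0], [1.0, 2.0])
        assert np.all(c.v10 == 1.0) and np.all(c.v01 == 1.0)
        assert c.variance() == 0.0
        assert delong_ci(c) == (1.0, 1.0)

    def test_variance_needs_two_per_class(self):
        with pytest.raises(ValueError):
            delong_components([1.0], [0.0, 0.5]).variance()


class TestDelongCI:
    def test_interval_contains_auc_and_stays_in_unit(self, rng):
        for _ in range(20):
            scores = rng.normal(size=60)
            labels = np.arange(60) < 20
            scores[labels] += 2.0
            c = delong_components(scores[labels], scores[~labels])
            lo, hi = delong_ci(c)
            assert 0.0 <= lo <= c.auc <= hi <= 1.0

    def test_level_monotone(self, rng):
        scores = rng.normal(size=100)
        labels = np.arange(100) < 40
        c = delong_components(scores[labels], scores[~labels])
        lo90, hi90 = delong_ci(c, 0.90)
        lo99, hi99 = delong_ci(c, 0.99)
        assert lo99 <= lo90 and hi90 <= hi99


class TestPairedTest:
    def test_marker_vs_itself_is_null(self, rng):
        scores = rng.normal(size=80)
        labels = np.arange(80) < 30
        cmp_ = delong_paired_test(scores, scores, labels)
        assert cmp_.z == 0.0 and cmp_.p_two_sided == 1.0

    def test_antisymmetry(self, rng):
        labels = np.arange(100) < 40
        a = rng.normal(size=100) + labels
        b = 0.7 * a + rng.normal(size=100)
        c1 = delong_paired_test(a, b, labels)
        c2 = delong_paired_test(b, a, labels)
        assert c1.z == pytest.approx(-c2.z)
        assert c1.p_two_sided == pytest.approx(c2.p_two_sided)
        assert c1.paired and c2.paired

    def test_detects_genuinely_better_marker(self, rng):
        n = 400
        labels = np.arange(n) < n // 2
        signal = labels * 1.5 + rng.normal(size=n)
        good = signal + 0.3 * rng.normal(size=n)
        bad = 0.2 * signal + rng.normal(size=n)
        cmp_ = delong_paired_test(good, bad, labels)
        assert cmp_.auc_a > cmp_.auc_b
        assert cmp_.p_two_sided < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [True, False])


class TestUnpairedTest:
    def test_identical_components_give_zero_z(self, rng):
        scores = rng.normal(size=100)
        labels = np.arange(100) < 50
        scores[labels] += 1
        c = delong_components(scores[labels], scores[~labels])
        cmp_ = independent_auc_test(c, c)
        assert cmp_.z == 0.0 and cmp_.covariance == 0.0 and not cmp_.paired

    def test_power_grows_with_auc_difference(self, rng):
        # fixed n; larger true separation in cohort A ⇒ larger |z| on average
        mean_abs_z = []
        for mu in (0.0, 0.8, 1.6):
            zs = []
            for _ in range(60):
                ca = delong_components(rng.normal(1.0 + mu, 1, 100), rng.normal(0, 1, 100))
                cb = delong_components(rng.normal(1.0, 1, 100), rng.normal(0, 1, 100))
                zs.append(abs(independent_auc_test(ca, cb).z))
            mean_abs_z.append(np.mean(zs))
        assert mean_abs_z[0] < mean_abs_z[1] < mean_abs_z[2]


class TestYouden:
    def test_perfect_separation_smallest_winning_cutoff(self):
        assert youden_cutoff(
            [5.0, 6.0, 1.0, 2.0], [True, True, False, False]
        ) == 5.0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            m, n = rng.integers(2, 30, 2)
            pos = np.round(rng.normal(1, 1, m), 1)
            neg = np.round(rng.normal(0, 1, n), 1)
            cut = youden_cutoff(
                np.concatenate([pos, neg]),
                np.concatenate([np.ones(m, bool), np.zeros(n, bool)]),
            )
            cands = np.unique(np.concatenate([pos, neg]))
            js = [(pos >= c).mean() + (neg < c).mean() - 1 for c in cands]
            best = max(js)
            got = (pos >= cut).mean() + (neg < cut).mean() - 1
            assert got == pytest.approx(best, abs=1e-12)
            # tie-break: no smaller candidate achieves the same J
            smaller = [c for c, j in zip(cands, js)
                       if c < cut and j == pytest.approx(best, abs=1e-12)]
            assert not smaller

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = np.arange(100) < 35
        scores[labels] += 1
        c1 = youden_cutoff(scores, labels)
        c2 = youden_cutoff(np.exp(scores), labels)
        assert c2 == pytest.approx(np.exp(c1))


class TestOperatingCharacteristics:
    def test_perfect_classifier(self):
        scores = np.array([5.0, 6.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        op = operating_characteristics(scores, labels, cutoff=5.0)
        assert op.sensitivity == op.specificity == op.ppv == op.npv == 1.0
        assert np.isinf(op.lr_pos)

    def test_hand_2x2(self):
        op = operating_characteristics(
            [3.0, 1.0, 2.0, 0.0], [True, True, False, False], cutoff=2.0
        )
        assert (op.tp, op.fn, op.fp, op.tn) == (1, 1, 1, 1)
        assert op.sensitivity == op.specificity == 0.5
        assert op.lr_pos == pytest.approx(1.0)
        assert op.lr_neg == pytest.approx(1.0)
        assert op.ppv == op.npv == 0.5

    def test_sensitivity_matches_roc_curve(self, rng):
        scores = rng.normal(size=120)
        labels = np.arange(120) < 50
        scores[labels] += 1
        roc = roc_curve(scores, labels)
        for i in rng.integers(0, roc.thresholds.size, 5):
            op = operating_characteristics(scores, labels, roc.thresholds[i])
            assert op.sensitivity == pytest.approx(roc.sensitivities[i])
            assert op.specificity == pytest.approx(roc.specificities[i])

    def test_clopper_pearson_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        from lactload.roc_stats import _clopper_pearson

        for k, n in [(0, 10), (3, 10), (10, 10), (45, 120)]:
            lo, hi = _clopper_pearson(k, n, 0.95)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_all_proportions_in_unit_interval(self, rng):
        scores = rng.normal(size=60)
        labels = np.arange(60) < 25
        op = operating_characteristics(scores, labels, float(np.median(scores)))
        for lo, hi, x in [
            (op.sensitivity_ci + (op.sensitivity,)),
            (op.specificity_ci + (op.specificity,)),
            (op.ppv_ci + (op.ppv,)),
            (op.npv_ci + (op.npv,)),
        ]:
            assert 0 <= lo <= x <= hi <= 1


def test_roc_curve_monotone_and_bounded(rng):
    scores = rng.normal(size=150)
    labels = np.arange(150) < 60
    scores[labels] += 0.7
    roc = roc_curve(scores, labels)
    assert 0 <= roc.auc <= 1
    assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]
    # thresholds decreasing ⇒ sensitivity non-decreasing
    assert np.all(np.diff(roc.sensitivities) >= 0)
    assert np.all(np.diff(roc.specificities) <= 0)
    assert roc.n_pos == 60 and roc.n_neg == 90
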