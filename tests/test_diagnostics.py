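import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoredux import (
    CohortError,
    ConfusionTable,
    auc_power_hanley,
    auc_se_ci_hanley,
    chi_square_test,
    confusion_table,
    diagnostic_metrics,
    roc_auc,
    spearman_rho,
    youden_cutoff,
)


class TestConfusionTable:
    def test_piv6_style_counts(self):
        truth = ["suboptimal"] * 31 + ["optimal"] * 52
        predicted = [1] * 7 + [0] * 24 + [0] * 52
        t = confusion_table(truth, predicted)
        assert (t.tp, t.fp, t.fn, t.tn) == (7, 0, 24, 52)

    def test_perfect_agreement_has_no_errors(self):
        t = confusion_table([1, 0, 1, 0], [1, 0, 1, 0])
        assert t.fp == t.fn == 0

    def test_complement_prediction_has_no_hits(self):
        t = confusion_table([1, 0, 1, 0], [0, 1, 0, 1])
        assert t.tp == t.tn == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            confusion_table([1, 0], [1])


class TestDiagnosticMetrics:
    def test_piv6_metrics(self):
        m = diagnostic_metrics(ConfusionTable(7, 0, 24, 52))
        assert m.sensitivity == pytest.approx(7 / 31)
        assert m.specificity == 1.0
        assert m.ppv == 1.0
        assert m.npv == pytest.approx(52 / 76)
        assert m.accuracy == pytest.approx(59 / 83)

    def test_all_correct_gives_all_ones(self):
        m = diagnostic_metrics(ConfusionTable(5, 0, 0, 5))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominator_is_nan_not_zero(self):
        m = diagnostic_metrics(ConfusionTable(0, 0, 5, 5))
        assert m.sensitivity == 0.0
        assert math.isnan(m.ppv)

    @given(
        st.tuples(
            st.integers(0, 40), st.integers(0, 40),
            st.integers(0, 40), st.integers(0, 40),
        ).filter(lambda t: sum(t) > 0 and t[0] + t[2] > 0 and t[1] + t[3] > 0)
    )
    @settings(derandomize=True, max_examples=200)
    def test_accuracy_identity(self, counts):
        """accuracy == prevalence*sens + (1-prevalence)*spec, exactly."""
        tp, fp, fn, tn = counts
        t = ConfusionTable(tp, fp, fn, tn)
        m = diagnostic_metrics(t)
        prev = t.n_pos / t.total
        assert m.accuracy == pytest.approx(
            prev * m.sensitivity + (1 - prev) * m.specificity, abs=1e-12
        )

    def test_ppv_is_one_whenever_no_false_positives(self):
        m = diagnostic_metrics(ConfusionTable(3, 0, 10, 20))
        assert m.ppv == 1.0


def _brute_force_auc(scores, y):
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,truth,expected",
        [
            ([2, 3, 1], [1, 1, 0], 1.0),
            ([1, 1], [1, 0], 0.5),
            ([3, 1, 2, 2], [1, 1, 0, 0], 0.5),  # 2 wins, 2 losses of 4 pairs
        ],
    )
    def test_small_examples(self, scores, truth, expected):
        assert roc_auc(scores, truth).auc == pytest.approx(expected)

    def test_one_class_input_rejected(self):
        with pytest.raises(CohortError):
            roc_auc([1, 2], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        r = roc_auc(scores, y)
        assert tuple(r.points[0]) == (0.0, 0.0)
        assert tuple(r.points[-1]) == (1.0, 1.0)
        assert (np.diff(r.points[:, 0]) >= 0).all()
        assert (np.diff(r.points[:, 1]) >= 0).all()

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_trapezoid_equals_midrank_mann_whitney(self, data):
        """Two independent AUC computations agree to 1e-12 (ties included)."""
        n = data.draw(st.integers(4, 40))
        scores = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n)
        )
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < len(v)
            )
        )
        r = roc_auc(np.array(scores, dtype=float), np.array(y))
        assert r.trapezoid_auc == pytest.approx(r.auc, abs=1e-12)
        assert r.auc == pytest.approx(_brute_force_auc(scores, y), abs=1e-12)

    def test_invariance_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        a1 = roc_auc(scores, y).auc
        a2 = roc_auc(np.exp(scores), y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_agrees_with_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.integers(0, 10, size=200).astype(float)
        y = (rng.random(200) < 0.35).astype(int)
        assert roc_auc(scores, y).auc == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )


class TestHanleyMcNeil:
    def test_perfect_auc_has_zero_se(self):
        se, ci = auc_se_ci_hanley(1.0, 10, 10)
        assert se == 0.0
        assert ci == (1.0, 1.0)

    def test_se_at_reference_group_sizes(self):
        se, _ = auc_se_ci_hanley(0.73, 31, 52)
        assert se == pytest.approx(0.0594, abs=2e-4)

    def test_se_at_null_small_groups(self):
        se, _ = auc_se_ci_hanley(0.5, 10, 10)
        assert se == pytest.approx(math.sqrt((0.25 + 18 / 12) / 100), abs=1e-12)

    def test_ci_clipped_to_unit_interval(self):
        _, ci = auc_se_ci_hanley(0.95, 2, 2)
        assert 0.0 <= ci[0] <= ci[1] <= 1.0

    def test_invalid_auc_rejected(self):
        with pytest.raises(ValueError):
            auc_se_ci_hanley(1.2, 10, 10)


class TestAucPower:
    def test_reference_power_rounds_to_96_percent(self):
        power = auc_power_hanley(0.73, 31, 52, 0.05)
        assert power == pytest.approx(0.955, abs=0.002)
        assert round(100 * power) == 96

    def test_near_null_power_collapses(self):
        assert auc_power_hanley(0.5001, 31, 52, 0.05) < 0.05

    def test_large_effect_power_near_one(self):
        assert auc_power_hanley(0.95, 50, 50, 0.05) > 0.999

    def test_monotone_in_effect_and_sample_size(self):
        grid = [0.55, 0.6, 0.65, 0.7, 0.8, 0.9]
        powers = [auc_power_hanley(a, 31, 52) for a in grid]
        assert powers == sorted(powers)
        sizes = [(10, 20), (20, 30), (31, 52), (60, 100)]
        powers = [auc_power_hanley(0.7, p, n) for p, n in sizes]
        assert powers == sorted(powers)

    def test_auc_at_or_below_half_rejected(self):
        with pytest.raises(ValueError):
            auc_power_hanley(0.5, 31, 52)


class TestYoudenCutoff:
    def test_perfect_separation_midpoint(self):
        r = youden_cutoff([10, 20, 1, 2], [1, 1, 0, 0])
        assert r.cutoff == pytest.approx(6.0)
        assert r.youden_j == pytest.approx(1.0)

    def test_identical_distributions_have_zero_j(self):
        r = youden_cutoff([1, 2, 1, 2], [1, 1, 0, 0])
        assert r.youden_j == pytest.approx(0.0)

    def test_single_midpoint(self):
        r = youden_cutoff([5, 1], [1, 0])
        assert r.cutoff == pytest.approx(3.0)
        assert (r.sensitivity, r.specificity) == (1.0, 1.0)

    def test_j_equals_sens_plus_spec_minus_one(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=80) + np.repeat([0, 1], 40)
        y = np.repeat([0, 1], 40)
        r = youden_cutoff(scores, y)
        assert r.youden_j == pytest.approx(r.sensitivity + r.specificity - 1)

    def test_cutoff_maps_through_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60) + np.repeat([0.0, 1.5], 30)
        y = np.repeat([0, 1], 30)
        r1 = youden_cutoff(scores, y)
        r2 = youden_cutoff(3.0 * scores + 7.0, y)
        assert r2.youden_j == pytest.approx(r1.youden_j, abs=1e-12)
        assert (r2.sensitivity, r2.specificity) == (r1.sensitivity, r1.specificity)


class TestSpearman:
    def test_monotone_vectors(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_binary_with_ties_uses_midranks(self):
        assert spearman_rho([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(
            0.8944, abs=1e-4
        )

    def test_constant_vector_is_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


class TestChiSquare:
    def test_figo_by_outcome_counts(self):
        stat, p = chi_square_test([[46, 6], [28, 3]])
        assert stat == pytest.approx(0.069, abs=0.002)
        assert p == pytest.approx(0.793, abs=0.002)

    def test_grade_by_outcome_counts(self):
        stat, p = chi_square_test([[18, 34], [10, 21]])
        assert stat == pytest.approx(0.049, abs=0.002)
        assert p == pytest.approx(0.825, abs=0.002)

    def test_proportional_table_has_zero_statistic(self):
        stat, p = chi_square_test([[10, 10], [20, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 5], [0, 3]])
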