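import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rocsurface import (
    LabeledScores,
    RocsCurve,
    ValidationError,
    auc,
    compute_curve,
    fcauc,
    orient,
    vus,
)

from conftest import random_labeled_scores


def mann_whitney_auc(data):
    """Independent oracle: concordant P-N pair fraction (ties count 1/2)."""
    pos = data.positive_scores[:, None]
    neg = data.negative_scores[None, :]
    return ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (
        data.n_pos * data.n_neg
    )


def riemann_vus(curve, n_grid=100_000):
    """Independent oracle: numeric integration of TDR(t) * (1 - FPR(t))
    over TPR levels t in [0, 1] for the step curve.

    The integrand is piecewise constant with breakpoints at the curve's
    TPR values, so a midpoint rule on the union of a uniform grid and the
    breakpoints integrates it to floating-point accuracy.
    """
    edges = np.union1d(np.linspace(0, 1, n_grid + 1), curve.tpr)
    mid = (edges[:-1] + edges[1:]) / 2
    widths = np.diff(edges)
    k = np.searchsorted(curve.tpr, mid, side="left")
    inside = k < len(curve.tpr)
    integrand = np.zeros_like(mid)
    integrand[inside] = curve.tdr[k[inside]] * (1 - curve.fpr[k[inside]])
    return float(np.sum(integrand * widths))


def constant_tdr_curve(base, c):
    """Copy of a curve with TDR forced to the constant c."""
    return RocsCurve(
        base.thresholds, base.fpr, base.tpr,
        np.full(len(base), 1.0 - c), base.n_pos, base.n_neg,
    )


class TestAuc:
    def test_perfect_separation_is_one(self):
        data = LabeledScores([4, 3, 2, 1], [1, 1, 0, 0])
        assert auc(compute_curve(data)) == 1.0

    def test_six_feature_example_matches_pair_counting(self, six_feature_curve):
        assert auc(six_feature_curve) == pytest.approx(7 / 9)

    def test_fully_tied_scores_give_zero_under_step_convention(self):
        # single block achieved at FPR = 1; trapezoids would give 0.5
        data = LabeledScores([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert auc(compute_curve(data)) == 0.0

    def test_matches_mann_whitney_on_tie_free_data(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            data = orient(random_labeled_scores(rng, n_max=50, ties=False))
            assert auc(compute_curve(data)) == pytest.approx(
                mann_whitney_auc(data), abs=1e-12
            )


class TestVus:
    @pytest.mark.parametrize("n_pos, n_neg", [(5, 5), (5, 50), (2, 200)])
    def test_perfect_separation_is_one_at_any_class_ratio(self, n_pos, n_neg):
        scores = np.r_[np.arange(n_neg), np.arange(n_neg, n_neg + n_pos)]
        labels = np.r_[np.zeros(n_neg, bool), np.ones(n_pos, bool)]
        assert vus(compute_curve(LabeledScores(scores, labels))) == 1.0

    def test_six_feature_example(self, six_feature_curve):
        assert vus(six_feature_curve) == pytest.approx(11 / 15)

    def test_vanishes_for_inseparable_classes_at_extreme_ratio(self):
        rng = np.random.default_rng(5)
        values = []
        for ratio in (1, 10, 100):
            scores = rng.normal(size=101 * 10)
            labels = np.zeros(scores.size, bool)
            labels[: scores.size // (1 + ratio)] = True
            values.append(vus(compute_curve(LabeledScores(scores, labels))))
        assert values[0] > values[1] > values[2]
        assert values[2] < 0.05

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_riemann_oracle(self, seed):
        data = orient(random_labeled_scores(np.random.default_rng(seed)))
        curve = compute_curve(data)
        assert vus(curve) == pytest.approx(riemann_vus(curve), abs=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_auc(self, seed):
        curve = compute_curve(
            orient(random_labeled_scores(np.random.default_rng(seed)))
        )
        assert 0.0 <= vus(curve) <= auc(curve) + 1e-12 <= 1.0 + 1e-12

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 1.0))
    def test_constant_tdr_identity(self, seed, c):
        base = compute_curve(
            orient(random_labeled_scores(np.random.default_rng(seed)))
        )
        forced = constant_tdr_curve(base, c)
        assert vus(forced) == pytest.approx(c * auc(forced), abs=1e-12)

    def test_class_labels_are_not_exchangeable(self, six_feature_data):
        curve = compute_curve(six_feature_data)
        swapped = compute_curve(
            LabeledScores(-six_feature_data.scores, ~six_feature_data.labels)
        )
        assert auc(swapped) == pytest.approx(auc(curve))
        assert vus(swapped) != pytest.approx(vus(curve))


class TestFcauc:
    def test_b_outside_unit_interval_rejected(self, six_feature_curve):
        with pytest.raises(ValidationError):
            fcauc(six_feature_curve, 1.5)
        with pytest.raises(ValidationError):
            fcauc(six_feature_curve, -0.1)

    def test_top_ranked_positives_reach_full_auc(self):
        # 4P/4N, positives on top: FDR sweep 0,0,0,0,1/5,1/3,3/7,1/2;
        # at b = 0.2 the most liberal cutoff has 5 discoveries, TPR = 1
        data = LabeledScores(np.arange(8, 0, -1), [1, 1, 1, 1, 0, 0, 0, 0])
        curve = compute_curve(data)
        np.testing.assert_allclose(
            curve.fdr, [0, 0, 0, 0, 1 / 5, 1 / 3, 3 / 7, 1 / 2]
        )
        assert fcauc(curve, 0.2) == auc(curve) == 1.0

    def test_six_feature_example_caps_at_two_thirds(self, six_feature_curve):
        assert fcauc(six_feature_curve, 0.2) == pytest.approx(2 / 3)

    def test_zero_when_no_cutoff_attains_the_level(self):
        # inseparable classes at high class ratio: min FDR stays above b
        rng = np.random.default_rng(3)
        scores = rng.normal(size=1100)
        labels = np.zeros(1100, bool)
        labels[:100] = True
        curve = compute_curve(orient(LabeledScores(scores, labels)))
        assert curve.fdr.min() > 0.2
        assert fcauc(curve, 0.2) == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_b_and_anchored_at_auc(self, seed, b1, b2):
        curve = compute_curve(
            orient(random_labeled_scores(np.random.default_rng(seed)))
        )
        lo, hi = min(b1, b2), max(b1, b2)
        assert fcauc(curve, 0.0) <= fcauc(curve, lo) <= fcauc(curve, hi)
        assert fcauc(curve, hi) <= fcauc(curve, 1.0)
        assert fcauc(curve, 1.0) == pytest.approx(auc(curve), abs=1e-12)
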