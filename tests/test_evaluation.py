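"""AUC/DeLong, IDI, continuous NRI, and score-stratified relative risks."""

import math

import numpy as np
import pytest

from dynascore.evaluation import (
    auc,
    category_free_nri,
    compare_scores,
    delta_auc,
    idi,
    risk_table_by_score,
    score_to_risk,
)


def brute_force_auc(scores, outcome):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_hand_example_with_tie(self):
        est, _ = auc([3, 2, 1, 2], [True, True, False, False])
        assert est == pytest.approx(0.875)

    def test_perfect_separation(self):
        est, _ = auc([5, 6, 1, 2], [True, True, False, False])
        assert est == 1.0

    def test_constant_scores_give_half(self):
        est, _ = auc([2, 2, 2, 2], [True, False, True, False])
        assert est == 0.5

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError, match="event"):
            auc([1, 2], [True, True])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 8, size=n)
            outcome = rng.random(n) < 0.3
            if outcome.all() or not outcome.any():
                continue
            est, (lo, hi) = auc(scores, outcome)
            assert est == pytest.approx(brute_force_auc(scores, outcome), abs=1e-12)
            assert lo <= est <= hi

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (100, 1000):
            scores = rng.normal(size=n) + rng.random(n)
            outcome = rng.random(n) < 0.4
            _, (lo, hi) = auc(scores, outcome)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestDeltaAuc:
    def test_identical_scores_zero_with_degenerate_ci(self):
        s = [1, 2, 3, 4]
        y = [False, True, False, True]
        est = delta_auc(s, s, y)
        assert est.estimate == 0.0
        assert est.ci_low == est.ci_high == 0.0
        assert est.p_value == 1.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=80), rng.normal(size=80)
        y = rng.random(80) < 0.35
        fwd, rev = delta_auc(a, b, y), delta_auc(b, a, y)
        assert fwd.estimate == pytest.approx(-rev.estimate)
        assert fwd.ci_low == pytest.approx(-rev.ci_high)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_matches_unpaired_auc_difference(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=60), rng.normal(size=60)
        y = rng.random(60) < 0.5
        est = delta_auc(a, b, y)
        assert est.estimate == pytest.approx(auc(a, y)[0] - auc(b, y)[0])


class TestScoreToRisk:
    def test_constant_score_returns_prevalence(self):
        prob = score_to_risk([3, 3, 3, 3], [True, False, False, False])
        assert prob == pytest.approx([0.25] * 4)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(13)
        scores = rng.integers(0, 6, size=400)
        outcome = rng.random(400) < (0.05 + 0.1 * scores / 5)
        prob = score_to_risk(scores, outcome)
        order = np.argsort(scores)
        assert (np.diff(prob[order]) >= -1e-12).all()

    def test_separation_fallback_uses_per_level_rates(self):
        # score perfectly separates outcome -> logistic MLE diverges
        scores = np.array([0] * 10 + [1] * 10)
        outcome = np.array([False] * 10 + [True] * 10)
        prob = score_to_risk(scores, outcome)
        assert prob[:10] == pytest.approx((0 + 0.5) / (10 + 1.0))
        assert prob[10:] == pytest.approx((10 + 0.5) / (10 + 1.0))


class TestIdi:
    def test_direct_formula_example(self):
        # events: new .6 vs old .5; non-events: new .3 vs old .35
        p_new = np.array([0.6, 0.6, 0.3, 0.3]) + np.array([0.01, -0.01, 0.01, -0.01])
        p_old = np.array([0.5, 0.5, 0.35, 0.35]) + np.array([0.01, -0.01, 0.01, -0.01])
        y = [True, True, False, False]
        assert idi(p_new, p_old, y).estimate == pytest.approx(0.15)

    def test_identical_probabilities_zero(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        est = idi(p, p, [True, False, True, False])
        assert est.estimate == 0.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(7)
        p_new, p_old = rng.random(50), rng.random(50)
        y = rng.random(50) < 0.4
        assert idi(p_new, p_old, y).estimate == pytest.approx(-idi(p_old, p_new, y).estimate)

    def test_equals_discrimination_slope_difference(self):
        rng = np.random.default_rng(19)
        p_new, p_old = rng.random(200), rng.random(200)
        y = rng.random(200) < 0.3
        slope_new = p_new[y].mean() - p_new[~y].mean()
        slope_old = p_old[y].mean() - p_old[~y].mean()
        assert idi(p_new, p_old, y).estimate == pytest.approx(slope_new - slope_old, abs=1e-12)


class TestCategoryFreeNri:
    def test_direct_counting_example(self):
        # events: 3 up 1 down; non-events: 1 up 3 down -> 0.5 + 0.5 = 1.0
        p_old = np.full(8, 0.5)
        p_new = np.array([0.6, 0.6, 0.6, 0.4, 0.6, 0.4, 0.4, 0.4])
        y = np.array([True] * 4 + [False] * 4)
        assert category_free_nri(p_new, p_old, y).estimate == pytest.approx(1.0)

    def test_ties_count_in_neither_direction(self):
        p_old = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.5, 0.6, 0.5, 0.4])  # one tie per class
        y = np.array([True, True, False, False])
        assert category_free_nri(p_new, p_old, y).estimate == pytest.approx(1.0)

    def test_identical_probabilities_zero(self):
        p = np.array([0.2, 0.8, 0.3, 0.7])
        assert category_free_nri(p, p, [True, True, False, False]).estimate == 0.0

    def test_bounded_in_minus_two_two(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(4, 60))
            p_new, p_old = rng.random(n), rng.random(n)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            est = category_free_nri(p_new, p_old, y).estimate
            assert -2.0 <= est <= 2.0


class TestRiskTable:
    def test_katz_interval_hand_example(self):
        scores = np.array([1] * 100 + [0] * 100)
        outcome = np.array([True] * 20 + [False] * 80 + [True] * 10 + [False] * 90)
        rows = risk_table_by_score(scores, outcome, min_stratum=20)
        ref, row = rows[0], rows[1]
        assert ref.reference and ref.relative_risk == 1.0 and ref.ci_low is None
        assert row.relative_risk == pytest.approx(2.0)
        # closed form: exp(ln 2 +/- 1.96 * sqrt(1/20 - 1/100 + 1/10 - 1/100))
        assert row.ci_low == pytest.approx(0.9866, abs=0.001)
        assert row.ci_high == pytest.approx(4.0545, abs=0.001)

    def test_stratum_identical_to_reference(self):
        scores = np.array([0] * 50 + [1] * 50)
        outcome = np.array(([True] * 10 + [False] * 40) * 2)
        rows = risk_table_by_score(scores, outcome, min_stratum=20)
        assert rows[1].relative_risk == pytest.approx(1.0)

    def test_pooled_af_risk_is_half_in_matched_cohort(self, small_frame):
        from dynascore.scoring import builtin_weights, score_frame

        outcome = (small_frame["group"] == "afl_daf").to_numpy()
        scores = score_frame(small_frame, builtin_weights("chads_vasc"))["delta"].to_numpy()
        rows = risk_table_by_score(scores, outcome)
        assert sum(r.n_events for r in rows) / sum(r.n_total for r in rows) == pytest.approx(0.5)

    def test_sparse_top_levels_merged_upward(self):
        scores = np.array([0] * 40 + [1] * 30 + [2] * 15 + [3] * 10)
        outcome = np.array([i % 3 == 0 for i in range(95)])
        rows = risk_table_by_score(scores, outcome, min_stratum=20)
        labels = [r.score_level for r in rows]
        assert labels == ["0", "1", "2+"]
        assert rows[2].n_total == 25

    def test_sparse_top_remainder_joins_band_below(self):
        scores = np.array([0] * 40 + [1] * 30 + [2] * 5 + [3] * 4)
        outcome = np.array([i % 3 == 0 for i in range(79)])
        rows = risk_table_by_score(scores, outcome, min_stratum=20)
        assert [r.score_level for r in rows] == ["0", "1+"]
        assert rows[1].n_total == 39

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            risk_table_by_score(np.array([1, 2, 3]), np.array([True, False, True]))

    def test_zero_cell_gets_continuity_correction(self):
        scores = np.array([0] * 30 + [1] * 30)
        outcome = np.array([True] * 10 + [False] * 20 + [False] * 30)
        rows = risk_table_by_score(scores, outcome, min_stratum=20)
        row = rows[1]
        assert row.n_events == 0
        assert 0 < row.relative_risk < 1
        assert row.ci_low is not None and math.isfinite(row.ci_high)


def test_compare_scores_report_is_internally_consistent(small_frame):
    from dynascore.scoring import builtin_weights, score_frame

    table = score_frame(small_frame, builtin_weights("chads_vasc"))
    stroke = small_frame["stroke_day"].notna().to_numpy()
    report = compare_scores(
        table["delta"].to_numpy(), table["follow_up"].to_numpy(), stroke,
        "chads_vasc:delta", "chads_vasc:follow_up",
    )
    assert report.delta_auc.estimate == pytest.approx(
        report.auc_new.estimate - report.auc_old.estimate
    )
    assert report.model_new == "chads_vasc:delta"
    payload = report.to_dict()
    assert set(payload) == {"model_new", "model_old", "auc_new", "auc_old", "delta_auc", "idi", "nri"}
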