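"""Standardized differences, classification, and the reweighting rule."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynascore.balance import (
    BalanceRow,
    balance_table,
    classify_std,
    derive_weights,
    std_binary,
    std_continuous,
)
from dynascore.cohort import to_frame
from dynascore.scoring import builtin_weights
from tests.conftest import make_record


class TestStdBinary:
    @pytest.mark.parametrize(
        "x_a, n_a, x_b, n_b, expected",
        [
            (874, 4101, 1428, 4101, -0.30),   # follow-up heart failure
            (382, 4101, 907, 4101, -0.36),    # incident heart failure
            (202, 4101, 521, 4101, -0.28),    # incident stroke/SE
            (732, 4101, 1068, 4101, -0.20),   # follow-up stroke/SE
            (479, 4101, 716, 4101, -0.16),    # incident vascular disease
            (2295, 12223, 999, 5397, 0.01),   # diabetes, pre-matching
        ],
    )
    def test_published_count_pairs(self, x_a, n_a, x_b, n_b, expected):
        assert round(std_binary(x_a, n_a, x_b, n_b), 2) == expected

    def test_equal_proportions_give_zero(self):
        assert std_binary(25, 100, 50, 200) == 0.0

    def test_degenerate_constant_groups(self):
        assert std_binary(0, 10, 0, 10) == 0.0
        assert std_binary(10, 10, 0, 10) == math.inf
        assert std_binary(0, 10, 10, 10) == -math.inf
        assert classify_std(std_binary(10, 10, 0, 10)) == "substantial"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            std_binary(11, 10, 0, 10)
        with pytest.raises(ValueError):
            std_binary(0, 0, 0, 10)


class TestStdContinuous:
    @pytest.mark.parametrize(
        "m_a, s_a, m_b, s_b, expected",
        [
            (68.7, 14.9, 71.3, 12.5, -0.19),  # age, pre-matching
            (0.44, 0.84, 0.92, 1.17, -0.47),  # delta reweighted score
        ],
    )
    def test_published_summary_pairs(self, m_a, s_a, m_b, s_b, expected):
        assert round(std_continuous(m_a, s_a, m_b, s_b), 2) == expected

    def test_identical_summaries_give_zero(self):
        assert std_continuous(3.1, 1.7, 3.1, 1.7) == 0.0

    def test_zero_spread_different_means(self):
        assert std_continuous(2.0, 0.0, 1.0, 0.0) == math.inf

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            std_continuous(0, -1, 0, 1)


class TestClassifyStd:
    @pytest.mark.parametrize(
        "value, category",
        [
            (-0.36, "substantial"),
            (-0.16, "moderate"),
            (0.0999, "negligible"),
            (0.1, "moderate"),
            (0.2, "moderate"),
            (0.2000001, "substantial"),
            (0.0, "negligible"),
            (math.inf, "substantial"),
        ],
    )
    def test_thresholds(self, value, category):
        assert classify_std(value) == category


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    x_a=st.integers(0, 50), n_a=st.integers(50, 100),
    x_b=st.integers(0, 50), n_b=st.integers(50, 100),
)
def test_std_binary_antisymmetric(x_a, n_a, x_b, n_b):
    assert std_binary(x_a, n_a, x_b, n_b) == pytest.approx(-std_binary(x_b, n_b, x_a, n_a))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    m_a=st.floats(-50, 50), s_a=st.floats(0.1, 20),
    m_b=st.floats(-50, 50), s_b=st.floats(0.1, 20),
    scale=st.floats(0.01, 100),
)
def test_std_continuous_antisymmetric_and_scale_invariant(m_a, s_a, m_b, s_b, scale):
    base = std_continuous(m_a, s_a, m_b, s_b)
    assert std_continuous(m_b, s_b, m_a, s_a) == pytest.approx(-base, abs=1e-9)
    rescaled = std_continuous(m_a * scale, s_a * scale, m_b * scale, s_b * scale)
    assert rescaled == pytest.approx(base, rel=1e-6, abs=1e-9)
    assert classify_std(base) == classify_std(-base)


def _two_group_cohort(daf_gains_hf: bool):
    records = []
    for i in range(30):
        records.append(make_record(patient_id=f"s{i}", group="solitary_afl", followup_end=300))
        onset = {"heart_failure": 100} if daf_gains_hf else {}
        records.append(
            make_record(
                patient_id=f"d{i}", group="afl_daf", followup_end=300, af_day=300, onset=onset
            )
        )
    return to_frame(records)


class TestBalanceTable:
    def test_extreme_incident_contrast_is_substantial(self):
        frame = _two_group_cohort(daf_gains_hf=True)
        rows = {(r.variable, r.timepoint): r for r in balance_table(frame)}
        row = rows[("heart_failure", "delta")]
        assert row.group_a_summary["proportion"] == 0.0
        assert row.group_b_summary["proportion"] == 1.0
        assert row.category == "substantial"

    def test_identical_groups_give_zero_stds(self):
        frame = _two_group_cohort(daf_gains_hf=False)
        for row in balance_table(frame):
            assert row.std == 0.0
            assert row.category == "negligible"

    def test_default_synthetic_cohort_incident_hf_substantial(self):
        from dynascore.synthetic import CohortGenParams, generate_cohort

        frame = to_frame(generate_cohort(CohortGenParams(n_per_group=4101, seed=21)))
        rows = {(r.variable, r.timepoint): r for r in balance_table(frame)}
        assert rows[("heart_failure", "delta")].category == "substantial"

    def test_unknown_variable_rejected(self, small_frame):
        with pytest.raises(ValueError, match="unknown balance variable"):
            balance_table(small_frame, variables=["cholesterol"])

    def test_no_delta_rows_for_sex_or_age_bands(self, small_frame):
        rows = balance_table(small_frame)
        emitted = {(r.variable, r.timepoint) for r in rows}
        assert ("female", "delta") not in emitted
        assert ("age_ge75", "delta") not in emitted
        assert ("female", "baseline") in emitted


def _delta_row(variable: str, category: str) -> BalanceRow:
    return BalanceRow(
        variable=variable,
        timepoint="delta",
        group_a_summary={"n": 100, "count": 0, "proportion": 0.0},
        group_b_summary={"n": 100, "count": 0, "proportion": 0.0},
        std=0.0,
        category=category,
    )


class TestDeriveWeights:
    def test_study_categories_recover_reweighted_score(self):
        rows = [
            _delta_row("heart_failure", "substantial"),
            _delta_row("stroke_tia", "substantial"),
            _delta_row("vascular_disease", "moderate"),
            _delta_row("hypertension", "negligible"),
            _delta_row("diabetes", "negligible"),
        ]
        derived = derive_weights(rows, builtin_weights("chads_vasc"))
        assert dict(derived.weights) == dict(builtin_weights("a2c2s2_vasc").weights)
        assert derived.name == "derived(chads_vasc)"

    def test_all_negligible_reduces_to_age_and_sex(self):
        rows = [_delta_row(v, "negligible") for v in (
            "heart_failure", "stroke_tia", "vascular_disease", "hypertension", "diabetes"
        )]
        derived = derive_weights(rows, builtin_weights("chads_vasc"))
        assert derived.max_score == 3  # female 1 + age>=75 2

    def test_missing_component_row_rejected(self):
        rows = [_delta_row("heart_failure", "substantial")]
        with pytest.raises(ValueError, match="delta rows"):
            derive_weights(rows, builtin_weights("chads_vasc"))

    def test_idempotent_on_same_balance_table(self):
        rows = [_delta_row(v, "moderate") for v in (
            "heart_failure", "stroke_tia", "vascular_disease", "hypertension", "diabetes"
        )]
        base = builtin_weights("chads_vasc")
        assert derive_weights(rows, base) == derive_weights(rows, base)
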