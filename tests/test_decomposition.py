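import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hct_options as h
from hct_options.decomposition import (
    DecompositionError,
    UnknownLevelError,
    solve_reference_survival,
)

MODES = list(h.DecompositionMode)


def _two_factor_cohort():
    return h.CohortTable(
        donor_type="matched_sibling",
        follow_up_months=36,
        n_total=100,
        age_bins=[h.AgeBin(lower=0, upper=20, count=100)],
        level_fractions={
            "sex": {"F": 0.6, "M": 0.4},
            "conditioning": {"myeloablative": 0.5, "reduced_intensity": 0.5},
        },
        baseline_outcomes={"graft_failure": 0.10, "OS": 0.90},
    )


def _two_factor_hrs(outcome="graft_failure"):
    return h.HazardRatioTable(
        outcome=outcome,
        entries={
            "sex": {"F": 1.0, "M": 1.5},
            "conditioning": {"myeloablative": 1.0, "reduced_intensity": 2.0},
        },
    )


@st.composite
def _decomposition_instance(draw):
    n_levels = draw(st.integers(min_value=2, max_value=4))
    weights = draw(st.lists(
        st.floats(min_value=0.05, max_value=1.0), min_size=n_levels, max_size=n_levels))
    total = sum(weights)
    fractions = {f"L{i}": w / total for i, w in enumerate(weights)}
    hrs = {f"L{i}": draw(st.floats(min_value=0.2, max_value=5.0))
           for i in range(n_levels)}
    r = draw(st.floats(min_value=0.0, max_value=1.0))
    return fractions, hrs, r


class TestSingleFactor:
    @pytest.mark.parametrize("mode", MODES)
    def test_identity_hazard_ratios_leave_risk_unchanged(self, mode):
        out = h.decompose_single_factor(
            0.12, {"a": 0.3, "b": 0.7}, {"a": 1.0, "b": 1.0}, mode)
        for r in out.risks.values():
            assert r == pytest.approx(0.12, abs=1e-10)
        assert not out.clamped

    def test_relative_risk_half_half_doubling(self):
        out = h.decompose_single_factor(
            0.12, {"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 2.0},
            h.DecompositionMode.RELATIVE_RISK)
        assert out.risks["a"] == pytest.approx(0.08, abs=1e-12)
        assert out.risks["b"] == pytest.approx(0.16, abs=1e-12)
        mixture = 0.5 * out.risks["a"] + 0.5 * out.risks["b"]
        assert mixture == pytest.approx(0.12, abs=1e-12)

    def test_proportional_hazards_matches_quadratic_closed_form(self):
        # 0.5 s + 0.5 s^2 = 0.88  =>  s = (-1 + sqrt(1 + 7.04)) / 2
        s_ref_expected = (-1.0 + math.sqrt(1.0 + 4.0 * 2.0 * 0.88)) / 2.0
        out = h.decompose_single_factor(
            0.12, {"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 2.0},
            h.DecompositionMode.PROPORTIONAL_HAZARDS)
        assert 1.0 - out.risks["a"] == pytest.approx(s_ref_expected, abs=1e-10)
        assert 1.0 - out.risks["b"] == pytest.approx(s_ref_expected ** 2, abs=1e-10)

    @pytest.mark.parametrize("mode", MODES)
    def test_zero_cohort_risk_gives_zero_everywhere(self, mode):
        out = h.decompose_single_factor(
            0.0, {"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 2.0}, mode)
        assert all(r == 0.0 for r in out.risks.values())

    def test_certain_event_is_exact_limit_in_proportional_hazards(self):
        # survival-scale endpoints are handled as exact limits, not root-solve
        # failures; the relative-risk algebra instead clamps (and flags) here
        out = h.decompose_single_factor(
            1.0, {"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 2.0},
            h.DecompositionMode.PROPORTIONAL_HAZARDS)
        assert all(r == 1.0 for r in out.risks.values())
        assert not out.clamped

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DecompositionError, match="sum"):
            h.decompose_single_factor(0.1, {"a": 0.5, "b": 0.4}, {"a": 1, "b": 2})
        with pytest.raises(DecompositionError, match="not > 0"):
            h.decompose_single_factor(0.1, {"a": 0.5, "b": 0.5}, {"a": 1, "b": -2})
        with pytest.raises(DecompositionError, match="outside"):
            h.decompose_single_factor(1.2, {"a": 1.0}, {"a": 1.0})

    def test_missing_hazard_ratio_treated_as_one(self, caplog):
        with caplog.at_level("WARNING"):
            out = h.decompose_single_factor(
                0.2, {"a": 0.5, "b": 0.5}, {"a": 1.0})
        assert out.risks["b"] == pytest.approx(0.2)
        assert "treating as 1" in caplog.text

    @given(_decomposition_instance())
    @settings(max_examples=150, derandomize=True)
    def test_mixture_conservation_both_modes(self, instance):
        fractions, hrs, r = instance
        rr = h.decompose_single_factor(r, fractions, hrs,
                                       h.DecompositionMode.RELATIVE_RISK)
        mix = sum(fractions[j] * rr.raw_risks[j] for j in fractions)
        assert mix == pytest.approx(r, abs=1e-12)
        ph = h.decompose_single_factor(r, fractions, hrs,
                                       h.DecompositionMode.PROPORTIONAL_HAZARDS)
        surv_mix = sum(fractions[j] * (1.0 - ph.risks[j]) for j in fractions)
        assert surv_mix == pytest.approx(1.0 - r, abs=1e-10)

    @given(_decomposition_instance())
    @settings(max_examples=100, derandomize=True)
    def test_risks_increase_with_hazard_ratio(self, instance):
        fractions, hrs, r = instance
        if not 1e-9 < r < 1.0 - 1e-9:
            return
        for mode in MODES:
            out = h.decompose_single_factor(r, fractions, hrs, mode)
            ordered = sorted(fractions, key=lambda j: hrs[j])
            for j1, j2 in zip(ordered, ordered[1:]):
                if hrs[j2] > hrs[j1]:
                    assert out.raw_risks[j2] > out.raw_risks[j1]

    @given(_decomposition_instance())
    @settings(max_examples=100, derandomize=True)
    def test_modes_agree_to_first_order_at_small_risk(self, instance):
        fractions, hrs, _ = instance
        r = 1e-3
        rr = h.decompose_single_factor(r, fractions, hrs,
                                       h.DecompositionMode.RELATIVE_RISK)
        ph = h.decompose_single_factor(r, fractions, hrs,
                                       h.DecompositionMode.PROPORTIONAL_HAZARDS)
        for j in fractions:
            assert rr.risks[j] == pytest.approx(ph.risks[j], rel=0.01)


class TestReferenceSurvivalRoot:
    def test_root_matches_dense_grid_search(self):
        fractions = {"a": 0.3, "b": 0.45, "c": 0.25}
        exponents = {"a": 1.0, "b": 2.5, "c": 0.6}
        for s in (0.15, 0.5, 0.88, 0.999):
            root = solve_reference_survival(fractions, exponents, s)
            xs = np.linspace(0.0, 1.0, 1_000_001)
            mix = sum(fractions[j] * xs ** exponents[j] for j in fractions)
            grid_root = xs[np.argmin(np.abs(mix - s))]
            assert root == pytest.approx(grid_root, abs=2e-6)
            assert sum(fractions[j] * root ** exponents[j]
                       for j in fractions) == pytest.approx(s, abs=1e-10)


class TestCombinations:
    def test_all_reference_identity(self):
        cohort = _two_factor_cohort()
        hr = h.HazardRatioTable(
            outcome="graft_failure",
            entries={"sex": {"F": 1.0, "M": 1.0},
                     "conditioning": {"myeloablative": 1.0, "reduced_intensity": 1.0}},
            reference_levels={"sex": "F", "conditioning": "myeloablative"},
        )
        combo = {"sex": "F", "conditioning": "myeloablative"}
        for mode in MODES:
            assert h.combination_multiplier(cohort, hr, combo, mode) == pytest.approx(1.0)

    def test_relative_risk_multiplier_hand_arithmetic(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        combo = {"sex": "M", "conditioning": "reduced_intensity"}
        mult = h.combination_multiplier(cohort, hr, combo,
                                        h.DecompositionMode.RELATIVE_RISK)
        # (1.5 / (0.6 + 0.4*1.5)) * (2 / (0.5 + 0.5*2)) = (1.5/1.2)*(2/1.5)
        assert mult == pytest.approx((1.5 / 1.2) * (2.0 / 1.5), abs=1e-12)
        assert mult == pytest.approx(1.6667, abs=5e-5)

    def test_proportional_hazards_multiplier_is_product_of_ratios(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        combo = {"sex": "M", "conditioning": "reduced_intensity"}
        mult = h.combination_multiplier(cohort, hr, combo,
                                        h.DecompositionMode.PROPORTIONAL_HAZARDS)
        assert mult == pytest.approx(3.0)

    def test_single_factor_combo_reduces_to_decomposition_ratio(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        out = h.decompose_single_factor(
            0.10, cohort.level_fractions["sex"], hr.entries["sex"],
            h.DecompositionMode.RELATIVE_RISK)
        mult = h.combination_multiplier(cohort, hr, {"sex": "M"},
                                        h.DecompositionMode.RELATIVE_RISK)
        assert out.risks["M"] / 0.10 == pytest.approx(mult, abs=1e-12)

    def test_risk_for_combination_hand_value(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        combo = {"sex": "M", "conditioning": "reduced_intensity"}
        risk = h.risk_for_combination(cohort, hr, combo,
                                      mode=h.DecompositionMode.RELATIVE_RISK)
        assert risk == pytest.approx(0.10 * (1.5 / 1.2) * (2.0 / 1.5), abs=1e-12)
        assert risk == pytest.approx(0.1667, abs=5e-5)
        assert not risk.clamped

    def test_zero_baseline_stays_zero(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        combo = {"sex": "M", "conditioning": "reduced_intensity"}
        for mode in MODES:
            risk = h.risk_for_combination(
                cohort, hr, combo, mode=mode, baseline_event_probability=0.0)
            assert float(risk) == 0.0

    def test_clamp_at_one_is_flagged(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        combo = {"sex": "M", "conditioning": "reduced_intensity"}
        risk = h.risk_for_combination(
            cohort, hr, combo, mode=h.DecompositionMode.RELATIVE_RISK,
            baseline_event_probability=0.9)
        assert float(risk) == 1.0
        assert risk.clamped

    def test_proportional_hazards_never_clamps(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        combo = {"sex": "M", "conditioning": "reduced_intensity"}
        risk = h.risk_for_combination(
            cohort, hr, combo, mode=h.DecompositionMode.PROPORTIONAL_HAZARDS,
            baseline_event_probability=0.9)
        assert 0.0 <= float(risk) < 1.0
        assert not risk.clamped

    def test_proportional_hazards_joint_mixture_conserved(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        r_base = 0.10
        total = 0.0
        for sex in ("F", "M"):
            for cond in ("myeloablative", "reduced_intensity"):
                risk = h.risk_for_combination(
                    cohort, hr, {"sex": sex, "conditioning": cond},
                    mode=h.DecompositionMode.PROPORTIONAL_HAZARDS,
                    baseline_event_probability=r_base)
                frac = (cohort.level_fractions["sex"][sex]
                        * cohort.level_fractions["conditioning"][cond])
                total += frac * (1.0 - float(risk))
        assert total == pytest.approx(1.0 - r_base, abs=1e-10)

    def test_unknown_level_and_outcome_rejected(self):
        cohort, hr = _two_factor_cohort(), _two_factor_hrs()
        with pytest.raises(UnknownLevelError):
            h.risk_for_combination(cohort, hr, {"sex": "X"})
        with pytest.raises(DecompositionError, match="no baseline"):
            h.risk_for_combination(cohort, _two_factor_hrs("chronic_GVHD"),
                                   {"sex": "M"}, outcome="chronic_GVHD")
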