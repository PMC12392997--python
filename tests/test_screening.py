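"""Strategy grid, schedules, and screening/follow-up round semantics."""

import numpy as np
import pytest

from ugc_cea.natural_history import run_cohort
from ugc_cea.screening import (ScreeningStrategy, apply_follow_up_round,
                               apply_screening_round, build_schedule,
                               enumerate_strategies, make_policy)
from ugc_cea.states import ExpandedSpace

# the published cumulative-screening-count column for all 40 strategies
EXPECTED_COUNTS = {
    "y40_nf_i1": 31, "y40_nf_i2": 16, "y40_nf_i5": 7, "y40_nf_i10": 4,
    "y40_nf_i15": 3, "y40_nf_in": 1, "y40_f_i5": 7, "y40_f_i10": 4,
    "y40_f_i15": 3, "y40_f_in": 1,
    "y45_nf_i1": 26, "y45_nf_i2": 13, "y45_nf_i5": 6, "y45_nf_i10": 3,
    "y45_nf_i15": 2, "y45_nf_in": 1, "y45_f_i5": 6, "y45_f_i10": 3,
    "y45_f_i15": 2, "y45_f_in": 1,
    "y50_nf_i1": 21, "y50_nf_i2": 11, "y50_nf_i5": 5, "y50_nf_i10": 3,
    "y50_nf_i15": 2, "y50_nf_in": 1, "y50_f_i5": 5, "y50_f_i10": 3,
    "y50_f_i15": 2, "y50_f_in": 1,
    "y55_nf_i1": 16, "y55_nf_i2": 8, "y55_nf_i5": 4, "y55_nf_i10": 2,
    "y55_nf_i15": 2, "y55_nf_in": 1, "y55_f_i5": 4, "y55_f_i10": 2,
    "y55_f_i15": 2, "y55_f_in": 1,
}


class TestStrategyGrid:
    def test_exactly_forty_unique_strategies(self):
        strategies = enumerate_strategies()
        codes = [s.code for s in strategies]
        assert len(strategies) == 40
        assert len(set(codes)) == 40
        assert "y40_nf_i2" in codes
        assert "y40_f_i1" not in codes          # no follow-up arm for annual screening
        assert "y40_f_i2" not in codes

    def test_code_round_trip(self):
        for s in enumerate_strategies():
            assert ScreeningStrategy.from_code(s.code) == s

    def test_follow_up_restricted_to_sparse_intervals(self):
        with pytest.raises(ValueError):
            ScreeningStrategy(40, 1, follow_up=True)

    def test_schedule_counts_match_published_column(self):
        for s in enumerate_strategies():
            assert len(build_schedule(s)) == EXPECTED_COUNTS[s.code], s.code

    def test_schedule_contents(self):
        assert build_schedule(ScreeningStrategy(40, 1, False)) == tuple(range(40, 71))
        assert build_schedule(ScreeningStrategy(55, 15, False)) == (55, 70)
        assert build_schedule(ScreeningStrategy(50, "once", True)) == (50,)

    def test_schedule_never_extends_past_seventy(self):
        for s in enumerate_strategies():
            assert max(build_schedule(s)) <= 70


@pytest.fixture()
def exp(base_params):
    return ExpandedSpace(base_params.state_space)


def unit_vector(exp, state, entry=True):
    v = np.zeros(exp.n)
    v[exp.entry_index(state) if entry else exp.index[state]] = 1.0
    return v


class TestScreeningRound:
    def test_zero_compliance_is_inert(self, params, exp):
        params.compliance["screening"].base = 0.0
        policy = make_policy(ScreeningStrategy(40, 5, False), params.state_space)
        v = unit_vector(exp, "cardia_hgin")
        v2, rep = apply_screening_round(v, params, policy, exp)
        assert np.array_equal(v, v2)
        assert rep.screening_cost == 0.0 and rep.treatment_cost == 0.0

    def test_saturated_detection_of_treatable_lesion(self, params, exp):
        params.compliance["screening"].base = 1.0
        params.test["sensitivity"].base = 1.0
        policy = make_policy(ScreeningStrategy(40, 5, False), params.state_space)
        v = unit_vector(exp, "eso_severe_dysplasia_cis")
        v2, rep = apply_screening_round(v, params, policy, exp)
        assert v2[exp.index["post_treatment"]] == pytest.approx(1.0)
        assert rep.screening_cost == pytest.approx(651.36)
        assert rep.treatment_cost == pytest.approx(21950.52)

    def test_detected_fraction_is_compliance_times_sensitivity(self, base_params, exp):
        policy = make_policy(ScreeningStrategy(40, 5, False), base_params.state_space)
        v = unit_vector(exp, "cardia_hgin")
        v2, rep = apply_screening_round(v, base_params, policy, exp)
        assert rep.detections["cardia_hgin"] == pytest.approx(0.6 * 0.96)
        assert v2[exp.index["post_treatment"]] == pytest.approx(0.576)

    def test_mass_conserved(self, base_params, exp):
        rng = np.random.default_rng(0)
        v = rng.dirichlet(np.ones(exp.n))
        policy = make_policy(ScreeningStrategy(40, 5, True), base_params.state_space)
        v2, _ = apply_screening_round(v, base_params, policy, exp)
        assert v2.sum() == pytest.approx(v.sum(), abs=1e-12)
        assert v2.min() >= -1e-15

    def test_low_grade_lesions_enter_surveillance_only_with_follow_up(
            self, base_params, exp):
        v = unit_vector(exp, "gastric_im")
        pol_f = make_policy(ScreeningStrategy(40, 5, True), base_params.state_space)
        v_f, _ = apply_screening_round(v, base_params, pol_f, exp)
        assert v_f[exp.surv_index("gastric_im")] == pytest.approx(0.576)
        pol_nf = make_policy(ScreeningStrategy(40, 5, False), base_params.state_space)
        v_nf, rep = apply_screening_round(v, base_params, pol_nf, exp)
        assert v_nf[exp.surv_index("gastric_im")] == 0.0
        assert np.array_equal(v_nf, v)  # seen but unmanaged

    def test_false_positives_among_healthy_attenders(self, base_params, exp):
        v = unit_vector(exp, "healthy")
        policy = make_policy(ScreeningStrategy(40, 5, False), base_params.state_space)
        _, rep = apply_screening_round(v, base_params, policy, exp)
        assert rep.false_positives == pytest.approx(0.6 * (1 - 0.90))

    def test_advanced_detection_tags_only_new_entries(self, base_params, exp):
        policy = make_policy(ScreeningStrategy(40, 5, False), base_params.state_space)
        v_new = unit_vector(exp, "eso_advanced")          # duration-1: undiagnosed
        _, rep = apply_screening_round(v_new, base_params, policy, exp)
        assert rep.detected_advanced["esophagus"] == pytest.approx(0.576)
        v_old = np.zeros(exp.n)
        v_old[exp.index["eso_advanced_d3"]] = 1.0          # already diagnosed
        _, rep = apply_screening_round(v_old, base_params, policy, exp)
        assert rep.detected_advanced == {}


class TestFollowUpRound:
    def test_requires_follow_up_strategy(self, base_params, exp):
        policy = make_policy(ScreeningStrategy(40, 5, False), base_params.state_space)
        with pytest.raises(ValueError, match="follow-up"):
            apply_follow_up_round(np.zeros(exp.n), base_params, policy, exp)

    def test_surveilled_hgin_managed_at_compliance_times_sensitivity(
            self, base_params, exp):
        policy = make_policy(ScreeningStrategy(40, 5, True), base_params.state_space)
        v = np.zeros(exp.n)
        v[exp.surv_index("cardia_hgin")] = 1.0
        v2, rep = apply_follow_up_round(v, base_params, policy, exp)
        assert rep.detections["cardia_hgin"] == pytest.approx(0.75 * 0.96)
        assert v2[exp.index["post_treatment"]] == pytest.approx(0.72)

    def test_no_surveilled_mass_means_zero_cost(self, base_params, exp):
        policy = make_policy(ScreeningStrategy(40, 5, True), base_params.state_space)
        v = unit_vector(exp, "healthy")
        v2, rep = apply_follow_up_round(v, base_params, policy, exp)
        assert rep.screening_cost == 0.0
        assert np.array_equal(v, v2)

    def test_zero_follow_up_compliance_is_inert(self, params, exp):
        params.compliance["follow_up"].base = 0.0
        policy = make_policy(ScreeningStrategy(40, 5, True), params.state_space)
        v = np.zeros(exp.n)
        v[exp.surv_index("eso_mild_dysplasia")] = 1.0
        v2, rep = apply_follow_up_round(v, params, policy, exp)
        assert np.array_equal(v, v2)
        assert rep.screening_cost == 0.0


class TestScreeningEffects:
    def test_detections_monotone_in_frequency(self, base_params):
        """More frequent screening detects at least as much, per start age."""
        from ugc_cea.natural_history import tally_events
        for start in (40, 55):
            detections = []
            for interval in ("once", 15, 10, 5, 2, 1):
                s = ScreeningStrategy(start, interval, False)
                trace = run_cohort(base_params, make_policy(s, base_params.state_space))
                detections.append(tally_events(trace)["screen_detections"])
            assert all(a <= b + 1e-12 for a, b in zip(detections, detections[1:]))

    def test_zero_sensitivity_matches_natural_history(self, params):
        """A blind test changes nothing but accrues screening costs."""
        params.test["sensitivity"].base = 0.0
        params.test["specificity"].base = 1.0
        s = ScreeningStrategy(40, 5, False)
        screened = run_cohort(params, make_policy(s, params.state_space))
        natural = run_cohort(params)
        assert np.allclose(screened.occupancy, natural.occupancy, atol=1e-12)
        assert screened.cost_screening.sum() > 0.0
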