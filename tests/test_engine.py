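"""Microsimulation engine: event semantics, determinism, analytic oracles."""

import copy

import numpy as np
import pytest

from cxlsim.engine import (
    CONVENTIONAL,
    CXL,
    EngineStateError,
    EyeDraws,
    EyeState,
    PatientState,
    accrue_cycle,
    apply_cxl,
    discount_factor,
    init_cohort,
    run_trial,
    step_eye,
)
from cxlsim.parameters import ModelParams
from conftest import toy_params
from markov_oracle import expected_costs_and_qalys


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(1, 0.05) == pytest.approx(1 / 1.05)
        assert discount_factor(72, 0.05) == pytest.approx(1.05**-72)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


class TestInitCohort:
    def test_degenerate_marginal_all_good(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.initial_va_marginal = [1.0, 0.0, 0.0, 0.0]
        cohort = init_cohort(params, 7)
        assert all(p.better_eye_va == 0 for p in cohort)

    def test_same_seed_identical(self, base_params):
        a = init_cohort(base_params, 123)
        b = init_cohort(base_params, 123)
        assert a == b

    def test_calibrated_fraction_near_target(self, base_params):
        cohort = init_cohort(base_params, 11)
        frac = np.mean([p.better_eye_va == 0 for p in cohort])
        n = base_params.econ.n_patients
        half = 1.96 * np.sqrt(0.799 * 0.201 / n)
        assert abs(frac - 0.799) < half

    def test_full_between_eye_correlation_copies_eyes(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.initial_va_between_eye_corr = 1.0
        cohort = init_cohort(params, 5)
        assert all(p.eyes[0].va_state == p.eyes[1].va_state for p in cohort)


class TestApplyCxl:
    def _patient(self):
        return PatientState(age=18, alive=True, eyes=[EyeState(0), EyeState(1)])

    def test_books_double_eye_cost(self, base_params):
        patient = self._patient()
        cost = apply_cxl(patient, base_params, np.random.default_rng(0))
        assert cost == pytest.approx(2 * 78.52)
        assert all(e.cxl_expiry_cycle == 10 for e in patient.eyes)

    def test_effectiveness_boundaries(self, base_params):
        for eff, expected in [(1.0, True), (0.0, False)]:
            params = base_params.model_copy(deep=True)
            params.cxl.effectiveness = eff
            patient = self._patient()
            apply_cxl(patient, params, np.random.default_rng(0))
            assert all(e.cxl_responder is expected for e in patient.eyes)

    def test_double_application_rejected(self, base_params):
        patient = self._patient()
        apply_cxl(patient, base_params, np.random.default_rng(0))
        with pytest.raises(EngineStateError):
            apply_cxl(patient, base_params, np.random.default_rng(0))


class TestStepEye:
    def test_no_events_is_absorbing(self, base_params):
        params = toy_params(progression=(0.0, 0.0), transplant=(0.0, 0.0))
        eye = EyeState(va_state=0)
        for cycle in range(30):
            ev = step_eye(eye, cycle, params, EyeDraws(0.0, 0.0, 0.0))
            assert ev.cost == 0.0
        assert eye == EyeState(va_state=0)

    def test_certain_progression_reaches_worst_state_in_k_minus_1_cycles(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.progression_prob = [1.0, 1.0, 1.0, 0.0]
        params.transitions.transplant_prob = [0.0] * 4
        eye = EyeState(va_state=0)
        for cycle in range(3):
            step_eye(eye, cycle, params, EyeDraws(progression=0.0))
        assert eye.va_state == 3
        step_eye(eye, 3, params, EyeDraws(progression=0.0))
        assert eye.va_state == 3  # worst state is terminal

    def test_cxl_responder_protected_until_expiry(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.progression_prob = [1.0, 1.0, 1.0, 0.0]
        params.transitions.transplant_prob = [0.0] * 4
        eye = EyeState(va_state=0, cxl_responder=True, cxl_expiry_cycle=10)
        for cycle in range(10):
            step_eye(eye, cycle, params, EyeDraws(progression=0.0))
        assert eye.va_state == 0
        step_eye(eye, 10, params, EyeDraws(progression=0.0))
        assert eye.va_state == 1  # protection lapsed

    def test_transplant_books_cost_and_restores_va(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.transplant_prob = [0.0, 0.0, 0.0, 1.0]
        eye = EyeState(va_state=3)
        ev = step_eye(eye, 0, params, EyeDraws(transplant=0.0))
        assert ev.cost == pytest.approx(414.0)
        assert ev.first_transplant and ev.transplants == 1
        assert eye.transplanted and eye.va_state == 0 and eye.graft_count == 1

    def test_graft_failure_triggers_regraft(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.graft_failure_prob = [1.0]
        eye = EyeState(va_state=0, transplanted=True, graft_age=0, graft_count=1)
        ev = step_eye(eye, 5, params, EyeDraws(graft_failure=0.0))
        assert ev.transplants == 1 and not ev.first_transplant
        assert eye.graft_count == 2 and eye.graft_age == 0

    def test_complication_costs_only_when_enabled(self, base_params):
        params = base_params.model_copy(deep=True)
        params.transitions.transplant_prob = [1.0, 0.0, 0.0, 0.0]
        comp_hit = EyeDraws(transplant=0.0, complications=[0.0] * 6)
        ev_off = step_eye(EyeState(va_state=0), 0, params, comp_hit)
        params.include_complication_costs = True
        ev_on = step_eye(EyeState(va_state=0), 0, params, comp_hit)
        expected_extra = sum(e.cost_point for e in params.complications.entries)
        assert ev_on.cost - ev_off.cost == pytest.approx(expected_extra)


class TestAccrueCycle:
    def test_better_eye_governs_utility(self, base_params):
        patient = PatientState(age=18, alive=True, eyes=[EyeState(0), EyeState(3)])
        _, utility = accrue_cycle(patient, 0, base_params)
        assert utility == pytest.approx(0.92)

    def test_transplant_switches_to_followup_cost(self, base_params):
        eyes = [EyeState(0, transplanted=True, graft_count=1), EyeState(2)]
        patient = PatientState(age=30, alive=True, eyes=eyes)
        cost, _ = accrue_cycle(patient, 0, base_params)
        assert cost == pytest.approx(59.94)

    def test_dead_patient_accrues_nothing(self, base_params):
        patient = PatientState(age=30, alive=False, eyes=[EyeState(0), EyeState(0)])
        assert accrue_cycle(patient, 3, base_params) == (0.0, 0.0)

    def test_discounting_applied(self, base_params):
        patient = PatientState(age=19, alive=True, eyes=[EyeState(0), EyeState(0)])
        cost, utility = accrue_cycle(patient, 1, base_params)
        assert cost == pytest.approx(19.98 / 1.05)
        assert utility == pytest.approx(0.92 / 1.05)


class TestRunTrial:
    def test_determinism(self):
        params = toy_params(n_patients=100)
        a = run_trial(params, 42)
        b = run_trial(params, 42)
        assert np.array_equal(a.cxl.cost, b.cxl.cost)
        assert np.array_equal(a.conventional.qaly, b.conventional.qaly)
        assert a.cxl.total_transplants == b.cxl.total_transplants

    def test_immediate_death_boundary(self):
        params = toy_params(qx=1.0, n_patients=50)
        trial = run_trial(params, 1, arms=(CONVENTIONAL,))
        arm = trial.conventional
        # everyone accrues exactly one (undiscounted) cycle, then dies
        assert np.all(arm.cost == pytest.approx(params.costs.routine_annual))
        utilities = params.utilities.utility_by_better_eye_va
        assert set(np.round(arm.qaly, 12)) <= {round(u, 12) for u in utilities}

    def test_transplant_conservation(self):
        params = toy_params(graft_failure=(0.05,), n_patients=500)
        trial = run_trial(params, 9)
        for arm in (trial.conventional, trial.cxl):
            assert arm.total_transplants >= arm.first_transplants
            assert arm.regrafts == arm.total_transplants - arm.first_transplants
            assert arm.bilateral_patients <= arm.first_transplants

    def test_raising_cost_cannot_decrease_arm_cost(self):
        params = toy_params(n_patients=300)
        base_trial = run_trial(params, 5)
        dearer = params.model_copy(deep=True)
        dearer.costs.transplant = params.costs.transplant * 2
        dearer_trial = run_trial(dearer, 5)
        for arm in (CONVENTIONAL, CXL):
            assert getattr(dearer_trial, arm).mean_cost >= getattr(base_trial, arm).mean_cost

    def test_longer_cxl_effect_reduces_expected_transplants(self, base_params):
        params = base_params.model_copy(deep=True)
        params.econ.n_patients = 100
        longer = params.model_copy(deep=True)
        longer.cxl.effect_duration = 30
        short_tx, long_tx = [], []
        for seed in range(30):
            short_tx.append(run_trial(params, seed, arms=(CXL,)).cxl.total_transplants)
            long_tx.append(run_trial(longer, seed, arms=(CXL,)).cxl.total_transplants)
        assert np.mean(long_tx) <= np.mean(short_tx)

    def test_matches_analytic_markov_expectation(self):
        params = toy_params(n_patients=2000)
        exact_cost, exact_qaly = expected_costs_and_qalys(params)
        trial = run_trial(params, 17, arms=(CONVENTIONAL,))
        arm = trial.conventional
        for observed, exact in [(arm.cost, exact_cost), (arm.qaly, exact_qaly)]:
            se = np.std(observed, ddof=1) / np.sqrt(len(observed))
            assert abs(np.mean(observed) - exact) < 3 * se

    def test_degenerate_cxl_equals_conventional_under_crn(self, base_params):
        params = base_params.model_copy(deep=True)
        params.econ.n_patients = 200
        params.cxl.effectiveness = 0.0
        trial = run_trial(params, 3)
        assert np.array_equal(trial.cxl.qaly, trial.conventional.qaly)
        diff = trial.cxl.cost - trial.conventional.cost
        assert np.max(np.abs(diff - 2 * 78.52)) < 1e-9
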