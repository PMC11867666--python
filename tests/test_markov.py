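"""Transition-matrix construction, cohort propagation and trace summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import small_cohort
from uticea.markov import (
    ArmHazards,
    ConsistencyError,
    State,
    TRANSIENT_STATES,
    bed_days,
    build_transition_matrix,
    inappropriate_person_days,
    result_allocation,
    run_cohort,
)

CLASSES = ("susceptible_appropriate", "resistant_inappropriate", "bsi")


def make_hazards(p_exit=0.0, death_frac=0.0, p_bsi=0.0, sens=0.95, spec=0.85,
                 turnaround=48.0, **per_class):
    """ArmHazards with uniform per-class values unless overridden."""
    exit_map = {c: per_class.get(f"exit_{c}", p_exit) for c in CLASSES}
    death_map = {c: per_class.get(f"death_{c}", death_frac) for c in CLASSES}
    return ArmHazards(
        p_bsi=p_bsi, p_exit=exit_map, death_fraction=death_map,
        sensitivity=sens, specificity=spec, turnaround_h=turnaround,
    )


class TestTransitionMatrix:
    def test_zero_hazards_give_identity(self):
        P = build_transition_matrix(make_hazards(), phase="pre_result")
        np.testing.assert_array_equal(P, np.eye(8))

    @pytest.mark.parametrize("phase", ["rate", "pre_result", "post_result"])
    def test_rows_stochastic(self, default_params, phase):
        for arm in ("culture", "bict"):
            hz = ArmHazards.from_params(default_params, arm)
            P = build_transition_matrix(hz, phase)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all() and (P <= 1).all()

    def test_absorbing_rows_are_identity(self, default_params):
        P = build_transition_matrix(
            ArmHazards.from_params(default_params, "culture")
        )
        for s in (State.WELL, State.DEAD):
            row = np.zeros(8)
            row[s] = 1.0
            np.testing.assert_array_equal(P[s], row)

    def test_geometric_decay_closed_form(self):
        """One transient state, discharge 0.01/h + death 0.002/h:
        P(still in hospital at 24 h) = (1 - 0.012)**24 ~ 0.7486."""
        hz = make_hazards(p_exit=0.012, death_frac=0.002 / 0.012)
        P = build_transition_matrix(hz, phase="pre_result")
        x = np.zeros(8)
        x[State.EMP_APPROPRIATE] = 1.0
        for _ in range(24):
            x = x @ P
        in_hospital = x[[int(s) for s in TRANSIENT_STATES]].sum()
        assert in_hospital == pytest.approx((1 - 0.012) ** 24, rel=1e-12)
        assert in_hospital == pytest.approx(0.74846, abs=1e-5)

    def test_competing_risks_over_one_named_error(self):
        hz = make_hazards(p_exit=0.9, turnaround=2.0)  # 0.9 + 0.5 > 1
        with pytest.raises(ConsistencyError, match="EMP_INAPPROPRIATE"):
            build_transition_matrix(hz, phase="rate")


class TestResultAllocation:
    def test_table_sensitivity_example(self):
        alloc = result_allocation(100, 0, 0.95, 0.85)
        assert alloc[State.POST_APPROPRIATE] == pytest.approx(95.0)
        assert alloc[State.POST_INAPPROPRIATE] == pytest.approx(5.0)

    def test_perfect_specificity_keeps_susceptible_on_empirical(self):
        alloc = result_allocation(0, 100, 0.5, 1.0)
        assert alloc[State.EMP_APPROPRIATE] == 100.0
        assert alloc[State.POST_FALSE_RESISTANT] == 0.0

    def test_perfect_test_no_misallocation(self):
        alloc = result_allocation(100, 100, 1.0, 1.0)
        assert alloc[State.POST_INAPPROPRIATE] == 0.0
        assert alloc[State.POST_FALSE_RESISTANT] == 0.0

    @given(
        resistant=st.floats(0, 1e5), susceptible=st.floats(0, 1e5),
        sens=st.floats(0, 1), spec=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=100)
    def test_mass_conserved(self, resistant, susceptible, sens, spec):
        alloc = result_allocation(resistant, susceptible, sens, spec)
        assert sum(alloc.values()) == pytest.approx(
            resistant + susceptible, rel=1e-12, abs=1e-9
        )


class TestRunCohort:
    def test_zero_cohort_all_zero_trace(self, default_params):
        trace = run_cohort(small_cohort(0.0), default_params, "culture")
        assert trace.occupancy.sum() == 0.0

    def test_mass_conserved_every_cycle(self, default_params):
        params = default_params.with_values({"horizon_h": 2000})
        trace = run_cohort(small_cohort(1000.0), params, "bict")
        totals = trace.occupancy.sum(axis=2)  # (T+1, n_strata)
        np.testing.assert_allclose(totals, 1000.0, rtol=1e-9)

    def test_transient_mass_absorbed_by_horizon(self, default_params,
                                                default_cohort):
        trace = run_cohort(default_cohort, default_params, "culture")
        transient = trace.occupancy[-1, :, [int(s) for s in TRANSIENT_STATES]]
        assert transient.sum() <= 1e-6 * default_cohort.total

    def test_person_hours_geometric_series_limit(self, default_params):
        """Single exit hazard, no BSI/result moves: person-hours -> N / p."""
        params = default_params.with_values(
            {
                "bsi_hourly_rate": 0.0,
                "test_specificity": 1.0,
                "resistance_prevalence.nitrofurantoin": 0.0,
                "los_mean_days.susceptible_appropriate": 4.0,
                "los_mean_days.resistant_inappropriate": 4.0,
            }
        )
        hz = ArmHazards.from_params(params, "culture")
        p = hz.p_exit["susceptible_appropriate"]
        trace = run_cohort(small_cohort(100.0), params, "culture")
        hours = trace.person_hours().sum()
        assert hours == pytest.approx(100.0 / p, rel=1e-6)

    def test_deterministic_inappropriate_day_accounting(self, default_params):
        """100 resistant patients, result at exactly 48 h, perfect
        sensitivity, no exits: exactly 200 inappropriate person-days; a
        halved turnaround gives exactly half."""
        base = default_params.with_values(
            {
                "bsi_hourly_rate": 0.0,
                "test_sensitivity": 1.0,
                "resistance_prevalence.nitrofurantoin": 1.0,
                "inappropriate_rx_proportion": 1.0,
                "los_mean_days.susceptible_appropriate": 1e9,
                "los_mean_days.resistant_inappropriate": 1e9,
                "mortality_fraction.susceptible_appropriate": 0.0,
                "mortality_fraction.resistant_inappropriate": 0.0,
                "horizon_h": 100,
            }
        )
        trace48 = run_cohort(small_cohort(100.0), base, "culture",
                             mode="deterministic")
        assert inappropriate_person_days(trace48) == pytest.approx(200.0, abs=1e-5)
        half = base.with_values({"turnaround_culture_h": 24})
        trace24 = run_cohort(small_cohort(100.0), half, "culture",
                             mode="deterministic")
        assert inappropriate_person_days(trace24) == pytest.approx(100.0, abs=1e-5)

    def test_zero_resistance_zero_inappropriate_days(self, default_params):
        params = default_params.with_values(
            {"resistance_prevalence.nitrofurantoin": 0.0}
        )
        trace = run_cohort(small_cohort(500.0), params, "culture")
        assert inappropriate_person_days(trace) == 0.0

    @pytest.mark.parametrize("mode", ["rate", "deterministic"])
    def test_faster_result_reduces_inappropriate_and_bed_days(
        self, default_params, mode
    ):
        cohort = small_cohort(1000.0)
        params = default_params.with_values({"horizon_h": 3000})
        culture = run_cohort(cohort, params, "culture", mode=mode)
        bict = run_cohort(cohort, params, "bict", mode=mode)
        assert inappropriate_person_days(bict) < inappropriate_person_days(culture)
        assert bed_days(bict) <= bed_days(culture)
        assert bict.deaths().sum() <= culture.deaths().sum()

    def test_higher_sensitivity_fewer_inappropriate_days(self, default_params):
        cohort = small_cohort(1000.0)
        params = default_params.with_values({"horizon_h": 3000})
        lo = params.with_values({"test_sensitivity": 0.75})
        hi = params.with_values({"test_sensitivity": 1.0})
        assert inappropriate_person_days(
            run_cohort(cohort, hi, "culture")
        ) < inappropriate_person_days(run_cohort(cohort, lo, "culture"))

    def test_repeat_runs_bitwise_identical(self, default_params):
        cohort = small_cohort(123.0)
        params = default_params.with_values({"horizon_h": 1500})
        a = run_cohort(cohort, params, "bict")
        b = run_cohort(cohort, params, "bict")
        np.testing.assert_array_equal(a.occupancy, b.occupancy)


class TestMicrosimOracle:
    @pytest.mark.parametrize(
        "field", ["hospital_hours", "inappropriate_hours", "bsi_hours", "died"]
    )
    def test_cohort_expectation_matches_patient_level_simulation(
        self, microsim_comparison, field
    ):
        """The deterministic cohort propagation must agree with an
        independent 50 000-replicate patient-level Monte Carlo within three
        Monte-Carlo standard errors."""
        engine, sim = microsim_comparison
        mean, se = sim.mean_and_se(field)
        assert abs(engine[field] - mean) <= 3 * se, (
            f"{field}: engine {engine[field]:.4f} vs sim {mean:.4f} +/- {se:.4f}"
        )
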