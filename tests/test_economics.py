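"""Cost accumulation, QALY losses, discounting and NMB identities."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_cohort
from uticea.economics import (
    IncrementalResult,
    compute_nmb,
    evaluate_arm,
    qaly_loss_at_death,
)
from uticea.markov import OccupancyTrace, State, run_cohort
from uticea.cohort import Stratum
from uticea.scenarios import run_scenario


class TestQalyLossAtDeath:
    def test_zero_life_expectancy(self):
        assert qaly_loss_at_death(0.0, 1.0, 0.035) == 0.0

    def test_two_year_annuity_at_three_and_a_half_percent(self):
        assert qaly_loss_at_death(2.0, 1.0, 0.035) == pytest.approx(
            1.96618, abs=1e-5
        )

    def test_undiscounted_limit_is_utility_times_years(self):
        assert qaly_loss_at_death(7.25, 0.8, 0.0) == pytest.approx(0.8 * 7.25)

    def test_final_partial_year_prorated(self):
        full = qaly_loss_at_death(3.0, 1.0, 0.035)
        part = qaly_loss_at_death(2.5, 1.0, 0.035)
        assert part == pytest.approx(full - 0.5 / 1.035**2, abs=1e-12)

    def test_monotone_in_life_expectancy(self):
        losses = [qaly_loss_at_death(L, 0.8, 0.035) for L in (1, 5, 20, 60)]
        assert losses == sorted(losses)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            qaly_loss_at_death(-1.0, 1.0, 0.035)


class TestComputeNmb:
    @pytest.mark.parametrize(
        "dc, dq, wtp, expected",
        [
            (0, 0, 20000, 0),
            (-606138, 186, 20000, 4326138),
            (-6826894, 1175, 20000, 30326894),
        ],
    )
    def test_arithmetic(self, dc, dq, wtp, expected):
        assert compute_nmb(dc, dq, wtp) == expected

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            compute_nmb(0, 0, -1)


class TestIncrementalResult:
    def test_nmb_identity_exact(self):
        inc = IncrementalResult.from_deltas(-100.0, 0.5, 20000)
        assert inc.nmb == 20000 * 0.5 - (-100.0)

    @pytest.mark.parametrize(
        "dc, dq, dominant",
        [(-1, 1, True), (-1, 0, True), (0, 1, True), (0, 0, False),
         (1, 1, False), (-1, -0.1, False)],
    )
    def test_dominance_flag(self, dc, dq, dominant):
        assert IncrementalResult.from_deltas(dc, dq, 20000).dominance_flag is dominant


def _bare_params(default_params, **extra):
    """Zero out drug, test and QALY components to isolate one cost channel."""
    zeros = {name: 0.0 for name in default_params
             if name.startswith("drug_cost_per_day")}
    zeros.update(
        cost_standard_test=0.0, cost_bict_test=0.0,
        qaly_decrement_uti_hour=0.0, qaly_decrement_bsi_hour=0.0,
    )
    zeros.update(extra)
    return default_params.with_values(zeros)


class TestEvaluateArm:
    def test_single_patient_general_ward_bed_cost(self, default_params):
        """One patient, 24 h in a general ward, nothing else: 24 x 24.6."""
        params = _bare_params(default_params)
        occ = np.zeros((25, 1, 8))
        occ[:24, 0, State.EMP_APPROPRIATE] = 1.0
        occ[24, 0, State.WELL] = 1.0
        trace = OccupancyTrace(
            occupancy=occ,
            strata=[Stratum("65-100", "F", "uncomplicated")],
            arm="culture",
            initial=np.array([1.0]),
        )
        res = evaluate_arm(trace, params)
        assert res.total_cost == pytest.approx(24 * 24.6, abs=1e-9)
        assert res.total_qalys_lost == 0.0
        assert res.bed_days == pytest.approx(1.0)

    def test_zero_cohort_zero_cost(self, default_params):
        trace = run_cohort(small_cohort(0.0), default_params, "culture")
        res = evaluate_arm(trace, default_params)
        assert res.total_cost == 0.0
        assert res.total_qalys_lost == 0.0

    def test_components_sum_to_total(self, default_params):
        trace = run_cohort(small_cohort(200.0), default_params, "bict")
        res = evaluate_arm(trace, default_params)
        assert sum(res.cost_components.values()) == pytest.approx(
            res.total_cost, rel=1e-12
        )
        assert res.total_cost > 0

    def test_equal_test_costs_equal_diagnostic_component(
        self, default_params
    ):
        """With the rapid test priced at the standard test, the diagnostics
        component is identical in both arms."""
        cohort = small_cohort(500.0)
        comp = {}
        for arm in ("culture", "bict"):
            trace = run_cohort(cohort, default_params, arm)
            comp[arm] = evaluate_arm(trace, default_params).cost_components[
                "diagnostics"
            ]
        assert comp["culture"] == comp["bict"]

    def test_linearity_in_cohort_mass(self, default_params):
        params = default_params.with_values({"horizon_h": 3000})
        res1 = evaluate_arm(
            run_cohort(small_cohort(100.0), params, "culture"), params
        )
        res3 = evaluate_arm(
            run_cohort(small_cohort(300.0), params, "culture"), params
        )
        assert res3.total_cost == pytest.approx(3 * res1.total_cost, rel=1e-9)
        assert res3.total_qalys_lost == pytest.approx(
            3 * res1.total_qalys_lost, rel=1e-9
        )

    def test_doubling_deaths_doubles_mortality_qaly_component(
        self, default_params
    ):
        """With in-state decrements zeroed, QALY loss is linear in deaths."""
        params = _bare_params(default_params)
        occ = np.zeros((2, 1, 8))
        occ[0, 0, State.EMP_APPROPRIATE] = 1.0
        occ[1, 0, State.DEAD] = 1.0
        stratum = [Stratum("16-64", "F", "uncomplicated")]
        one = evaluate_arm(
            OccupancyTrace(occ, stratum, "culture", np.array([1.0])), params
        )
        two = evaluate_arm(
            OccupancyTrace(occ * 2, stratum, "culture", np.array([2.0])), params
        )
        assert one.total_qalys_lost > 0
        assert two.total_qalys_lost == pytest.approx(
            2 * one.total_qalys_lost, rel=1e-12
        )


class TestEqualArms:
    def test_identical_turnaround_gives_exactly_zero_incrementals(
        self, default_params
    ):
        params = default_params.with_values(
            {"turnaround_bict_h": 48.0, "horizon_h": 3000}
        )
        res = run_scenario("base_population", small_cohort(1000.0), params)
        assert res.incremental.delta_cost == 0.0
        assert res.incremental.delta_qaly == 0.0
        assert res.incremental.nmb == 0.0
        assert res.incremental.dominance_flag is False
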