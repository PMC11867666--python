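"""Shared fixtures and the patient-level Monte-Carlo oracle.

The microsimulation draws individual patient trajectories from the same
hourly hazard primitives the cohort engine uses (exit probability and death
share per state class, BSI probability, result-arrival probability, test
sensitivity/specificity) but with its own, independent sampling logic - no
transition matrix, no cohort propagation - so it can serve as an oracle for
the cohort-expectation engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from uticea import CostEffectivenessModel, build_cohort, load_default_parameters
from uticea.cohort import CohortTable
from uticea.markov import ArmHazards, State, run_cohort
import pandas as pd


@pytest.fixture(scope="session")
def default_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return build_cohort(default_params["bsi_cohort_total"])


@pytest.fixture(scope="session")
def base_result(default_params, default_cohort):
    """Deterministic base-case result, shared across tests (pure function)."""
    from uticea import run_scenario

    return run_scenario("base_population", default_cohort, default_params)


def small_cohort(count: float, age_band="65-100", sex="F",
                 uti_type="uncomplicated") -> CohortTable:
    """Single-stratum cohort table for focused engine tests."""
    return CohortTable(
        pd.DataFrame(
            [{"age_band": age_band, "sex": sex, "uti_type": uti_type,
              "count": count}]
        )
    )


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Per-replicate totals (arrays of length n) from the microsimulation."""

    hospital_hours: np.ndarray
    inappropriate_hours: np.ndarray
    bsi_hours: np.ndarray
    died: np.ndarray

    def mean_and_se(self, field: str) -> tuple[float, float]:
        x = getattr(self, field).astype(float)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def microsimulate(
    hazards: ArmHazards,
    rho: float,
    n: int,
    horizon: int,
    seed: int,
) -> MicrosimResult:
    """Simulate ``n`` independent patients under rate-mode result arrival.

    A fraction ``rho`` starts resistant on inappropriate empirical therapy.
    Event order within an hour (exit-dead, exit-alive, BSI, result) uses
    disjoint sub-intervals of a single uniform draw, matching the competing-
    risk layout of an hourly multinomial transition.
    """
    rng = np.random.default_rng(seed)
    S = State
    state = np.where(rng.random(n) < rho, S.EMP_INAPPROPRIATE, S.EMP_APPROPRIATE)
    state = state.astype(np.int8)

    cls_of = {
        S.EMP_APPROPRIATE: "susceptible_appropriate",
        S.EMP_INAPPROPRIATE: "resistant_inappropriate",
        S.POST_APPROPRIATE: "susceptible_appropriate",
        S.POST_INAPPROPRIATE: "resistant_inappropriate",
        S.POST_FALSE_RESISTANT: "susceptible_appropriate",
        S.BSI: "bsi",
    }
    p_result = 1.0 - np.exp(-1.0 / hazards.turnaround_h)

    hospital = np.zeros(n)
    inappropriate = np.zeros(n)
    bsi_hours = np.zeros(n)

    for _ in range(horizon):
        active = state < S.WELL
        if not active.any():
            break
        hospital[active] += 1
        inappropriate[(state == S.EMP_INAPPROPRIATE)
                      | (state == S.POST_INAPPROPRIATE)] += 1
        bsi_hours[state == S.BSI] += 1

        u = rng.random(n)
        new_state = state.copy()
        for s in (S.EMP_APPROPRIATE, S.EMP_INAPPROPRIATE, S.POST_APPROPRIATE,
                  S.POST_INAPPROPRIATE, S.POST_FALSE_RESISTANT, S.BSI):
            mask = state == s
            if not mask.any():
                continue
            cls = cls_of[s]
            p_exit = hazards.p_exit[cls]
            f_death = hazards.death_fraction[cls]
            uu = u[mask]
            dest = np.full(mask.sum(), int(s), dtype=np.int8)
            edge0 = p_exit * f_death
            edge1 = p_exit
            edge2 = p_exit + (hazards.p_bsi if s != S.BSI else 0.0)
            dest[uu < edge2] = S.BSI
            dest[uu < edge1] = S.WELL
            dest[uu < edge0] = S.DEAD
            if s == S.EMP_INAPPROPRIATE:
                e3 = edge2 + p_result * hazards.sensitivity
                e4 = edge2 + p_result
                sel = (uu >= edge2) & (uu < e3)
                dest[sel] = S.POST_APPROPRIATE
                sel = (uu >= e3) & (uu < e4)
                dest[sel] = S.POST_INAPPROPRIATE
            elif s == S.EMP_APPROPRIATE:
                e3 = edge2 + p_result * (1.0 - hazards.specificity)
                sel = (uu >= edge2) & (uu < e3)
                dest[sel] = S.POST_FALSE_RESISTANT
            new_state[mask] = dest
        state = new_state

    return MicrosimResult(
        hospital_hours=hospital,
        inappropriate_hours=inappropriate,
        bsi_hours=bsi_hours,
        died=(state == S.DEAD).astype(float),
    )


@pytest.fixture(scope="session")
def microsim_comparison(default_params):
    """Cohort-engine expectation vs 50 000-replicate microsimulation.

    Coarse, fast-absorbing parameters: short stays, inflated BSI hazard and
    a 24 h vs 6 h turnaround so every pathway is exercised within a 600 h
    horizon. Returns (per-patient engine expectations, microsim result, n).
    """
    params = default_params.with_values(
        {
            "los_mean_days.susceptible_appropriate": 1.5,
            "los_mean_days.resistant_inappropriate": 2.0,
            "los_mean_days.bsi": 2.5,
            "bsi_hourly_rate": 1e-3,
            "turnaround_culture_h": 24,
            "turnaround_bict_h": 6,
            "horizon_h": 600,
            "resistance_prevalence.nitrofurantoin": 0.30,
            "inappropriate_rx_proportion": 1.0,
        }
    )
    rho = 0.30
    n_cohort = 500.0
    n_reps = 50_000
    cohort = small_cohort(n_cohort)
    trace = run_cohort(cohort, params, "culture")
    hazards = ArmHazards.from_params(params, "culture")
    sim = microsimulate(hazards, rho=rho, n=n_reps, horizon=600, seed=20240901)

    from uticea.markov import (
        bed_days,
        bsi_person_days,
        inappropriate_person_days,
    )

    engine = {
        "hospital_hours": bed_days(trace) * 24.0 / n_cohort,
        "inappropriate_hours": inappropriate_person_days(trace) * 24.0 / n_cohort,
        "bsi_hours": bsi_person_days(trace) * 24.0 / n_cohort,
        "died": float(trace.deaths().sum()) / n_cohort,
    }
    return engine, sim
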