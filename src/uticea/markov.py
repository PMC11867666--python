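"""Hourly-cycle Markov cohort engine.

State space (per stratum, per arm):

* ``EMP_APPROPRIATE`` - susceptible infection on empirical antibiotics;
* ``EMP_INAPPROPRIATE`` - resistant infection on (ineffective) empirical
  antibiotics, awaiting the susceptibility result;
* ``POST_APPROPRIATE`` - switched to an effective second-line agent after a
  true-resistant result;
* ``POST_INAPPROPRIATE`` - resistant but missed by the test (false
  susceptible), still on ineffective treatment;
* ``POST_FALSE_RESISTANT`` - susceptible but flagged resistant (false
  positive), switched unnecessarily to the second-line agent;
* ``BSI`` - progressed to bloodstream infection;
* ``WELL`` / ``DEAD`` - absorbing discharge states.

Every in-hospital UTI state carries a fixed hourly bloodstream-infection
probability, a discharge hazard derived from the state class's mean length
of stay, and a death share applied to each exit. The only difference between
the two arms is the turnaround time of the susceptibility result (48 h
culture vs 5 h rapid test). Result arrival is modelled either as a
memoryless hourly rate 1/turnaround converted to the hourly probability
``1 - exp(-1/turnaround)`` (``mode="rate"``, default) or as a deterministic
reallocation at exactly t = turnaround (``mode="deterministic"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np

from .cohort import (
    CohortTable,
    ExitProfile,
    Stratum,
    exit_profile_from_los,
    resistant_inappropriate_prevalence,
)
from .parameters import (
    ParameterSet,
    daily_prob_to_hourly_prob,
    hourly_rate_to_hourly_prob,
)
from .pathways import Scenario, SCENARIOS, assign_regimen, resistance_prevalence

__all__ = [
    "State",
    "TRANSIENT_STATES",
    "UTI_STATES",
    "INAPPROPRIATE_STATES",
    "ArmHazards",
    "ConsistencyError",
    "build_transition_matrix",
    "result_allocation",
    "run_cohort",
    "OccupancyTrace",
    "inappropriate_person_days",
    "bed_days",
    "bsi_person_days",
]

logger = logging.getLogger(__name__)


class State(IntEnum):
    EMP_APPROPRIATE = 0
    EMP_INAPPROPRIATE = 1
    POST_APPROPRIATE = 2
    POST_INAPPROPRIATE = 3
    POST_FALSE_RESISTANT = 4
    BSI = 5
    WELL = 6
    DEAD = 7


N_STATES = len(State)
TRANSIENT_STATES = tuple(State)[:6]
UTI_STATES = tuple(State)[:5]
INAPPROPRIATE_STATES = (State.EMP_INAPPROPRIATE, State.POST_INAPPROPRIATE)
ABSORBING_STATES = (State.WELL, State.DEAD)

#: exit-profile class used by each transient state
STATE_CLASS_OF = {
    State.EMP_APPROPRIATE: "susceptible_appropriate",
    State.EMP_INAPPROPRIATE: "resistant_inappropriate",
    State.POST_APPROPRIATE: "susceptible_appropriate",
    State.POST_INAPPROPRIATE: "resistant_inappropriate",
    State.POST_FALSE_RESISTANT: "susceptible_appropriate",
    State.BSI: "bsi",
}

_ROW_TOL = 1e-12


class ConsistencyError(RuntimeError):
    """Internal consistency violated (mass not conserved, bad row sums)."""


@dataclass(frozen=True)
class ArmHazards:
    """Hourly hazards for one arm, assembled from a parameter set."""

    p_bsi: float  # hourly probability of progression to BSI
    p_exit: Mapping[str, float]  # hourly exit probability per state class
    death_fraction: Mapping[str, float]  # share of exits that are deaths
    sensitivity: float
    specificity: float
    turnaround_h: float

    @classmethod
    def from_params(
        cls,
        params: ParameterSet,
        arm: str,
        exit_profile: ExitProfile | None = None,
    ) -> "ArmHazards":
        if arm not in ("culture", "bict"):
            raise ValueError(f"unknown arm {arm!r}")
        if exit_profile is None:
            exit_profile = exit_profile_from_los(
                params.group("los_mean_days"), params.group("mortality_fraction")
            )
        turnaround = params[f"turnaround_{arm}_h"]
        if turnaround < 1:
            raise ValueError("turnaround must be at least one cycle (1 h)")
        p_exit = {
            cls_name: daily_prob_to_hourly_prob(daily)
            for cls_name, daily in exit_profile.daily_discharge_prob.items()
        }
        return cls(
            p_bsi=hourly_rate_to_hourly_prob(params["bsi_hourly_rate"]),
            p_exit=p_exit,
            death_fraction=dict(exit_profile.death_fraction),
            sensitivity=params["test_sensitivity"],
            specificity=params["test_specificity"],
            turnaround_h=turnaround,
        )


def build_transition_matrix(hazards: ArmHazards, phase: str = "rate") -> np.ndarray:
    """Hourly transition matrix for one arm.

    ``phase`` is ``"rate"`` (result arrival as an hourly probability
    1/turnaround) or ``"pre_result"`` / ``"post_result"`` for the
    deterministic-arrival mode, where no in-matrix result transition exists
    and the switch is applied as a one-off reallocation at t = turnaround.

    Rows are stochastic to 1e-12; a row whose competing risks exceed 1
    raises :class:`ConsistencyError` naming the state.
    """
    if phase not in ("rate", "pre_result", "post_result"):
        raise ValueError(f"unknown phase {phase!r}")
    P = np.zeros((N_STATES, N_STATES))

    p_result = (
        hourly_rate_to_hourly_prob(1.0 / hazards.turnaround_h)
        if phase == "rate"
        else 0.0
    )

    for s in TRANSIENT_STATES:
        cls_name = STATE_CLASS_OF[s]
        p_exit = hazards.p_exit[cls_name]
        f_death = hazards.death_fraction[cls_name]
        row = P[s]
        row[State.WELL] = p_exit * (1.0 - f_death)
        row[State.DEAD] = p_exit * f_death
        if s != State.BSI:
            row[State.BSI] = hazards.p_bsi
        if s == State.EMP_INAPPROPRIATE:
            row[State.POST_APPROPRIATE] = p_result * hazards.sensitivity
            row[State.POST_INAPPROPRIATE] = p_result * (1.0 - hazards.sensitivity)
        elif s == State.EMP_APPROPRIATE:
            # a (false) resistant result switches susceptible patients to the
            # second line; a susceptible result leaves them in place
            row[State.POST_FALSE_RESISTANT] = p_result * (1.0 - hazards.specificity)
        off_diag = row.sum()
        if off_diag > 1.0 + _ROW_TOL:
            raise ConsistencyError(
                f"competing risks sum to {off_diag:.6f} > 1 in state {State(s).name}"
            )
        row[s] = max(0.0, 1.0 - off_diag)

    for s in ABSORBING_STATES:
        P[s, s] = 1.0

    err = np.abs(P.sum(axis=1) - 1.0).max()
    if err > _ROW_TOL:
        raise ConsistencyError(f"row sums deviate from 1 by {err:.2e}")
    return P


def result_allocation(
    resistant_mass: float,
    susceptible_mass: float,
    sensitivity: float,
    specificity: float,
) -> dict[State, float]:
    """Allocate cohort mass on result arrival.

    Resistant mass tests resistant (true positive) with probability
    ``sensitivity`` and moves to the second line; otherwise it is missed.
    Susceptible mass tests susceptible with probability ``specificity`` and
    stays on empirical treatment; otherwise it is switched unnecessarily.
    Total mass is conserved exactly.
    """
    if resistant_mass < 0 or susceptible_mass < 0:
        raise ValueError("masses must be non-negative")
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return {
        State.POST_APPROPRIATE: resistant_mass * sensitivity,
        State.POST_INAPPROPRIATE: resistant_mass * (1.0 - sensitivity),
        State.EMP_APPROPRIATE: susceptible_mass * specificity,
        State.POST_FALSE_RESISTANT: susceptible_mass * (1.0 - specificity),
    }


@dataclass
class OccupancyTrace:
    """Cohort mass per (hour, stratum, state) for one arm.

    ``occupancy[t, s, k]`` is the mass of stratum ``s`` in state ``k`` during
    cycle ``t`` (equivalently at the start of hour ``t``); the last slice
    ``occupancy[horizon]`` is the terminal allocation. Person-hours in a
    state are the sum of its occupancy over cycles ``0 .. horizon-1``.
    """

    occupancy: np.ndarray  # (horizon+1, n_strata, n_states)
    strata: list[Stratum]
    arm: str
    initial: np.ndarray  # (n_strata,) initial masses

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def person_hours(self, states=TRANSIENT_STATES) -> np.ndarray:
        """Person-hours per stratum summed over the given states."""
        idx = [int(s) for s in states]
        return self.occupancy[:-1, :, idx].sum(axis=(0, 2))

    def state_person_hours(self) -> np.ndarray:
        """(n_strata, n_states) person-hours; absorbing columns are zeroed."""
        hours = self.occupancy[:-1].sum(axis=0)
        hours[:, [int(s) for s in ABSORBING_STATES]] = 0.0
        return hours

    def deaths(self) -> np.ndarray:
        return self.occupancy[-1, :, State.DEAD].copy()

    def discharged_alive(self) -> np.ndarray:
        return self.occupancy[-1, :, State.WELL].copy()

    def to_frame(self):
        """Long-format export (stratum, arm, state, hour, mass)."""
        import pandas as pd

        T, S, K = self.occupancy.shape
        hours, strata_i, states_i = np.meshgrid(
            np.arange(T), np.arange(S), np.arange(K), indexing="ij"
        )
        return pd.DataFrame(
            {
                "age_band": [self.strata[i].age_band for i in strata_i.ravel()],
                "sex": [self.strata[i].sex for i in strata_i.ravel()],
                "uti_type": [self.strata[i].uti_type for i in strata_i.ravel()],
                "arm": self.arm,
                "state": [State(k).name for k in states_i.ravel()],
                "hour": hours.ravel(),
                "mass": self.occupancy.ravel(),
            }
        )


def initial_allocation(
    cohort: CohortTable, params: ParameterSet, scenario: Scenario
) -> tuple[np.ndarray, list[Stratum]]:
    """Initial state allocation per stratum.

    A share ``resistance prevalence x inappropriate-prescribing proportion``
    of each stratum starts resistant on ineffective empirical treatment; the
    remainder starts susceptible on effective empirical treatment.
    """
    strata = cohort.strata()
    counts = cohort.counts()
    x0 = np.zeros((len(strata), N_STATES))
    inappropriate = params["inappropriate_rx_proportion"]
    for i, stratum in enumerate(strata):
        reg = assign_regimen(stratum, scenario)
        prev = resistance_prevalence(scenario, reg.empirical_abx, params)
        rho = resistant_inappropriate_prevalence(prev, inappropriate)
        x0[i, State.EMP_INAPPROPRIATE] = counts[i] * rho
        x0[i, State.EMP_APPROPRIATE] = counts[i] * (1.0 - rho)
    return x0, strata


def run_cohort(
    cohort: CohortTable,
    params: ParameterSet,
    arm: str,
    scenario: Scenario | None = None,
    mode: str = "rate",
) -> OccupancyTrace:
    """Propagate the cohort hour by hour to the horizon.

    Deterministic given its inputs. Mass is conservation-checked at every
    cycle (1e-9 relative); any transient mass left at the horizon (expected
    < 1e-6 of the cohort) is force-discharged alive and logged.
    """
    if mode not in ("rate", "deterministic"):
        raise ValueError(f"unknown mode {mode!r}")
    scenario = scenario or SCENARIOS["base_population"]
    horizon = int(params["horizon_h"])
    hazards = ArmHazards.from_params(params, arm)

    x0, strata = initial_allocation(cohort, params, scenario)
    counts = x0.sum(axis=1)
    occ = np.empty((horizon + 1, len(strata), N_STATES))
    occ[0] = x0

    phase = "rate" if mode == "rate" else "pre_result"
    P = build_transition_matrix(hazards, phase)
    switch_t = int(round(hazards.turnaround_h)) if mode == "deterministic" else None

    X = x0.copy()
    tol = 1e-9 * np.maximum(counts, 1e-300)
    for t in range(horizon):
        X = X @ P
        if switch_t is not None and t + 1 == switch_t:
            X = _apply_result_allocation(X, hazards)
            P = build_transition_matrix(hazards, "post_result")
        drift = np.abs(X.sum(axis=1) - counts)
        if (drift > tol).any():
            raise ConsistencyError(
                f"mass conservation violated at hour {t + 1}: "
                f"max drift {drift.max():.3e}"
            )
        occ[t + 1] = X

    leftover = X[:, [int(s) for s in TRANSIENT_STATES]].sum()
    total = counts.sum()
    if leftover > 0:
        if total > 0 and leftover > 1e-6 * total:
            logger.warning(
                "transient mass %.3e (%.2e of cohort) remained at the horizon; "
                "force-discharging alive", leftover, leftover / total,
            )
        else:
            logger.debug("force-discharging %.3e leftover transient mass", leftover)
        final = occ[horizon].copy()
        for s in TRANSIENT_STATES:
            final[:, State.WELL] += final[:, s]
            final[:, s] = 0.0
        occ[horizon] = final

    return OccupancyTrace(occupancy=occ, strata=strata, arm=arm, initial=counts)


def _apply_result_allocation(X: np.ndarray, hazards: ArmHazards) -> np.ndarray:
    """One-off reallocation of the empirical states at t = turnaround."""
    out = X.copy()
    resistant = X[:, State.EMP_INAPPROPRIATE]
    susceptible = X[:, State.EMP_APPROPRIATE]
    out[:, State.EMP_INAPPROPRIATE] = 0.0
    out[:, State.EMP_APPROPRIATE] = susceptible * hazards.specificity
    out[:, State.POST_FALSE_RESISTANT] += susceptible * (1.0 - hazards.specificity)
    out[:, State.POST_APPROPRIATE] += resistant * hazards.sensitivity
    out[:, State.POST_INAPPROPRIATE] += resistant * (1.0 - hazards.sensitivity)
    return out


# ---------------------------------------------------------------------------
# trace summaries
# ---------------------------------------------------------------------------


def inappropriate_person_days(trace: OccupancyTrace, per_stratum: bool = False):
    """Person-days on inappropriate (ineffective) antibiotics."""
    days = trace.person_hours(INAPPROPRIATE_STATES) / 24.0
    return days if per_stratum else float(days.sum())


def bed_days(trace: OccupancyTrace, per_stratum: bool = False):
    """Person-days across all in-hospital states."""
    days = trace.person_hours(TRANSIENT_STATES) / 24.0
    return days if per_stratum else float(days.sum())


def bsi_person_days(trace: OccupancyTrace, per_stratum: bool = False):
    """Person-days in the bloodstream-infection state."""
    days = trace.person_hours((State.BSI,)) / 24.0
    return days if per_stratum else float(days.sum())
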