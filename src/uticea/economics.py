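"""Costs, QALY losses and cost-effectiveness summary measures.

Costs (2022 GBP, NHS perspective) comprise blended hospital bed costs (an
ICU/general-ward weighted hourly rate by state class), antibiotic costs per
drug-day split by current regimen (empirical vs second line), and a one-off
susceptibility-test cost per patient entering the model. QALY losses
comprise hourly utility decrements while in UTI or BSI states plus, for each
death, the discounted remaining quality-adjusted life expectancy at the age
band midpoint. Only death-related losses extend beyond a year, so only they
are discounted (3.5% per annum); all other costs and effects accrue
undiscounted within the admission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .markov import (
    INAPPROPRIATE_STATES,
    OccupancyTrace,
    State,
    TRANSIENT_STATES,
    UTI_STATES,
)
from .parameters import ParameterSet, blended_bed_cost_hour
from .pathways import Scenario, SCENARIOS, assign_regimen

__all__ = [
    "EconResult",
    "IncrementalResult",
    "qaly_loss_at_death",
    "compute_nmb",
    "evaluate_arm",
    "incremental",
]

#: states billed at the empirical antibiotic's daily cost
_EMPIRICAL_STATES = (
    State.EMP_APPROPRIATE,
    State.EMP_INAPPROPRIATE,
    State.POST_INAPPROPRIATE,  # missed by the test, still on empirical drugs
)
#: states billed at the second-line antibiotic's daily cost
_SECOND_LINE_STATES = (State.POST_APPROPRIATE, State.POST_FALSE_RESISTANT)

_ICU_PROP_KEY = {
    "uncomplicated": "prop_icu_uncomplicated",
    "complicated_oral": "prop_icu_complicated",
    "complicated_iv": "prop_icu_complicated",
}

_LIFE_EXPECTANCY_KEY = {
    "16-64": "life_expectancy_years.age_16_64",
    "65-100": "life_expectancy_years.age_65_100",
}


def qaly_loss_at_death(
    life_expectancy_remaining: float,
    utility: float = 1.0,
    annual_discount: float = 0.035,
) -> float:
    """Discounted quality-adjusted life years lost by one death.

    Sums ``utility / (1 + d)^t`` over whole remaining years ``t = 0, 1, ...``
    with the final partial year prorated, so an undiscounted loss equals
    ``utility * L`` exactly.
    """
    L = life_expectancy_remaining
    if L < 0 or utility < 0 or annual_discount < 0:
        raise ValueError("inputs must be non-negative")
    if L == 0:
        return 0.0
    whole = int(math.floor(L))
    d = 1.0 + annual_discount
    if annual_discount == 0:
        total = float(whole)
    else:
        total = (1.0 - d ** -whole) / (1.0 - 1.0 / d)
    frac = L - whole
    if frac > 0:
        total += frac * d ** -whole
    return utility * total


def compute_nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * delta_qaly - delta_cost``."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return wtp * delta_qaly - delta_cost


@dataclass
class EconResult:
    """Economic outcomes of one arm (totals over the evaluated cohort)."""

    total_cost: float
    cost_components: dict[str, float]
    total_qalys_lost: float
    bed_days: float
    icu_weighted_bed_days: float
    inappropriate_days: float
    bsi_person_days: float
    deaths: float
    per_stratum: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        for name in (
            "total_cost", "total_qalys_lost", "bed_days",
            "icu_weighted_bed_days", "inappropriate_days",
            "bsi_person_days", "deaths",
        ):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be non-negative")
        comp_sum = sum(self.cost_components.values())
        if abs(comp_sum - self.total_cost) > 1e-6 * max(abs(self.total_cost), 1.0):
            raise ValueError(
                f"cost components sum to {comp_sum:.6f} != total {self.total_cost:.6f}"
            )


@dataclass(frozen=True)
class IncrementalResult:
    """Rapid-test arm vs culture arm: cost difference, QALY gain, NMB."""

    delta_cost: float  # bict - culture (negative = cost saving)
    delta_qaly: float  # culture losses - bict losses (positive = gain)
    nmb: float
    dominance_flag: bool

    @classmethod
    def from_deltas(
        cls, delta_cost: float, delta_qaly: float, wtp: float
    ) -> "IncrementalResult":
        dominant = (
            delta_cost <= 0
            and delta_qaly >= 0
            and (delta_cost < 0 or delta_qaly > 0)
        )
        return cls(
            delta_cost=delta_cost,
            delta_qaly=delta_qaly,
            nmb=compute_nmb(delta_cost, delta_qaly, wtp),
            dominance_flag=dominant,
        )


def evaluate_arm(
    trace: OccupancyTrace,
    params: ParameterSet,
    scenario: Scenario | None = None,
) -> EconResult:
    """Convert an occupancy trace into costs, QALY losses and day counts."""
    scenario = scenario or SCENARIOS["base_population"]
    hours = trace.state_person_hours()  # (n_strata, n_states)
    drug_costs = params.group("drug_cost_per_day")
    c_general = params["cost_bed_hour_general"]
    c_icu = params["cost_bed_hour_icu"]
    bsi_bed_rate = blended_bed_cost_hour(params["prop_icu_bsi"], c_general, c_icu)
    test_cost = params[
        "cost_bict_test" if trace.arm == "bict" else "cost_standard_test"
    ]
    dec_uti = params["qaly_decrement_uti_hour"]
    dec_bsi = params["qaly_decrement_bsi_hour"]
    utility = params["utility_norm"]
    discount = params["discount_rate_annual"]

    uti_idx = [int(s) for s in UTI_STATES]
    emp_idx = [int(s) for s in _EMPIRICAL_STATES]
    second_idx = [int(s) for s in _SECOND_LINE_STATES]
    inapp_idx = [int(s) for s in INAPPROPRIATE_STATES]

    rows = []
    deaths = trace.deaths()
    for i, stratum in enumerate(trace.strata):
        reg = assign_regimen(stratum, scenario)
        prop_icu = params[_ICU_PROP_KEY[stratum.uti_type]]
        uti_bed_rate = blended_bed_cost_hour(prop_icu, c_general, c_icu)

        uti_hours = hours[i, uti_idx].sum()
        bsi_hours = hours[i, State.BSI]
        bed_cost = uti_hours * uti_bed_rate + bsi_hours * bsi_bed_rate

        try:
            c_emp = drug_costs[reg.empirical_cost_key]
            c_second = drug_costs[reg.second_line_cost_key]
        except KeyError as e:
            raise KeyError(
                f"no daily drug cost configured for {e.args[0]!r} "
                f"(stratum {stratum.key})"
            ) from None
        drug_cost = (
            hours[i, emp_idx].sum() / 24.0 * c_emp
            + hours[i, second_idx].sum() / 24.0 * c_second
        )
        diag_cost = trace.initial[i] * test_cost

        le_key = _LIFE_EXPECTANCY_KEY[stratum.age_band]
        death_loss = deaths[i] * qaly_loss_at_death(
            params[le_key], utility, discount
        )
        qaly_lost = uti_hours * dec_uti + bsi_hours * dec_bsi + death_loss

        rows.append(
            {
                "age_band": stratum.age_band,
                "sex": stratum.sex,
                "uti_type": stratum.uti_type,
                "arm": trace.arm,
                "bed_cost": bed_cost,
                "drug_cost": drug_cost,
                "test_cost": diag_cost,
                "total_cost": bed_cost + drug_cost + diag_cost,
                "qalys_lost": qaly_lost,
                "bed_days": hours[i, [int(s) for s in TRANSIENT_STATES]].sum() / 24.0,
                "icu_weighted_bed_days": (
                    uti_hours * prop_icu + bsi_hours * params["prop_icu_bsi"]
                )
                / 24.0,
                "inappropriate_days": hours[i, inapp_idx].sum() / 24.0,
                "bsi_person_days": bsi_hours / 24.0,
                "deaths": deaths[i],
            }
        )

    frame = pd.DataFrame(rows)
    components = {
        "bed": float(frame["bed_cost"].sum()),
        "antibiotics": float(frame["drug_cost"].sum()),
        "diagnostics": float(frame["test_cost"].sum()),
    }
    return EconResult(
        total_cost=sum(components.values()),
        cost_components=components,
        total_qalys_lost=float(frame["qalys_lost"].sum()),
        bed_days=float(frame["bed_days"].sum()),
        icu_weighted_bed_days=float(frame["icu_weighted_bed_days"].sum()),
        inappropriate_days=float(frame["inappropriate_days"].sum()),
        bsi_person_days=float(frame["bsi_person_days"].sum()),
        deaths=float(frame["deaths"].sum()),
        per_stratum=frame,
    )


def incremental(
    culture: EconResult, bict: EconResult, wtp: float
) -> IncrementalResult:
    """Incremental result of the rapid-test arm over the culture arm."""
    return IncrementalResult.from_deltas(
        delta_cost=bict.total_cost - culture.total_cost,
        delta_qaly=culture.total_qalys_lost - bict.total_qalys_lost,
        wtp=wtp,
    )
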