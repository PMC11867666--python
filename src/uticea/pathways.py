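"""Treatment pathways and modelled scenarios.

Maps each cohort stratum to its empirical antibiotic, second-line antibiotic
and administration route (guideline-style defaults), and defines the four
named scenarios: base case at population level, base case per patient, low
trimethoprim resistance (trimethoprim replaces nitrofurantoin as the
uncomplicated empirical agent) and a hypothetical 40%-resistance-to-
everything scenario. Only resistance to the *empirical* antibiotic enters
the model; second-line agents are assumed effective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .cohort import CohortTable, Stratum, all_strata
from .parameters import ParameterSet

__all__ = [
    "Regimen",
    "Scenario",
    "SCENARIOS",
    "get_scenario",
    "assign_regimen",
    "annotate_cohort",
    "resistance_prevalence",
    "pathways_table",
]


@dataclass(frozen=True)
class Regimen:
    """Empirical and second-line antibiotic choice for one stratum."""

    empirical_abx: str
    second_line_abx: str
    route: str  # "oral" or "intravenous"
    #: keys into the drug_cost_per_day parameter group
    empirical_cost_key: str = ""
    second_line_cost_key: str = ""

    def __post_init__(self):
        if self.route not in ("oral", "intravenous"):
            raise ValueError(f"unknown route {self.route!r}")
        object.__setattr__(
            self, "empirical_cost_key", self.empirical_cost_key or self.empirical_abx
        )
        object.__setattr__(
            self,
            "second_line_cost_key",
            self.second_line_cost_key or self.second_line_abx,
        )


@dataclass(frozen=True)
class Scenario:
    """A named analysis scenario.

    ``resistance_prevalence`` overrides the base prevalence per antibiotic
    (``None`` entries fall back to the parameter set); ``cohort_scale`` is
    ``None`` for the full population or a number (1 for per-patient results);
    ``empirical_uncomplicated`` selects the uncomplicated empirical agent.
    """

    name: str
    resistance_prevalence: Mapping[str, float] = field(default_factory=dict)
    cohort_scale: float | None = None
    empirical_uncomplicated: str = "nitrofurantoin"
    uniform_resistance: float | None = None


_BASE = Scenario(name="base_population")
SCENARIOS: dict[str, Scenario] = {
    "base_population": _BASE,
    "base_per_patient": Scenario(name="base_per_patient", cohort_scale=1.0),
    "low_trimethoprim": Scenario(
        name="low_trimethoprim", empirical_uncomplicated="trimethoprim"
    ),
    "high_resistance": Scenario(name="high_resistance", uniform_resistance=0.40),
}

#: short aliases accepted by the CLI
SCENARIO_ALIASES = {
    "base": "base_population",
    "per_patient": "base_per_patient",
    "low_tmp": "low_trimethoprim",
    "high_res": "high_resistance",
}


def get_scenario(name: str) -> Scenario:
    key = SCENARIO_ALIASES.get(name, name)
    try:
        return SCENARIOS[key]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
        ) from None


def assign_regimen(stratum: Stratum, scenario: Scenario = _BASE) -> Regimen:
    """Deterministic stratum -> regimen mapping.

    Uncomplicated UTI: oral nitrofurantoin (trimethoprim in the
    low-trimethoprim scenario), second line pivmecillinam. Complicated oral:
    cefalexin then oral co-amoxiclav. Complicated IV: gentamicin then
    intravenous co-amoxiclav.
    """
    if stratum.uti_type == "uncomplicated":
        emp = scenario.empirical_uncomplicated
        return Regimen(emp, "pivmecillinam", "oral")
    if stratum.uti_type == "complicated_oral":
        return Regimen(
            "cefalexin", "co-amoxiclav", "oral",
            second_line_cost_key="co_amoxiclav_oral",
        )
    if stratum.uti_type == "complicated_iv":
        return Regimen(
            "gentamicin", "co-amoxiclav", "intravenous",
            empirical_cost_key="gentamicin_iv",
            second_line_cost_key="co_amoxiclav_iv",
        )
    raise ValueError(f"unknown stratum {stratum!r}")  # pragma: no cover


def resistance_prevalence(
    scenario: Scenario, antibiotic: str, params: ParameterSet
) -> float:
    """Resistance prevalence to an empirical antibiotic under a scenario."""
    known = sorted(params.group("resistance_prevalence"))
    if antibiotic not in known:
        raise KeyError(
            f"unknown antibiotic {antibiotic!r}; known empirical agents: {known}"
        )
    if scenario.uniform_resistance is not None:
        return scenario.uniform_resistance
    if antibiotic in scenario.resistance_prevalence:
        return scenario.resistance_prevalence[antibiotic]
    return params[f"resistance_prevalence.{antibiotic}"]


def annotate_cohort(
    cohort: CohortTable, scenario: Scenario = _BASE
) -> CohortTable:
    """Fill the regimen columns of a cohort table for a scenario."""
    frame = cohort.frame.copy()
    for i, row in frame.iterrows():
        reg = assign_regimen(Stratum(row.age_band, row.sex, row.uti_type), scenario)
        frame.loc[i, ["empirical_abx", "second_line_abx", "route"]] = (
            reg.empirical_abx,
            reg.second_line_abx,
            reg.route,
        )
    return CohortTable(frame)


def pathways_table(params: ParameterSet) -> pd.DataFrame:
    """Long-format pathway export: one row per scenario x stratum."""
    rows = []
    for scen in SCENARIOS.values():
        for stratum in all_strata():
            reg = assign_regimen(stratum, scen)
            rows.append(
                {
                    "scenario": scen.name,
                    "age_band": stratum.age_band,
                    "sex": stratum.sex,
                    "uti_type": stratum.uti_type,
                    "empirical_abx": reg.empirical_abx,
                    "route": reg.route,
                    "second_line_abx": reg.second_line_abx,
                    "resistance_prevalence": resistance_prevalence(
                        scen, reg.empirical_abx, params
                    ),
                }
            )
    return pd.DataFrame(rows)
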