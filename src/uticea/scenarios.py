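"""Paired culture-vs-rapid-test evaluation of the named scenarios.

A scenario run propagates the same cohort under the same parameters through
both arms — identical in everything except the susceptibility-result
turnaround — and assembles population-level and per-stratum incremental
results (cost difference, QALY gain, net monetary benefit, bed days saved,
inappropriate prescribing days avoided). Runs are pure functions of
(scenario, cohort, parameters): repeated calls are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .economics import EconResult, IncrementalResult, evaluate_arm, incremental
from .markov import run_cohort
from .parameters import ParameterSet
from .pathways import Scenario, get_scenario

__all__ = ["ScenarioResult", "run_scenario", "per_patient_results"]

_STRATUM_KEYS = ["age_band", "sex", "uti_type"]


@dataclass
class ScenarioResult:
    """Both arms plus incremental outcomes for one scenario."""

    scenario: Scenario
    culture: EconResult
    bict: EconResult
    incremental: IncrementalResult
    per_stratum: pd.DataFrame
    cohort_total: float
    wtp: float

    def summary(self) -> str:
        inc = self.incremental
        lines = [
            f"Scenario: {self.scenario.name}  (cohort mass {self.cohort_total:,.0f})",
            f"  Total cost      culture £{self.culture.total_cost:,.0f}   "
            f"rapid test £{self.bict.total_cost:,.0f}",
            f"  Incremental cost        £{inc.delta_cost:,.0f}",
            f"  Incremental QALY gain   {inc.delta_qaly:,.1f}",
            f"  NMB (£{self.wtp:,.0f}/QALY)   £{inc.nmb:,.0f}"
            + ("   [dominant]" if inc.dominance_flag else ""),
            f"  Inappropriate days      culture {self.culture.inappropriate_days:,.0f}"
            f" -> rapid test {self.bict.inappropriate_days:,.0f}",
            f"  Bed days saved          "
            f"{self.culture.bed_days - self.bict.bed_days:,.1f}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy population-level export: measure x arm."""
        rows = []
        for arm, res in (("culture", self.culture), ("bict", self.bict)):
            rows += [
                {"scenario": self.scenario.name, "arm": arm, "measure": m, "value": v}
                for m, v in (
                    ("total_cost", res.total_cost),
                    ("total_qalys_lost", res.total_qalys_lost),
                    ("bed_days", res.bed_days),
                    ("inappropriate_days", res.inappropriate_days),
                    ("bsi_person_days", res.bsi_person_days),
                    ("deaths", res.deaths),
                )
            ]
        inc = self.incremental
        rows += [
            {"scenario": self.scenario.name, "arm": "incremental", "measure": m,
             "value": v}
            for m, v in (
                ("delta_cost", inc.delta_cost),
                ("delta_qaly", inc.delta_qaly),
                ("nmb", inc.nmb),
            )
        ]
        return pd.DataFrame(rows)


def run_scenario(
    scenario: Scenario | str,
    cohort: CohortTable,
    params: ParameterSet,
    mode: str = "rate",
) -> ScenarioResult:
    """Evaluate one scenario on both arms and compute incrementals."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if scenario.cohort_scale is not None:
        total = cohort.total
        if total <= 0:
            raise ValueError("cannot rescale an empty cohort")
        cohort = cohort.scaled(scenario.cohort_scale / total)

    wtp = params["wtp"]
    traces = {
        arm: run_cohort(cohort, params, arm, scenario, mode=mode)
        for arm in ("culture", "bict")
    }
    econ = {arm: evaluate_arm(tr, params, scenario) for arm, tr in traces.items()}
    inc = incremental(econ["culture"], econ["bict"], wtp)

    per_stratum = _stratum_incrementals(econ["culture"], econ["bict"], wtp)
    _check_aggregation(per_stratum, inc)
    return ScenarioResult(
        scenario=scenario,
        culture=econ["culture"],
        bict=econ["bict"],
        incremental=inc,
        per_stratum=per_stratum,
        cohort_total=cohort.total,
        wtp=wtp,
    )


def _stratum_incrementals(
    culture: EconResult, bict: EconResult, wtp: float
) -> pd.DataFrame:
    c = culture.per_stratum.set_index(_STRATUM_KEYS)
    b = bict.per_stratum.set_index(_STRATUM_KEYS)
    out = pd.DataFrame(index=c.index)
    out["bed_days_saved"] = c["bed_days"] - b["bed_days"]
    out["inappropriate_days_avoided"] = (
        c["inappropriate_days"] - b["inappropriate_days"]
    )
    out["delta_cost"] = b["total_cost"] - c["total_cost"]
    out["delta_qaly"] = c["qalys_lost"] - b["qalys_lost"]
    out["nmb"] = wtp * out["delta_qaly"] - out["delta_cost"]
    out["deaths_averted"] = c["deaths"] - b["deaths"]
    return out.reset_index()


def _check_aggregation(per_stratum: pd.DataFrame, inc: IncrementalResult) -> None:
    """Per-stratum values must sum to the population incrementals."""
    for col, total in (
        ("delta_cost", inc.delta_cost),
        ("delta_qaly", inc.delta_qaly),
        ("nmb", inc.nmb),
    ):
        s = per_stratum[col].sum()
        if abs(s - total) > 1e-6 * max(abs(total), 1.0):
            raise AssertionError(
                f"stratum {col} sum {s:.6g} != population {total:.6g}"
            )


def per_patient_results(
    result: ScenarioResult, cohort: CohortTable
) -> pd.DataFrame:
    """Per-stratum NMB (and companions) per patient case.

    Divides each stratum's incremental outcomes by its cohort mass. Strata
    with zero mass are reported as NaN (undefined), not zero. By linearity of
    the cohort model this equals running the model with unit mass in the
    stratum.
    """
    if scenario_scale := result.scenario.cohort_scale:
        cohort = cohort.scaled(scenario_scale / cohort.total)
    counts = cohort.frame.set_index(_STRATUM_KEYS)["count"]
    out = result.per_stratum.set_index(_STRATUM_KEYS).copy()
    n = counts.reindex(out.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in ("nmb", "delta_cost", "delta_qaly", "bed_days_saved",
                    "inappropriate_days_avoided"):
            out[f"{col}_per_patient"] = np.where(n > 0, out[col] / n, np.nan)
    out["count"] = n
    return out.reset_index()
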