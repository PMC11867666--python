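"""Model/Results front end for the cost-effectiveness analysis.

`CostEffectivenessModel` bundles a cohort, a parameter set and a scenario;
``fit()`` runs the deterministic paired (culture vs rapid test) evaluation
and returns a :class:`CEResults` carrying the incremental estimates, the
per-stratum breakdowns and a ``summary()`` table; ``fit_psa()`` quantifies
parameter uncertainty and returns a :class:`PSAResultsWrapper` with the
acceptability curve, the cost-effectiveness plane and plotting helpers.

    >>> model = CostEffectivenessModel.from_defaults()
    >>> res = model.fit()
    >>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, build_cohort
from .parameters import ParameterSet, load_default_parameters
from .pathways import Scenario, get_scenario
from .scenarios import ScenarioResult, per_patient_results, run_scenario
from .sensitivity import PSAResults, ceac, run_psa, tornado

__all__ = ["CostEffectivenessModel", "CEResults", "PSAResultsWrapper"]


class CostEffectivenessModel:
    """Markov cohort cost-effectiveness model of rapid susceptibility testing.

    Parameters
    ----------
    cohort : CohortTable
        Patient mass per age-band x sex x UTI-type stratum.
    params : ParameterSet, optional
        Model inputs; defaults to the packaged base-case configuration.
    scenario : str or Scenario
        One of ``base_population`` (default), ``base_per_patient``,
        ``low_trimethoprim``, ``high_resistance``.
    arrival_mode : str
        ``"rate"`` (memoryless result arrival, default) or
        ``"deterministic"`` (switch at exactly t = turnaround).
    """

    def __init__(
        self,
        cohort: CohortTable,
        params: ParameterSet | None = None,
        scenario: Scenario | str = "base_population",
        arrival_mode: str = "rate",
    ):
        self.cohort = cohort
        self.params = params if params is not None else load_default_parameters()
        self.scenario = (
            get_scenario(scenario) if isinstance(scenario, str) else scenario
        )
        self.arrival_mode = arrival_mode

    @classmethod
    def from_defaults(
        cls,
        scenario: Scenario | str = "base_population",
        total: float | None = None,
        age_sex_weights: Mapping | None = None,
        **kwargs,
    ) -> "CostEffectivenessModel":
        """Model on the default synthetic cohort and packaged parameters."""
        params = kwargs.pop("params", None) or load_default_parameters()
        cohort = build_cohort(
            total if total is not None else params["bsi_cohort_total"],
            age_sex_weights,
        )
        return cls(cohort, params, scenario, **kwargs)

    def fit(self) -> "CEResults":
        """Deterministic paired evaluation of both arms."""
        result = run_scenario(
            self.scenario, self.cohort, self.params, mode=self.arrival_mode
        )
        return CEResults(self, result)

    def fit_psa(self, n: int = 1000, seed: int = 0) -> "PSAResultsWrapper":
        """Probabilistic sensitivity analysis with ``n`` joint draws."""
        psa = run_psa(
            n, seed, self.scenario, self.cohort, self.params, mode=self.arrival_mode
        )
        return PSAResultsWrapper(self, psa)

    def tornado(self, param_ranges=None) -> pd.DataFrame:
        """One-way sensitivity of the NMB (see :func:`uticea.sensitivity.tornado`)."""
        return tornado(
            self.params, param_ranges, self.scenario, self.cohort,
            mode=self.arrival_mode,
        )


class CEResults:
    """Deterministic results: incremental estimates and breakdowns."""

    def __init__(self, model: CostEffectivenessModel, result: ScenarioResult):
        self.model = model
        self.result = result

    # convenience accessors -------------------------------------------------
    @property
    def delta_cost(self) -> float:
        return self.result.incremental.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.result.incremental.delta_qaly

    @property
    def nmb(self) -> float:
        return self.result.incremental.nmb

    @property
    def dominant(self) -> bool:
        return self.result.incremental.dominance_flag

    @property
    def per_stratum(self) -> pd.DataFrame:
        return self.result.per_stratum

    def per_patient(self) -> pd.DataFrame:
        """Per-stratum incremental outcomes per patient case."""
        return per_patient_results(self.result, self.model.cohort)

    def to_frame(self) -> pd.DataFrame:
        return self.result.to_frame()

    def summary(self) -> str:
        res = self.result
        pct = (
            100.0
            * (res.culture.inappropriate_days - res.bict.inappropriate_days)
            / res.culture.inappropriate_days
            if res.culture.inappropriate_days > 0
            else 0.0
        )
        extra = [
            "",
            f"  Inappropriate-day reduction  {pct:.1f}%",
            f"  Deaths averted               "
            f"{res.culture.deaths - res.bict.deaths:,.2f}",
            f"  BSI person-days avoided      "
            f"{res.culture.bsi_person_days - res.bict.bsi_person_days:,.2f}",
        ]
        return res.summary() + "\n".join(extra)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CEResults {self.result.scenario.name}: "
            f"NMB £{self.nmb:,.0f}, dQALY {self.delta_qaly:.2f}>"
        )


class PSAResultsWrapper:
    """Probabilistic results with acceptability-curve and plane helpers."""

    def __init__(self, model: CostEffectivenessModel, psa: PSAResults):
        self.model = model
        self.psa = psa

    @property
    def draws(self) -> pd.DataFrame:
        return self.psa.draws

    def ceac(self, lambda_grid=None) -> pd.DataFrame:
        return ceac(self.psa, lambda_grid)

    def prob_cost_effective(self, lam: float | None = None) -> float:
        return self.psa.prob_cost_effective(
            self.psa.wtp if lam is None else lam
        )

    def ce_plane_points(self) -> pd.DataFrame:
        return self.psa.ce_plane_points()

    def summary(self) -> str:
        return self.psa.summary()

    def plot_ce_plane(self, ax=None):
        from .plots import plot_ce_plane

        return plot_ce_plane(self.psa, ax=ax)

    def plot_ceac(self, ax=None, lambda_grid=None):
        from .plots import plot_ceac

        return plot_ceac(self.psa, ax=ax, lambda_grid=lambda_grid)
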