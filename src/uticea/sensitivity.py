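"""Univariate (tornado) and probabilistic sensitivity analysis.

The probabilistic analysis redraws every distributed parameter jointly
(default 1000 draws), re-runs the paired scenario per draw, and keeps the
per-draw incremental cost / QALY pair; from those the cost-effectiveness
acceptability curve (probability of positive net monetary benefit as a
function of willingness to pay) and the cost-effectiveness plane follow.
Draws are seeded counter-style from a root seed plus the draw index, so any
single draw is independently reproducible.

The tornado analysis re-evaluates the deterministic model one parameter at a
time at the endpoints of its plausible range, all else held at base values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .markov import ConsistencyError
from .parameters import ParameterSet
from .pathways import Scenario, get_scenario
from .scenarios import run_scenario

__all__ = [
    "PSAResults",
    "run_psa",
    "ceac",
    "tornado",
    "default_tornado_ranges",
]

logger = logging.getLogger(__name__)


@dataclass
class PSAResults:
    """Per-draw incremental outcomes from the probabilistic analysis."""

    draws: pd.DataFrame  # columns: draw, delta_cost, delta_qaly, nmb
    seed: int
    n: int
    wtp: float
    scenario: str
    n_redraws: int = 0

    def nmb_at(self, lam: float) -> np.ndarray:
        return lam * self.draws["delta_qaly"].to_numpy() - self.draws[
            "delta_cost"
        ].to_numpy()

    def prob_cost_effective(self, lam: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``lam``."""
        return float((self.nmb_at(lam) > 0).mean())

    def ce_plane_points(self) -> pd.DataFrame:
        """(delta_qaly, delta_cost) pairs for the cost-effectiveness plane."""
        return self.draws[["draw", "delta_qaly", "delta_cost"]].copy()

    def summary(self) -> str:
        d = self.draws
        return "\n".join(
            [
                f"PSA: {self.n} draws, scenario {self.scenario}, seed {self.seed}",
                f"  mean incremental cost  £{d['delta_cost'].mean():,.0f}"
                f"  (95% CI {d['delta_cost'].quantile(0.025):,.0f} to"
                f" {d['delta_cost'].quantile(0.975):,.0f})",
                f"  mean incremental QALYs {d['delta_qaly'].mean():,.2f}"
                f"  (95% CI {d['delta_qaly'].quantile(0.025):,.2f} to"
                f" {d['delta_qaly'].quantile(0.975):,.2f})",
                f"  mean NMB               £{d['nmb'].mean():,.0f}",
                f"  P(cost-effective at £{self.wtp:,.0f}/QALY) = "
                f"{self.prob_cost_effective(self.wtp):.3f}",
            ]
        )


def _draw_rng(seed: int, draw: int, retry: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, draw, retry)))


def run_psa(
    n: int,
    seed: int,
    scenario: Scenario | str,
    cohort: CohortTable,
    params: ParameterSet,
    mode: str = "rate",
    max_retries: int = 5,
) -> PSAResults:
    """Probabilistic sensitivity analysis with ``n`` joint parameter draws.

    Each draw samples every distributed parameter, runs both arms of the
    scenario, and records the incremental cost/QALY pair and the NMB at the
    base willingness-to-pay. A draw aborting on an internal-consistency
    error is logged and redrawn (the count is reported).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    wtp = params["wtp"]
    rows = []
    n_redraws = 0
    for i in range(n):
        for retry in range(max_retries + 1):
            sampled = params.sample(_draw_rng(seed, i, retry))
            try:
                res = run_scenario(scenario, cohort, sampled, mode=mode)
                break
            except ConsistencyError as err:  # pragma: no cover - defensive
                n_redraws += 1
                logger.warning("draw %d aborted (%s); redrawing", i, err)
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"draw {i} failed after {max_retries} redraws")
        inc = res.incremental
        rows.append(
            {
                "draw": i,
                "delta_cost": inc.delta_cost,
                "delta_qaly": inc.delta_qaly,
                "nmb": inc.nmb,
            }
        )
    return PSAResults(
        draws=pd.DataFrame(rows),
        seed=seed,
        n=n,
        wtp=wtp,
        scenario=scenario.name,
        n_redraws=n_redraws,
    )


def ceac(psa: PSAResults, lambda_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of draws whose net
    monetary benefit is positive.
    """
    if lambda_grid is None:
        lambda_grid = np.arange(0, 50001, 1000)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if (lambda_grid < 0).any():
        raise ValueError("willingness-to-pay values must be non-negative")
    probs = [psa.prob_cost_effective(lam) for lam in lambda_grid]
    return pd.DataFrame({"lambda": lambda_grid, "probability": probs})


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------

#: pseudo-parameters expressed as ratios on the susceptible exit profile
_PSEUDO_PARAMS = ("resistant_mortality_ratio", "resistant_los_ratio")


def default_tornado_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Ranges for the one-way analysis: every uniform-distributed parameter's
    bounds, the rapid-test turnaround (1 h to culture parity), and the
    resistant-vs-susceptible mortality and length-of-stay impact ratios."""
    ranges: dict[str, tuple[float, float]] = {}
    for name in params.names():
        dist = params.parameter(name).distribution
        if dist.kind == "uniform":
            ranges[name] = (dist.params[0], dist.params[1])
    ranges["turnaround_bict_h"] = (1.0, params["turnaround_culture_h"])
    ranges["resistant_mortality_ratio"] = (1.0, 3.0)
    ranges["resistant_los_ratio"] = (1.0, 2.0)
    # the resistant LoS/mortality entries are expressed via the ratios instead
    for name in (
        "los_mean_days.resistant_inappropriate",
        "mortality_fraction.resistant_inappropriate",
    ):
        ranges.pop(name, None)
    return ranges


def _overrides_for(params: ParameterSet, name: str, value: float) -> dict[str, float]:
    if name == "resistant_mortality_ratio":
        return {
            "mortality_fraction.resistant_inappropriate": value
            * params["mortality_fraction.susceptible_appropriate"]
        }
    if name == "resistant_los_ratio":
        return {
            "los_mean_days.resistant_inappropriate": value
            * params["los_mean_days.susceptible_appropriate"]
        }
    if name not in params:
        raise KeyError(f"unknown tornado parameter {name!r}")
    return {name: value}


def tornado(
    base_params: ParameterSet,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    scenario: Scenario | str = "base_population",
    cohort: CohortTable | None = None,
    mode: str = "rate",
) -> pd.DataFrame:
    """One-at-a-time sensitivity of the NMB to each parameter.

    Re-evaluates the deterministic paired scenario at the low and high end of
    each range with everything else at base values; returns a table sorted by
    bar width ``|nmb_high - nmb_low|`` descending.
    """
    if cohort is None:
        from .cohort import build_cohort

        cohort = build_cohort(base_params["bsi_cohort_total"])
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if param_ranges is None:
        param_ranges = default_tornado_ranges(base_params)

    base_nmb = run_scenario(scenario, cohort, base_params, mode=mode).incremental.nmb
    rows = []
    for name, (lo, hi) in param_ranges.items():
        if lo > hi:
            raise ValueError(f"range for {name} has low > high")
        if name in base_params:
            dist = base_params.parameter(name).distribution
            if not dist.is_fixed and not (
                dist.support_contains(lo) and dist.support_contains(hi)
            ):
                raise ValueError(
                    f"range ({lo}, {hi}) for {name} lies outside its "
                    f"distribution support {dist}"
                )
        nmbs = {}
        for end, value in (("low", lo), ("high", hi)):
            p = base_params.with_values(_overrides_for(base_params, name, value))
            nmbs[end] = run_scenario(scenario, cohort, p, mode=mode).incremental.nmb
        rows.append(
            {
                "parameter": name,
                "low": lo,
                "high": hi,
                "nmb_low": nmbs["low"],
                "nmb_high": nmbs["high"],
                "nmb_base": base_nmb,
                "spread": abs(nmbs["high"] - nmbs["low"]),
            }
        )
    out = pd.DataFrame(rows).sort_values("spread", ascending=False)
    return out.reset_index(drop=True)
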