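"""Model inputs: point estimates, uncertainty distributions and rate arithmetic.

Every input of the cost-effectiveness model lives in a :class:`ParameterSet`,
a flat mapping from dotted parameter names (``"los_mean_days.bsi"``) to a
:class:`Parameter` carrying the deterministic point value and, where the
analysis treats the input as uncertain, a sampling :class:`Distribution`
(gamma, uniform or degenerate/fixed) used by the probabilistic sensitivity
analysis.

The module also owns the elementary conversions the transition probabilities
are built from: cumulative-probability -> hourly rate, daily -> hourly
probability, and the ICU/general-ward blended bed cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Distribution",
    "Parameter",
    "ParameterSet",
    "cumulative_prob_to_hourly_rate",
    "daily_prob_to_hourly_prob",
    "hourly_rate_to_hourly_prob",
    "blended_bed_cost_hour",
    "sample_parameter_set",
    "load_default_parameters",
]

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# rate / probability conversions
# ---------------------------------------------------------------------------


def cumulative_prob_to_hourly_rate(p: float, window_h: float) -> float:
    """Convert a cumulative probability over ``window_h`` hours to a constant
    per-hour hazard rate, ``-ln(1 - p) / window_h``.

    Parameters
    ----------
    p : float
        Cumulative probability of the event over the window, ``0 <= p < 1``.
    window_h : float
        Window length in hours, strictly positive.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {p}")
    if window_h <= 0:
        raise ValueError(f"window must be positive, got {window_h} h")
    return -math.log1p(-p) / window_h


def daily_prob_to_hourly_prob(p_daily: float) -> float:
    """Convert a daily probability to the equivalent hourly probability,
    ``1 - (1 - p_daily)^(1/24)``, so that compounding the hourly probability
    over 24 cycles recovers the daily one."""
    if not 0.0 <= p_daily <= 1.0:
        raise ValueError(f"daily probability must be in [0, 1], got {p_daily}")
    if p_daily == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-p_daily) / 24.0)


def hourly_rate_to_hourly_prob(rate: float) -> float:
    """Probability of at least one event in a one-hour cycle under a constant
    hazard ``rate`` per hour: ``1 - exp(-rate)``."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return -math.expm1(-rate)


def blended_bed_cost_hour(prop_icu: float, c_general: float, c_icu: float) -> float:
    """ICU/general-ward weighted hourly bed cost,
    ``(1 - prop_icu) * c_general + prop_icu * c_icu``."""
    if not 0.0 <= prop_icu <= 1.0:
        raise ValueError(f"ICU proportion must be in [0, 1], got {prop_icu}")
    if c_general < 0 or c_icu < 0:
        raise ValueError("bed costs must be non-negative")
    return (1.0 - prop_icu) * c_general + prop_icu * c_icu


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """A sampling distribution for one uncertain parameter.

    ``kind`` is one of ``"gamma"`` (shape/scale), ``"uniform"`` (min/max) or
    ``"fixed"`` (degenerate at ``value``).
    """

    kind: str
    params: tuple[float, ...]

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "Distribution":
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        return cls("gamma", (float(shape), float(scale)))

    @classmethod
    def uniform(cls, lo: float, hi: float) -> "Distribution":
        if lo > hi:
            raise ValueError("uniform requires min <= max")
        return cls("uniform", (float(lo), float(hi)))

    @classmethod
    def fixed(cls, value: float) -> "Distribution":
        return cls("fixed", (float(value),))

    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed"

    def mean(self) -> float:
        if self.kind == "gamma":
            return self.params[0] * self.params[1]
        if self.kind == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "gamma":
            return float(rng.gamma(self.params[0], self.params[1]))
        if self.kind == "uniform":
            return float(rng.uniform(self.params[0], self.params[1]))
        return self.params[0]

    def support_contains(self, x: float) -> bool:
        if self.kind == "gamma":
            return x > 0
        if self.kind == "uniform":
            return self.params[0] <= x <= self.params[1]
        return x == self.params[0]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "gamma":
            return f"Gamma(shape={self.params[0]:g}, scale={self.params[1]:g})"
        if self.kind == "uniform":
            return f"Uniform({self.params[0]:g}, {self.params[1]:g})"
        return f"Fixed({self.params[0]:g})"


@dataclass(frozen=True)
class Parameter:
    """One named model input: point value, distribution and provenance."""

    name: str
    value: float
    distribution: Distribution
    units: str = ""
    source: str = ""


# parameters whose values must lie in [0, 1]
_PROPORTION_PREFIXES = (
    "test_sensitivity",
    "test_specificity",
    "prop_icu_",
    "inappropriate_rx_proportion",
    "resistance_prevalence.",
    "mortality_fraction.",
    "utility_norm",
    "discount_rate_annual",
)

# ratio beyond which the printed gamma scale is treated as mis-specified and
# rescaled so the distribution mean matches the point estimate
_GAMMA_MEAN_MISMATCH = 10.0


def _is_proportion(name: str) -> bool:
    return any(name.startswith(p) for p in _PROPORTION_PREFIXES)


class ParameterSet:
    """Immutable-by-convention mapping of parameter name -> :class:`Parameter`.

    Point values are read with ``ps["name"]``; the full record with
    ``ps.parameter("name")``. ``sample`` draws one probabilistic-sensitivity
    realisation, ``with_values`` returns a copy with point values overridden
    (used by scenarios and the tornado analysis).
    """

    def __init__(self, parameters: Iterable[Parameter], *, validate: bool = True):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ValueError(f"duplicate parameter {p.name!r}")
            self._params[p.name] = self._normalise_gamma(p)
        if validate:
            self.validate()

    @staticmethod
    def _normalise_gamma(p: Parameter) -> Parameter:
        """Rescale a gamma whose mean is wildly off the point estimate.

        Keeps the printed shape (hence the dispersion profile) but resets the
        scale so the distribution mean equals the point value, keeping the
        probabilistic analysis centred on the deterministic model.
        """
        d = p.distribution
        if d.kind != "gamma" or p.value <= 0:
            return p
        ratio = d.mean() / p.value
        if ratio > _GAMMA_MEAN_MISMATCH or ratio < 1.0 / _GAMMA_MEAN_MISMATCH:
            shape = d.params[0]
            new_scale = p.value / shape
            logger.warning(
                "gamma distribution for %s has mean %.3g vs point estimate %.3g; "
                "rescaling scale %.6g -> %.6g to match the point-estimate mean",
                p.name, d.mean(), p.value, d.params[1], new_scale,
            )
            return replace(p, distribution=Distribution.gamma(shape, new_scale))
        return p

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._params[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._params == other._params

    def parameter(self, name: str) -> Parameter:
        return self._params[name]

    def names(self) -> list[str]:
        return list(self._params)

    def group(self, prefix: str) -> dict[str, float]:
        """Values of all parameters under a dotted prefix, keyed by suffix."""
        pre = prefix.rstrip(".") + "."
        return {
            n[len(pre):]: p.value for n, p in self._params.items() if n.startswith(pre)
        }

    # -- construction helpers ----------------------------------------------
    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Copy with some point values replaced (distributions untouched)."""
        params = []
        unknown = set(overrides) - set(self._params)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        for name, p in self._params.items():
            if name in overrides:
                p = replace(p, value=float(overrides[name]))
            params.append(p)
        return ParameterSet(params)

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        for name, p in self._params.items():
            if _is_proportion(name) and not 0.0 <= p.value <= 1.0:
                raise ValueError(f"{name} = {p.value} is not a proportion in [0, 1]")
            if (name.startswith("cost_") or name.startswith("drug_cost")) and p.value < 0:
                raise ValueError(f"{name} = {p.value}: costs must be non-negative")
        if "turnaround_bict_h" in self and "turnaround_culture_h" in self:
            if self["turnaround_bict_h"] > self["turnaround_culture_h"]:
                raise ValueError("BICT turnaround must not exceed culture turnaround")
            if "horizon_h" in self and self["horizon_h"] <= self["turnaround_culture_h"]:
                raise ValueError("horizon must exceed the longest turnaround")

    # -- sampling ------------------------------------------------------------
    def sample(self, rng: np.random.Generator, *, max_redraws: int = 100) -> "ParameterSet":
        """One independent probabilistic draw of every distributed parameter.

        Draws violating a structural invariant (a sampled proportion outside
        [0, 1], a negative cost) are rejected and redrawn, with the rejection
        logged.
        """
        sampled = []
        for name, p in self._params.items():
            if p.distribution.is_fixed:
                sampled.append(p)
                continue
            value = p.distribution.sample(rng)
            tries = 0
            while not self._draw_ok(name, value):
                tries += 1
                if tries > max_redraws:
                    raise RuntimeError(f"could not draw a valid value for {name}")
                logger.info("rejecting draw %g for %s; redrawing", value, name)
                value = p.distribution.sample(rng)
            sampled.append(replace(p, value=value))
        out = {p.name: p for p in sampled}
        self._enforce_los_ordering(out, rng, max_redraws)
        return ParameterSet(out.values())

    @staticmethod
    def _enforce_los_ordering(
        out: dict[str, Parameter], rng: np.random.Generator, max_redraws: int
    ) -> None:
        """Cross-parameter invariant: resistant/inappropriate stays are no
        shorter than susceptible/appropriate ones. Offending joint draws are
        rejected and the resistant length of stay redrawn (logged)."""
        res_key = "los_mean_days.resistant_inappropriate"
        sus_key = "los_mean_days.susceptible_appropriate"
        if res_key not in out or sus_key not in out:
            return
        sus = out[sus_key].value
        res_param = out[res_key]
        if res_param.distribution.is_fixed:
            return
        tries = 0
        value = res_param.value
        while value < sus:
            tries += 1
            if tries > max_redraws:
                raise RuntimeError(
                    "could not draw a resistant length of stay >= the "
                    "susceptible one"
                )
            logger.info(
                "rejecting resistant LoS draw %.3f < susceptible %.3f; redrawing",
                value, sus,
            )
            value = res_param.distribution.sample(rng)
        out[res_key] = replace(res_param, value=value)

    @staticmethod
    def _draw_ok(name: str, value: float) -> bool:
        if _is_proportion(name):
            return 0.0 <= value <= 1.0
        if name.startswith("cost_") or name.startswith("drug_cost"):
            return value >= 0.0
        return np.isfinite(value)

    # -- reporting -----------------------------------------------------------
    def audit(self) -> pd.DataFrame:
        """Parameter audit table: name, value, distribution, support check."""
        rows = []
        for name, p in self._params.items():
            rows.append(
                {
                    "parameter": name,
                    "value": p.value,
                    "units": p.units,
                    "distribution": str(p.distribution),
                    "point_in_support": p.distribution.is_fixed
                    or p.distribution.support_contains(p.value),
                    "source": p.source,
                }
            )
        return pd.DataFrame(rows)

    # -- serialisation -------------------------------------------------------
    @classmethod
    def from_dict(cls, doc: Mapping[str, Mapping]) -> "ParameterSet":
        params = []
        for name, entry in doc.items():
            value = float(entry["value"])
            dist_doc = entry.get("distribution")
            if dist_doc is None or dist_doc.get("kind", "fixed") == "fixed":
                dist = Distribution.fixed(value)
            elif dist_doc["kind"] == "gamma":
                dist = Distribution.gamma(dist_doc["shape"], dist_doc["scale"])
            elif dist_doc["kind"] == "uniform":
                dist = Distribution.uniform(dist_doc["min"], dist_doc["max"])
            else:
                raise ValueError(f"unknown distribution kind {dist_doc['kind']!r}")
            params.append(
                Parameter(
                    name=name,
                    value=value,
                    distribution=dist,
                    units=entry.get("units", ""),
                    source=entry.get("source", ""),
                )
            )
        return cls(params)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_default_parameters() -> ParameterSet:
    """The packaged default configuration (base-case point estimates and
    probabilistic-sensitivity distributions)."""
    text = resources.files("uticea").joinpath("data/parameters.yaml").read_text()
    return ParameterSet.from_dict(yaml.safe_load(text))


def sample_parameter_set(base: ParameterSet, seed: int) -> ParameterSet:
    """One reproducible probabilistic draw from ``base``.

    Identical seeds yield identical parameter sets; a set with only fixed
    distributions is returned value-identical to the input.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return base.sample(rng)
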