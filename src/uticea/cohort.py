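"""Synthetic patient cohort and exit (discharge/death) profiles.

The analysis was designed around a national hospital-admissions extract that
is access-restricted, so this module generates a cohort table with the same
statistical structure: 12 strata (2 age bands x 2 sexes x 3 UTI types) whose
continuous masses exactly partition a configured total, an 80/10/10
uncomplicated / complicated-oral / complicated-IV split within every age-sex
group, and exit profiles (daily discharge probability plus the share of exits
that are deaths) derived from mean lengths of stay under a constant-hazard
assumption.

Cohort mass is continuous (expected-value cohort semantics); integer views
are produced only at report time with half-up rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "UTI_TYPES",
    "STATE_CLASSES",
    "Stratum",
    "all_strata",
    "CohortTable",
    "build_cohort",
    "default_age_sex_weights",
    "ExitProfile",
    "exit_profile_from_los",
    "resistant_inappropriate_prevalence",
]

AGE_BANDS = ("16-64", "65-100")
SEXES = ("F", "M")
UTI_TYPES = ("uncomplicated", "complicated_oral", "complicated_iv")

#: exit-profile state classes: susceptible UTI on effective treatment,
#: resistant UTI on inappropriate empirical treatment, bloodstream infection
STATE_CLASSES = ("susceptible_appropriate", "resistant_inappropriate", "bsi")

#: default within-group split of UTI types (uncomplicated, oral, IV)
DEFAULT_COMPLICATED_SPLIT = (0.8, 0.1, 0.1)


@dataclass(frozen=True, order=True)
class Stratum:
    age_band: str
    sex: str
    uti_type: str

    def __post_init__(self):
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.uti_type not in UTI_TYPES:
            raise ValueError(f"unknown UTI type {self.uti_type!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.age_band, self.sex, self.uti_type)


def all_strata() -> list[Stratum]:
    """The 12 modelled strata in canonical order."""
    return [
        Stratum(a, s, u) for a in AGE_BANDS for s in SEXES for u in UTI_TYPES
    ]


def default_age_sex_weights() -> dict[tuple[str, str], float]:
    """Default age-sex admission weights.

    The 16-64 male weight reproduces the documented worked example
    (17 192 of 280 462 admissions); the remaining weights are synthetic
    placeholders that put the largest share in 65-100 females, consistent
    with the dominance of elderly women among hospital UTI admissions.
    """
    w_m1664 = 17192 / 280462
    return {
        ("16-64", "F"): 0.17,
        ("16-64", "M"): w_m1664,
        ("65-100", "F"): 0.47,
        ("65-100", "M"): 1.0 - 0.17 - 0.47 - w_m1664,
    }


class CohortTable:
    """Patient mass per stratum with treatment-pathway annotations.

    Backed by a :class:`pandas.DataFrame` with columns ``age_band, sex,
    uti_type, count, empirical_abx, second_line_abx, route``.
    """

    COLUMNS = ["age_band", "sex", "uti_type", "count",
               "empirical_abx", "second_line_abx", "route"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS[:4]) - set(frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if (frame["count"] < 0).any():
            raise ValueError("cohort counts must be non-negative")
        frame = frame.copy()
        for col in self.COLUMNS[4:]:
            if col not in frame.columns:
                frame[col] = ""
        self.frame = frame.reset_index(drop=True)[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total(self) -> float:
        return float(self.frame["count"].sum())

    def strata(self) -> list[Stratum]:
        return [
            Stratum(r.age_band, r.sex, r.uti_type)
            for r in self.frame.itertuples()
        ]

    def counts(self) -> np.ndarray:
        return self.frame["count"].to_numpy(dtype=float)

    def count(self, stratum: Stratum) -> float:
        f = self.frame
        m = (
            (f["age_band"] == stratum.age_band)
            & (f["sex"] == stratum.sex)
            & (f["uti_type"] == stratum.uti_type)
        )
        return float(f.loc[m, "count"].sum())

    def scaled(self, factor: float) -> "CohortTable":
        out = self.frame.copy()
        out["count"] = out["count"] * factor
        return CohortTable(out)

    def rounded(self) -> pd.DataFrame:
        """Integer report view: counts rounded half-up."""
        out = self.frame.copy()
        out["count"] = np.floor(out["count"] + 0.5).astype(int)
        return out

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, keep_default_na=False))


def build_cohort(
    total: float,
    age_sex_weights: Mapping[tuple[str, str], float] | None = None,
    complicated_split: tuple[float, float, float] = DEFAULT_COMPLICATED_SPLIT,
) -> CohortTable:
    """Partition ``total`` admissions into the 12 strata.

    ``age_sex_weights`` maps (age_band, sex) to a weight; weights must be
    non-negative and sum to 1. Within each age-sex group the mass is split
    across uncomplicated / complicated-oral / complicated-IV by
    ``complicated_split`` (default 80% / 10% / 10%). Stratum masses are
    continuous and exactly partition the total.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    weights = dict(age_sex_weights or default_age_sex_weights())
    if any(w < 0 for w in weights.values()):
        raise ValueError("age-sex weights must be non-negative")
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("age-sex weights must sum to 1")
    if any(s < 0 for s in complicated_split):
        raise ValueError("complicated split shares must be non-negative")
    if abs(sum(complicated_split) - 1.0) > 1e-9:
        raise ValueError("complicated split must sum to 1")

    rows = []
    split = dict(zip(UTI_TYPES, complicated_split))
    for age in AGE_BANDS:
        for sex in SEXES:
            group = total * weights[(age, sex)]
            for uti_type in UTI_TYPES:
                rows.append(
                    {
                        "age_band": age,
                        "sex": sex,
                        "uti_type": uti_type,
                        "count": group * split[uti_type],
                    }
                )
    return CohortTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class ExitProfile:
    """Per state-class daily discharge probability and death share of exits."""

    daily_discharge_prob: Mapping[str, float]
    death_fraction: Mapping[str, float]

    def __post_init__(self):
        for name, mapping in (
            ("daily_discharge_prob", self.daily_discharge_prob),
            ("death_fraction", self.death_fraction),
        ):
            if set(mapping) != set(STATE_CLASSES):
                raise ValueError(f"{name} must cover exactly {STATE_CLASSES}")
            for k, v in mapping.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}] = {v} outside [0, 1]")
        if (
            self.daily_discharge_prob["resistant_inappropriate"]
            > self.daily_discharge_prob["susceptible_appropriate"]
        ):
            raise ValueError(
                "resistant/inappropriate discharge probability must not exceed "
                "the susceptible/appropriate one (resistance lengthens stay)"
            )


def exit_profile_from_los(
    mean_los_days: Mapping[str, float],
    mortality_fraction: float | Mapping[str, float],
) -> ExitProfile:
    """Exit profile from mean lengths of stay under a constant exit hazard.

    The daily discharge probability for a class with mean stay ``L`` days is
    ``1 - exp(-1/L)``. ``mortality_fraction`` (the share of exits that are
    deaths, applied uniformly across the stay) may be a scalar broadcast to
    all classes or a per-class mapping.
    """
    if set(mean_los_days) != set(STATE_CLASSES):
        raise ValueError(f"mean_los_days must cover exactly {STATE_CLASSES}")
    for k, los in mean_los_days.items():
        if los <= 0:
            raise ValueError(f"mean LoS for {k} must be positive, got {los}")
    if isinstance(mortality_fraction, Mapping):
        death = {k: float(mortality_fraction[k]) for k in STATE_CLASSES}
    else:
        death = {k: float(mortality_fraction) for k in STATE_CLASSES}
    daily = {k: -math.expm1(-1.0 / mean_los_days[k]) for k in STATE_CLASSES}
    return ExitProfile(daily_discharge_prob=daily, death_fraction=death)


def resistant_inappropriate_prevalence(
    resistance_prev: float, inappropriate_prop: float
) -> float:
    """Prevalence of the resistant-and-inappropriately-prescribed pathway.

    Product of the resistance prevalence for the empirical antibiotic and the
    proportion of prescribing that is inappropriate; this is the share of a
    stratum that enters the model on ineffective empirical treatment.
    """
    if not 0.0 <= resistance_prev <= 1.0:
        raise ValueError(f"resistance prevalence {resistance_prev} outside [0, 1]")
    if not 0.0 <= inappropriate_prop <= 1.0:
        raise ValueError(f"inappropriate proportion {inappropriate_prop} outside [0, 1]")
    return resistance_prev * inappropriate_prop
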