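"""Synthetic cancer-registry generator.

Produces :class:`RegistryDataset` objects with the statistical structure the
pipeline assumes, so every stage is testable at desk scale without any
registry download:

* all-cause mortality hazard increasing exponentially with age
  (Gompertz-like, the standard adult-mortality shape);
* site-specific incidence rising exponentially with age;
* site mortality tied to incidence by a true lethality ratio
  ``rho in [0, 1]`` per age group — which makes ``rho`` exactly identifiable
  as the lethality factor, since proportional series cancel the survival
  weights;
* linear secular multipliers per quantity (e.g. a 30% mortality-rate decline
  across the span);
* expected-value output (deterministic, real-valued counts) or Poisson
  counts with per-(year, site, kind) substreams, so adding a site never
  perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigError
from .grids import AgeGrid
from .registry import ALL_CAUSE, KIND_DEATH, KIND_INCIDENCE, RegistryDataset
from .sites import COMPUTED_SITES, usa_2012_reference

EXPECTED_VALUE = "expected_value"
POISSON = "poisson"

_KIND_CODE = {KIND_DEATH: 1, KIND_INCIDENCE: 2}


@dataclass(frozen=True)
class SiteSpec:
    """Generative description of one cancer site.

    ``incidence_level`` is the incidence rate per person-year at the
    reference age of 70; the age curve is ``level * exp(slope*(age - 70))``.
    ``lethality`` is the true mortality/incidence ratio ``rho`` applied per
    age group.  A non-zero ``mortality_age_shift`` (years) evaluates the
    mortality age curve at ``age - shift``, breaking the proportionality
    between the two series to exercise the survival weighting.
    """

    name: str
    incidence_level: float
    lethality: float
    age_slope: float = 0.06
    mortality_age_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.incidence_level < 0:
            raise ConfigError(f"site {self.name!r}: incidence level must be >= 0")
        if not 0.0 <= self.lethality <= 1.0:
            raise ConfigError(f"site {self.name!r}: lethality must lie in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """A complete generative configuration for one synthetic registry."""

    years: tuple[int, ...] = tuple(range(1980, 2013))
    grid: AgeGrid = field(default_factory=AgeGrid)
    population_per_group: float = 1_000_000.0
    all_cause_level: float = 8e-5  # hazard per person-year at age 0
    all_cause_slope: float = 0.084  # exponential age slope, 1/years
    sites: tuple[SiteSpec, ...] = ()
    mortality_multiplier: tuple[float, float] = (1.0, 1.0)  # start -> end factors
    incidence_multiplier: tuple[float, float] = (1.0, 1.0)
    all_cause_multiplier: tuple[float, float] = (1.0, 1.0)
    noise: str = EXPECTED_VALUE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.years) < 1 or len(set(self.years)) != len(self.years):
            raise ConfigError("scenario years must be non-empty and unique")
        if self.population_per_group <= 0:
            raise ConfigError("population per group must be positive")
        if self.all_cause_level < 0 or self.all_cause_slope < 0:
            raise ConfigError("all-cause hazard parameters must be non-negative")
        for pair in (self.mortality_multiplier, self.incidence_multiplier,
                     self.all_cause_multiplier):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ConfigError("temporal multipliers must be positive")
        if self.noise not in (EXPECTED_VALUE, POISSON):
            raise ConfigError(f"unknown noise mode {self.noise!r}")
        if not self.sites:
            raise ConfigError("scenario needs at least one site")

    # -- temporal factors ----------------------------------------------------

    def _factor(self, pair: tuple[float, float], year: int) -> float:
        y0, y1 = min(self.years), max(self.years)
        if y1 == y0:
            return pair[0]
        frac = (year - y0) / (y1 - y0)
        return pair[0] + (pair[1] - pair[0]) * frac

    # -- true rates (per person-year, one per age group) ----------------------

    def all_cause_rates(self, year: int) -> np.ndarray:
        ages = self.grid.midpoints
        base = self.all_cause_level * np.exp(self.all_cause_slope * ages)
        return base * self._factor(self.all_cause_multiplier, year)

    def incidence_rates(self, site: SiteSpec, year: int) -> np.ndarray:
        ages = self.grid.midpoints
        base = site.incidence_level * np.exp(site.age_slope * (ages - 70.0))
        return base * self._factor(self.incidence_multiplier, year)

    def mortality_rates(self, site: SiteSpec, year: int) -> np.ndarray:
        ages = self.grid.midpoints - site.mortality_age_shift
        base = site.lethality * site.incidence_level * np.exp(
            site.age_slope * (ages - 70.0)
        )
        return base * self._factor(self.mortality_multiplier, year)

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "years": list(self.years),
            "grid": {
                "lower_bounds": list(self.grid.lower_bounds),
                "width": self.grid.width,
                "open_top": self.grid.open_top,
                "top_midpoint": self.grid.top_midpoint,
            },
            "population_per_group": self.population_per_group,
            "all_cause_level": self.all_cause_level,
            "all_cause_slope": self.all_cause_slope,
            "sites": [
                {
                    "name": s.name,
                    "incidence_level": s.incidence_level,
                    "lethality": s.lethality,
                    "age_slope": s.age_slope,
                    "mortality_age_shift": s.mortality_age_shift,
                }
                for s in self.sites
            ],
            "mortality_multiplier": list(self.mortality_multiplier),
            "incidence_multiplier": list(self.incidence_multiplier),
            "all_cause_multiplier": list(self.all_cause_multiplier),
            "noise": self.noise,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        grid = d.pop("grid", None)
        kwargs: dict = {}
        if grid is not None:
            kwargs["grid"] = AgeGrid(
                lower_bounds=tuple(float(x) for x in grid["lower_bounds"]),
                width=float(grid.get("width", 5.0)),
                open_top=bool(grid.get("open_top", True)),
                top_midpoint=float(grid.get("top_midpoint", 87.5)),
            )
        sites = tuple(SiteSpec(**s) for s in d.pop("sites", []))
        for key in ("years", "mortality_multiplier", "incidence_multiplier",
                    "all_cause_multiplier"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown scenario keys {sorted(unknown)}")
        return cls(sites=sites, **kwargs, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: scenario must be a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _substream(seed: int, year: int, site: str, kind: str) -> np.random.Generator:
    """Deterministic per-(year, site, kind) stream, stable across platforms."""
    return np.random.default_rng(
        [seed, year, zlib.crc32(site.encode()), _KIND_CODE[kind]]
    )


def generate(scenario: Scenario) -> RegistryDataset:
    """Materialize a scenario into a registry dataset.

    Expected-value mode emits ``N_i * r_i`` directly (real-valued,
    seed-independent); Poisson mode draws integer counts with those means
    from per-series substreams.  Site series are generated marginally: the
    all-cause deaths are not constrained to dominate the summed site deaths.
    """
    pop = np.full(scenario.grid.m, scenario.population_per_group, dtype=float)
    population = {year: pop.copy() for year in scenario.years}
    events: dict[tuple[int, str, str], np.ndarray] = {}

    def counts(year: int, site: str, kind: str, rates: np.ndarray) -> np.ndarray:
        mean = pop * rates
        if scenario.noise == EXPECTED_VALUE:
            return mean
        return _substream(scenario.seed, year, site, kind).poisson(mean).astype(float)

    for year in scenario.years:
        events[(year, ALL_CAUSE, KIND_DEATH)] = counts(
            year, ALL_CAUSE, KIND_DEATH, scenario.all_cause_rates(year)
        )
        for site in scenario.sites:
            events[(year, site.name, KIND_INCIDENCE)] = counts(
                year, site.name, KIND_INCIDENCE, scenario.incidence_rates(site, year)
            )
            events[(year, site.name, KIND_DEATH)] = counts(
                year, site.name, KIND_DEATH, scenario.mortality_rates(site, year)
            )
    return RegistryDataset(scenario.grid, population, events)


#: Loosely realistic whole-population incidence levels at age 70
#: (per person-year) for the 12 computed sites.
_DEFAULT_INCIDENCE_LEVELS: dict[str, float] = {
    "esophagus": 5e-5,
    "stomach": 1e-4,
    "colon": 2e-3,
    "liver": 1e-4,
    "lung": 3e-3,
    "bone": 8e-6,
    "skin": 5e-3,
    "breast": 3e-3,
    "ovary": 3e-4,
    "bladder": 1e-3,
    "thyroid": 2e-4,
    "bone_marrow": 3e-4,
}


def lethality_decline_scenario(
    noise: str = EXPECTED_VALUE, seed: int = 0
) -> Scenario:
    """The linear-lethality-decline study scenario.

    33 calendar years (1980-2012) on the default 18-group grid; the 12
    computed sites with their catalogue risk coefficients and q_min rules,
    true lethality set to the USA-2012 reference values; site mortality
    rates scaled linearly from 1.0 down to 0.7 across the span while
    incidence and all-cause mortality stay constant.  In expected-value mode
    the overall lethality therefore declines by exactly 30% first-to-last
    year, while the total detriment declines by strictly less (the
    quality-of-life floor, the unchanged life-lost pattern and the fixed
    rows all damp the decline).
    """
    ref = usa_2012_reference()
    sites = tuple(
        SiteSpec(
            name=s.name,
            incidence_level=_DEFAULT_INCIDENCE_LEVELS[s.name],
            lethality=float(ref.loc[s.name, "k"]),
        )
        for s in COMPUTED_SITES
    )
    return Scenario(
        years=tuple(range(1980, 2013)),
        sites=sites,
        mortality_multiplier=(1.0, 0.7),
        noise=noise,
        seed=seed,
    )


def single_year_scenario(
    lethalities: Mapping[str, float],
    year: int = 2012,
    population_per_group: float = 1_000_000.0,
    noise: str = EXPECTED_VALUE,
    seed: int = 0,
    incidence_level: float = 1e-3,
) -> Scenario:
    """One-year scenario with caller-chosen true lethalities, for recovery tests."""
    sites = tuple(
        SiteSpec(name=name, incidence_level=incidence_level, lethality=rho)
        for name, rho in lethalities.items()
    )
    return Scenario(
        years=(year,),
        population_per_group=population_per_group,
        sites=sites,
        noise=noise,
        seed=seed,
    )
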