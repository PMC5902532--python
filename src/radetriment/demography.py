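"""Life-table core: age-specific rates, cumulative rates, survival, life expectancy.

Rates are period quantities: events in calendar year ``t`` divided by the
mean population at risk in that year.  The survival function is the
piecewise-exponential (actuarial) survival implied by the current year's
all-cause mortality, i.e. a period life table on the abridged age grid:

    S_i = prod_{k<=i} exp(-dA * n_k,all / N_k)

By the literal convention used throughout this package, ``S_i`` is the
probability of surviving from birth through the END of group ``i`` (the
product includes group ``i`` itself).  The conventional life-table reading —
survival to the START of group ``i`` — is available via
``survival_curve(..., convention="start")`` and propagates consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .grids import DELTA_T, AgeGrid
from .registry import ALL_CAUSE, KIND_DEATH, RegistryDataset

#: Survival-index conventions (which end of group i the product runs through).
SURVIVAL_END = "end"
SURVIVAL_START = "start"


@dataclass(frozen=True)
class RateSeries:
    """Age-specific event rates for one (year, site, kind), per person-year."""

    year: int
    site: str
    kind: str
    rates: np.ndarray
    grid: AgeGrid

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (self.grid.m,):
            raise DomainError("rate vector does not match the grid")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise DomainError("rates must be finite and non-negative")
        object.__setattr__(self, "rates", r)


@dataclass(frozen=True)
class SurvivalCurve:
    """All-cause survival probabilities per age group for one calendar year."""

    year: int
    values: np.ndarray
    grid: AgeGrid
    convention: str = SURVIVAL_END

    def __post_init__(self) -> None:
        s = np.asarray(self.values, dtype=float)
        if s.shape != (self.grid.m,):
            raise DomainError("survival vector does not match the grid")
        if np.any(s <= 0) or np.any(s > 1 + 1e-12):
            raise DomainError("survival values must lie in (0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise DomainError("survival must be non-increasing with age")
        object.__setattr__(self, "values", s)


def age_specific_rates(
    data: RegistryDataset, year: int, site: str, kind: str
) -> RateSeries:
    """Age-specific mortality or incidence rate r_i = n_i / (N_i * dt).

    ``dt`` is the 1-year observation window; the result is events per
    person-year, one value per age group.
    """
    counts = data.counts(year, site, kind)
    pop = data.population(year)
    return RateSeries(year, site, kind, counts / (pop * DELTA_T), data.grid)


def cumulative_rate(rates: RateSeries, upper_group: int | None = None) -> float:
    """Cumulative rate P = sum_{i<=m'} r_i * dA, a direct age standardization.

    Equally weights all age groups up to ``upper_group`` (1-based, defaults
    to the whole grid); the result is on the probability scale.
    """
    m = rates.grid.m if upper_group is None else rates.grid.check_group(upper_group)
    return float(np.sum(rates.rates[:m]) * rates.grid.width)


def survival_curve(
    data: RegistryDataset, year: int, convention: str = SURVIVAL_END
) -> SurvivalCurve:
    """Period survival function from the year's all-cause mortality.

    S_i = exp(-cumulative all-cause rate through group i) under the default
    "end" convention; under "start" the cumulative sum excludes group i.
    """
    if convention not in (SURVIVAL_END, SURVIVAL_START):
        raise DomainError(f"unknown survival convention {convention!r}")
    all_cause = age_specific_rates(data, year, ALL_CAUSE, KIND_DEATH)
    cum_hazard = np.cumsum(all_cause.rates * data.grid.width)
    if convention == SURVIVAL_START:
        cum_hazard = np.concatenate([[0.0], cum_hazard[:-1]])
    return SurvivalCurve(year, np.exp(-cum_hazard), data.grid, convention)


def remaining_life_expectancy(curve: SurvivalCurve, group: int) -> float:
    """Expected remaining years of life at age group ``i`` (1-based).

    a_i = (sum_{k=i..m} S_k * dA) / S_i — the tail of the survival curve
    normalized by survival up to the group.  Bounded by dA*(m-i+1); equals
    that bound under zero hazard.
    """
    i = curve.grid.check_group(group)
    s = curve.values
    if s[i - 1] <= 0:
        raise DomainError(f"survival is zero at group {i}; life expectancy undefined")
    return float(np.sum(s[i - 1 :]) * curve.grid.width / s[i - 1])
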