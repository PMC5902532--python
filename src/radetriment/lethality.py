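"""Survival-weighted cumulative rates and cancer lethality factors.

The lethality factor ``k`` of a cancer site is the ratio of its
age-standardized cumulative mortality rate to its age-standardized cumulative
incidence rate, both weighted by the same year's all-cause survival function.
It is the mortality-to-incidence ratio of registry epidemiology, placed on a
common survival-weighted age standard so the numerator and denominator are
comparable across sites and years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .demography import RateSeries, SurvivalCurve, age_specific_rates, survival_curve
from .exceptions import DomainError, UndefinedLethalityError
from .registry import KIND_DEATH, KIND_INCIDENCE, RegistryDataset

logger = logging.getLogger(__name__)

#: Policy names for standardized mortality exceeding incidence (k > 1).
CLAMP = "clamp"
ERROR = "error"

#: Pseudo-site label for the all-sites-combined lethality.
ALL_SITES = "ALL"


@dataclass(frozen=True)
class WeightedCumulativeRates:
    """Survival-weighted cumulative mortality and incidence for one site-year."""

    year: int
    site: str
    mortality: float  # ^M P_S, probability scale
    incidence: float  # ^I P_S, probability scale


@dataclass(frozen=True)
class LethalityResult:
    """Lethality factor for one site (or all sites combined) in one year.

    ``k`` is the value used downstream (clamped to [0, 1] under the default
    policy); ``raw_k`` retains the unclamped ratio for diagnostics.
    """

    year: int
    site: str
    k: float
    raw_k: float
    mortality_weighted: float
    incidence_weighted: float

    @property
    def clamped(self) -> bool:
        return self.k != self.raw_k


def weighted_cumulative_rate(rates: RateSeries, curve: SurvivalCurve) -> float:
    """P_S = sum_i r_i * dA * S_i — survival-weighted direct standardization.

    With unit weights (S_i = 1 everywhere) this reduces to the plain
    cumulative rate.
    """
    if rates.grid is not curve.grid and rates.grid != curve.grid:
        raise DomainError("rate series and survival curve use different grids")
    if rates.year != curve.year:
        raise DomainError(
            f"rate series year {rates.year} != survival curve year {curve.year}"
        )
    return float(np.sum(rates.rates * curve.values) * rates.grid.width)


def weighted_rates(
    data: RegistryDataset,
    year: int,
    site: str,
    curve: SurvivalCurve | None = None,
) -> WeightedCumulativeRates:
    """Both survival-weighted cumulative rates for one site-year."""
    curve = curve if curve is not None else survival_curve(data, year)
    mort = weighted_cumulative_rate(
        age_specific_rates(data, year, site, KIND_DEATH), curve
    )
    inc = weighted_cumulative_rate(
        age_specific_rates(data, year, site, KIND_INCIDENCE), curve
    )
    return WeightedCumulativeRates(year, site, mort, inc)


def _ratio(
    year: int, site: str, mort: float, inc: float, policy: str
) -> LethalityResult:
    if inc <= 0:
        raise UndefinedLethalityError(
            f"weighted cumulative incidence is zero for {site!r} in {year}; "
            "lethality undefined"
        )
    raw = mort / inc
    k = raw
    if raw > 1.0:
        if policy == ERROR:
            raise DomainError(
                f"lethality {raw:.4f} > 1 for {site!r} in {year} "
                "(standardized mortality exceeds incidence)"
            )
        logger.warning(
            "lethality %.4f > 1 for %r in %d; clamped to 1", raw, site, year
        )
        k = 1.0
    return LethalityResult(year, site, k, raw, mort, inc)


def lethality_factor(
    data: RegistryDataset,
    year: int,
    site: str,
    curve: SurvivalCurve | None = None,
    policy: str = CLAMP,
) -> LethalityResult:
    """Site lethality k_T = ^M P_S / ^I P_S, same-year survival weights."""
    w = weighted_rates(data, year, site, curve)
    return _ratio(year, site, w.mortality, w.incidence, policy)


def overall_lethality(
    data: RegistryDataset,
    year: int,
    sites: Sequence[str],
    curve: SurvivalCurve | None = None,
    policy: str = CLAMP,
) -> LethalityResult:
    """Combined lethality over ``sites``: ratio of summed weighted rates.

    Identical to applying the site formula to counts summed over sites.
    """
    if not sites:
        raise DomainError("overall lethality needs at least one site")
    curve = curve if curve is not None else survival_curve(data, year)
    mort = 0.0
    inc = 0.0
    for site in sites:
        w = weighted_rates(data, year, site, curve)
        mort += w.mortality
        inc += w.incidence
    return _ratio(year, ALL_SITES, mort, inc, policy)
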