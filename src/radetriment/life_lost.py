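"""Mean age at death, absolute life lost, and relative life lost.

The absolute life lost ``L_T`` of a cancer site is approximated at group
resolution: compute the survival-weighted mean age at death, map it to its
age group, and read off the remaining life expectancy at that group.  The
relative life lost ``L_rel,T`` rescales the ``L_T`` so their cross-site mean
is exactly 1, which makes them usable as dimensionless severity weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .demography import (
    RateSeries,
    SurvivalCurve,
    remaining_life_expectancy,
)
from .exceptions import DomainError, UndefinedLifeLostError
from .grids import AgeGrid
from .registry import KIND_DEATH


@dataclass(frozen=True)
class LifeLostResult:
    """Life-lost quantities for one site-year."""

    year: int
    site: str
    mean_age_at_death: float  # years
    group: int  # 1-based group containing the mean age at death
    life_lost: float  # L_T = remaining life expectancy at that group, years
    relative_life_lost: float | None = None  # filled once all sites are known


def mean_age_at_death(
    rates: RateSeries, curve: SurvivalCurve, grid: AgeGrid | None = None
) -> tuple[float, int]:
    """Survival-weighted mean age at death and its 1-based age group.

    ^M A_T = sum_i r_i S_i Abar_i / sum_i r_i S_i, with Abar_i the group
    midpoints (nominal for the open top group).
    """
    grid = grid or rates.grid
    if rates.kind != KIND_DEATH:
        raise DomainError(f"mean age at death needs a death series, got {rates.kind!r}")
    weights = rates.rates * curve.values
    total = float(np.sum(weights))
    if total <= 0.0:
        raise UndefinedLifeLostError(
            f"survival-weighted mortality is zero for {rates.site!r} in {rates.year}; "
            "mean age at death undefined"
        )
    mean_age = float(np.sum(weights * grid.midpoints) / total)
    return mean_age, grid.group_of(mean_age)


def absolute_life_lost(
    curve: SurvivalCurve, mean_age_group: int, interpolate: bool = False,
    mean_age: float | None = None,
) -> float:
    """L_T: remaining life expectancy at the group holding the mean age at death.

    The default reads the group-level value (no interpolation, matching the
    group-resolution approximation used throughout).  With
    ``interpolate=True`` and a ``mean_age``, a_i is interpolated linearly
    between the group's value and its successor's.
    """
    a = remaining_life_expectancy(curve, mean_age_group)
    if not interpolate:
        return a
    if mean_age is None:
        raise DomainError("interpolation needs the mean age itself")
    grid = curve.grid
    i = grid.check_group(mean_age_group)
    if i == grid.m:
        return a
    frac = (mean_age - grid.lower_bounds[i - 1]) / grid.width
    a_next = remaining_life_expectancy(curve, i + 1)
    return float((1.0 - frac) * a + frac * a_next)


def relative_life_lost(life_lost_by_site: Mapping[str, float]) -> dict[str, float]:
    """L_rel,T = n * L_T / sum(L_T) over the ``n`` supplied sites.

    The results are renormalized so that their sum equals ``n`` (and their
    mean equals 1) exactly, up to floating-point rounding of the final
    rescale.
    """
    if not life_lost_by_site:
        raise DomainError("relative life lost needs at least one site")
    sites = list(life_lost_by_site)
    values = np.asarray([life_lost_by_site[s] for s in sites], dtype=float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise DomainError("all absolute life-lost values must be positive and finite")
    n = len(sites)
    rel = n * values / float(values.sum())
    rel *= n / float(rel.sum())  # pin the normalization exactly
    return dict(zip(sites, rel.tolist()))
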