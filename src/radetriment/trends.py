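"""Temporal-trend machinery: per-year pipeline runs, baseline-normalized
series, percent changes, and the linear incidence proxy for sites whose
incidence registries are incomplete."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import DomainError
from .model import DetrimentModel, DetrimentResults
from .registry import RegistryDataset
from .sites import CancerSite


@dataclass(frozen=True)
class TrendSeries:
    """A named per-year series with units and an optional baseline year."""

    name: str
    units: str
    values: pd.Series  # index: years, strictly increasing
    baseline_year: int | None = None

    def __post_init__(self) -> None:
        vals = self.values.sort_index()
        if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
            raise DomainError(f"series {self.name!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, year: int) -> float:
        return float(self.values.loc[year])


def run_series(
    data: RegistryDataset,
    years: Sequence[int] | None = None,
    sites: Sequence[CancerSite] | None = None,
    config: RunConfig | None = None,
) -> DetrimentResults:
    """Evaluate the full pipeline for each year (independently, no smoothing).

    Thin wrapper over :class:`DetrimentModel`; years with missing series
    fail loudly and appear in ``results.failures`` as gaps, never
    interpolated.
    """
    model = DetrimentModel(data, sites=sites, config=config)
    return model.fit(years=years)


def relative_series(series: TrendSeries, baseline_year: int) -> TrendSeries:
    """Series rescaled to percent of its value in ``baseline_year``."""
    if baseline_year not in series.values.index:
        raise DomainError(f"baseline year {baseline_year} absent from {series.name!r}")
    base = float(series.values.loc[baseline_year])
    if base == 0.0:
        raise DomainError(f"baseline value is zero in {baseline_year}")
    return TrendSeries(
        f"{series.name} (relative to {baseline_year})",
        "%",
        series.values * 100.0 / base,
        baseline_year=baseline_year,
    )


def percent_change(series: TrendSeries, year0: int, year1: int) -> float:
    """Decline from ``year0`` to ``year1`` in percent (a decrease is positive)."""
    for y in (year0, year1):
        if y not in series.values.index:
            raise DomainError(f"year {y} absent from {series.name!r}")
    v0 = float(series.values.loc[year0])
    v1 = float(series.values.loc[year1])
    if v0 == 0.0:
        raise DomainError(f"value at {year0} is zero; percent change undefined")
    return 100.0 * (v0 - v1) / v0


def linear_incidence_proxy(
    zone_series: Sequence[pd.Series],
    target_years: Sequence[int],
    companion_factor: float = 1.0,
) -> pd.Series:
    """Incidence proxy by zone-wise linear extrapolation.

    Fits an unweighted ordinary-least-squares line (rate vs calendar year)
    to each zone's observed series, extrapolates every line to
    ``target_years``, and averages the zone lines (unweighted mean).  A
    companion cancer type assumed to track the fitted type with a constant
    proportional factor is added on top, so the returned rate is
    ``(1 + companion_factor) * mean(zone lines)``.

    This generalizes the registry practice of reconstructing a missing
    incidence series (e.g. non-melanoma skin cancer) from survey-based
    linear trends.
    """
    if not zone_series:
        raise DomainError("at least one zone series is required")
    if companion_factor < 0:
        raise DomainError("companion factor must be non-negative")
    target_years = np.asarray(sorted(int(y) for y in target_years))
    lines = []
    for z, s in enumerate(zone_series):
        s = s.dropna()
        years = s.index.to_numpy(dtype=float)
        rates = s.to_numpy(dtype=float)
        if len(s) < 2:
            raise DomainError(f"zone {z}: need at least two points for a line")
        if np.ptp(years) == 0:
            raise DomainError(f"zone {z}: all observations share one year")
        slope, intercept = np.polyfit(years, rates, 1)
        lines.append(intercept + slope * target_years)
    combined = np.mean(lines, axis=0) * (1.0 + companion_factor)
    return pd.Series(combined, index=target_years, name="incidence_proxy")


def plot_series(
    series_list: Sequence[TrendSeries], path: str, title: str | None = None
) -> None:
    """Line plot of one or more trend series to ``path`` (file-only backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for s in series_list:
        ax.plot(s.values.index, s.values.to_numpy(), marker="o", ms=3, label=s.name)
    ax.set_xlabel("year")
    ax.set_ylabel(series_list[0].units if series_list else "")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
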