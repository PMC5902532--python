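"""Model/Results facade over the detriment pipeline.

`DetrimentModel` binds a registry dataset to a site catalogue and a run
configuration; `fit()` evaluates the full pipeline — survival curve,
survival-weighted lethality, life lost, severity, per-organ and total
detriment — for each requested year and returns a `DetrimentResults`
carrying tidy per-year tables, diagnostics, and a `summary()` view shaped
like the standard 14-organ detriment table.

Years are evaluated independently (period analysis, no smoothing); a year
whose input series are incomplete fails loudly and is reported in
``results.failures`` while the remaining years proceed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import RunConfig
from .demography import age_specific_rates, survival_curve
from .detriment import DetrimentTable, detriment_row, total_detriment
from .exceptions import RadetrimentError
from .lethality import ALL_SITES, LethalityResult, lethality_factor, overall_lethality
from .life_lost import LifeLostResult, absolute_life_lost, mean_age_at_death, relative_life_lost
from .registry import KIND_DEATH, RegistryDataset
from .sites import ICRP103_SITES, CancerSite

logger = logging.getLogger(__name__)


@dataclass
class YearBundle:
    """All intermediate and final results for one calendar year."""

    year: int
    table: DetrimentTable
    lethality: dict[str, LethalityResult]
    overall: LethalityResult
    life_lost: dict[str, LifeLostResult]


class DetrimentModel:
    """ICRP 103 detriment model bound to registry data.

    Parameters
    ----------
    data : RegistryDataset
        Population and per-site incidence/death counts on the model's grid.
    sites : sequence of CancerSite, optional
        Organ catalogue; defaults to the bundled 14-site ICRP 103 set.
        Fixed sites contribute frozen rows; computed sites need death and
        incidence series in ``data``.
    config : RunConfig, optional
        Policies (clamping, q source, survival convention).

    Examples
    --------
    >>> model = DetrimentModel(data)
    >>> res = model.fit()
    >>> res.total_detriment          # pandas Series, year -> D_total
    >>> print(res.summary(2012))
    """

    def __init__(
        self,
        data: RegistryDataset,
        sites: Sequence[CancerSite] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.data = data
        self.config = config or RunConfig(grid=data.grid)
        if self.config.grid != data.grid:
            raise RadetrimentError("config grid differs from the dataset grid")
        catalogue = list(sites) if sites is not None else list(ICRP103_SITES)
        self.sites = [self._apply_overrides(s) for s in catalogue]
        self.computed_sites = [s for s in self.sites if not s.fixed]
        self.fixed_sites = [s for s in self.sites if s.fixed]

    def _apply_overrides(self, site: CancerSite) -> CancerSite:
        if site.name in self.config.q_min_overrides and not site.fixed:
            from dataclasses import replace

            return replace(site, q_min=self.config.q_min_overrides[site.name])
        return site

    # -- fitting ------------------------------------------------------------

    def fit(self, years: Sequence[int] | None = None) -> "DetrimentResults":
        """Run the pipeline per year and collect results.

        Deterministic given the inputs; independent per year, so permuting
        the requested order cannot change any per-year output.
        """
        years = sorted(int(y) for y in (years if years is not None else self.data.years))
        bundles: dict[int, YearBundle] = {}
        failures: dict[int, Exception] = {}
        for year in years:
            try:
                bundles[year] = self._fit_year(year)
            except RadetrimentError as exc:
                logger.error("year %d failed: %s", year, exc)
                failures[year] = exc
        return DetrimentResults(self, bundles, failures)

    def _fit_year(self, year: int) -> YearBundle:
        cfg = self.config
        curve = survival_curve(self.data, year, convention=cfg.survival_convention)

        lethalities: dict[str, LethalityResult] = {}
        life: dict[str, LifeLostResult] = {}
        for site in self.computed_sites:
            lethalities[site.name] = lethality_factor(
                self.data, year, site.name, curve=curve, policy=cfg.clamp_policy
            )
            death_rates = age_specific_rates(self.data, year, site.name, KIND_DEATH)
            mean_age, group = mean_age_at_death(death_rates, curve)
            life[site.name] = LifeLostResult(
                year, site.name, mean_age, group,
                absolute_life_lost(curve, group),
            )

        l_rel = relative_life_lost({s: r.life_lost for s, r in life.items()})
        life = {
            s: LifeLostResult(
                r.year, r.site, r.mean_age_at_death, r.group, r.life_lost, l_rel[s]
            )
            for s, r in life.items()
        }

        rows = []
        for site in self.sites:
            if site.fixed:
                rows.append(detriment_row(site))
            else:
                rows.append(
                    detriment_row(site, k=lethalities[site.name].k,
                                  l_rel=l_rel[site.name])
                )
        table = total_detriment(rows, year=year, expected_sites=self.sites)
        overall = overall_lethality(
            self.data, year, [s.name for s in self.computed_sites],
            curve=curve, policy=cfg.clamp_policy,
        )
        return YearBundle(year, table, lethalities, overall, life)


class DetrimentResults:
    """Fit output: per-year detriment tables, lethality and life-lost series.

    Attributes
    ----------
    bundles : dict[int, YearBundle]
        Complete per-year results, successful years only.
    failures : dict[int, Exception]
        Years that could not be evaluated, with their errors.
    """

    def __init__(
        self,
        model: DetrimentModel,
        bundles: dict[int, YearBundle],
        failures: dict[int, Exception],
    ) -> None:
        self.model = model
        self.bundles = bundles
        self.failures = failures

    @property
    def years(self) -> list[int]:
        return sorted(self.bundles)

    # -- tidy views ----------------------------------------------------------

    @property
    def total_detriment(self) -> pd.Series:
        """Year -> total detriment, per 10,000 persons per Sv."""
        return pd.Series(
            {y: b.table.total for y, b in sorted(self.bundles.items())},
            name="total_detriment_per_10k_sv",
        )

    @property
    def overall_lethality(self) -> pd.Series:
        """Year -> combined lethality over the computed sites."""
        return pd.Series(
            {y: b.overall.k for y, b in sorted(self.bundles.items())},
            name="overall_lethality",
        )

    def detriment_frame(self) -> pd.DataFrame:
        """Long table: year, site, k, q, l_rel, severity, detriment."""
        parts = []
        for year, b in sorted(self.bundles.items()):
            df = b.table.to_frame().reset_index()
            df.insert(0, "year", year)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    def lethality_frame(self) -> pd.DataFrame:
        """Long table of weighted cumulative rates and lethality per site-year."""
        rows = []
        for year, b in sorted(self.bundles.items()):
            for site, res in b.lethality.items():
                rows.append(
                    (year, site, res.mortality_weighted, res.incidence_weighted,
                     res.raw_k, res.k)
                )
            o = b.overall
            rows.append((year, ALL_SITES, o.mortality_weighted,
                         o.incidence_weighted, o.raw_k, o.k))
        return pd.DataFrame(
            rows,
            columns=["year", "site", "weighted_mortality_rate",
                     "weighted_incidence_rate", "raw_k", "k"],
        )

    def life_lost_frame(self) -> pd.DataFrame:
        rows = []
        for year, b in sorted(self.bundles.items()):
            for site, res in b.life_lost.items():
                rows.append(
                    (year, site, res.mean_age_at_death, res.group,
                     res.life_lost, res.relative_life_lost)
                )
        return pd.DataFrame(
            rows,
            columns=["year", "site", "mean_age_at_death", "age_group",
                     "life_lost_years", "l_rel"],
        )

    def series(self, site: str, quantity: str) -> pd.Series:
        """Per-year series of one site-level quantity.

        ``quantity`` is one of "k", "l_rel", "life_lost", "detriment".
        """
        getters = {
            "k": lambda b: b.lethality[site].k,
            "l_rel": lambda b: b.life_lost[site].relative_life_lost,
            "life_lost": lambda b: b.life_lost[site].life_lost,
            "detriment": lambda b: next(
                r.detriment for r in b.table.rows if r.site.name == site
            ),
        }
        if quantity not in getters:
            raise RadetrimentError(f"unknown quantity {quantity!r}")
        get = getters[quantity]
        return pd.Series(
            {y: get(b) for y, b in sorted(self.bundles.items())},
            name=f"{site}:{quantity}",
        )

    # -- reporting -----------------------------------------------------------

    def summary(self, year: int | None = None) -> str:
        """Human-readable per-organ table (1 dp detriments, 2 dp factors)."""
        if year is None:
            if len(self.bundles) != 1:
                raise RadetrimentError("summary() needs a year when several were fit")
            year = self.years[0]
        if year not in self.bundles:
            raise RadetrimentError(f"year {year} was not successfully fit")
        b = self.bundles[year]
        head = [
            f"ICRP 103 detriment — year {year}",
            f"overall lethality (computed sites): {b.overall.k:.2f}",
            "",
        ]
        return "\n".join(head) + b.table.summary()

    def to_csv(self, directory: str | Path) -> dict[str, Path]:
        """Write detriment/lethality/life-lost long tables plus totals."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        frames = {
            "detriment": self.detriment_frame(),
            "lethality": self.lethality_frame(),
            "life_lost": self.life_lost_frame(),
        }
        totals = pd.DataFrame(
            {
                "year": self.years,
                "total_detriment_per_10k_sv": self.total_detriment.values,
                "overall_lethality": self.overall_lethality.values,
            }
        )
        frames["totals"] = totals
        for name, df in frames.items():
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        return paths
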