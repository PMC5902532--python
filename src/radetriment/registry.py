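"""Registry-style tabular data: population at risk and event counts.

A :class:`RegistryDataset` holds, for each calendar year, the mean population
per age group plus death/incidence counts per cancer site, all on a common
:class:`~radetriment.grids.AgeGrid`.  All-cause deaths are stored under the
sentinel site :data:`ALL_CAUSE` (deaths only).

File format (long CSV, UTF-8, "." decimal separator):

* events:     ``year, age_lower, site, kind, count``
* population: ``year, age_lower, population``

The age rows of every series must tile the configured grid exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DomainError, MissingSeriesError, SchemaError
from .grids import AgeGrid

#: Sentinel site label for all-cause deaths (the survival-curve input).
ALL_CAUSE = "ALL_CAUSE"

KIND_DEATH = "death"
KIND_INCIDENCE = "incidence"
KINDS = (KIND_DEATH, KIND_INCIDENCE)

EVENT_COLUMNS = ["year", "age_lower", "site", "kind", "count"]
POPULATION_COLUMNS = ["year", "age_lower", "population"]


class RegistryDataset:
    """Per-year population and per-site event counts on a fixed age grid.

    Parameters
    ----------
    grid : AgeGrid
        The common age axis.
    population : Mapping[int, numpy.ndarray]
        Year -> population vector (length ``grid.m``), persons.
    events : Mapping[tuple[int, str, str], numpy.ndarray]
        (year, site, kind) -> count vector (length ``grid.m``).  Counts may
        be real-valued (expected-value synthetic data); they must be finite
        and non-negative.
    """

    def __init__(
        self,
        grid: AgeGrid,
        population: Mapping[int, np.ndarray],
        events: Mapping[tuple[int, str, str], np.ndarray],
    ) -> None:
        self.grid = grid
        self._population: dict[int, np.ndarray] = {}
        self._events: dict[tuple[int, str, str], np.ndarray] = {}
        for year, vec in population.items():
            arr = np.asarray(vec, dtype=float)
            self._check_vector(arr, f"population for year {year}")
            if np.any(arr <= 0):
                bad = int(np.argmin(arr))
                raise DomainError(
                    f"non-positive population in year {year}, age group starting at "
                    f"{grid.lower_bounds[bad]}"
                )
            self._population[int(year)] = arr
        for (year, site, kind), vec in events.items():
            arr = np.asarray(vec, dtype=float)
            self._check_vector(arr, f"{kind} counts for site {site!r}, year {year}")
            if np.any(arr < 0):
                raise DomainError(f"negative count in {kind} series for {site!r}, year {year}")
            if site == ALL_CAUSE and kind != KIND_DEATH:
                raise DomainError("ALL_CAUSE carries death counts only")
            self._events[(int(year), str(site), str(kind))] = arr

    def _check_vector(self, arr: np.ndarray, what: str) -> None:
        if arr.shape != (self.grid.m,):
            raise DomainError(
                f"{what}: expected {self.grid.m} age groups, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"{what}: non-finite values")

    # -- accessors ----------------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self._population)

    def sites(self, kind: str | None = None) -> list[str]:
        """Cancer sites present (excludes the ALL_CAUSE sentinel)."""
        found = {
            s for (_, s, k) in self._events if s != ALL_CAUSE and (kind is None or k == kind)
        }
        return sorted(found)

    def population(self, year: int) -> np.ndarray:
        try:
            return self._population[year]
        except KeyError:
            raise MissingSeriesError(f"no population data for year {year}") from None

    def counts(self, year: int, site: str, kind: str) -> np.ndarray:
        try:
            return self._events[(year, site, kind)]
        except KeyError:
            raise MissingSeriesError(
                f"no {kind} series for site {site!r} in year {year}"
            ) from None

    def has_series(self, year: int, site: str, kind: str) -> bool:
        return (year, site, kind) in self._events

    # -- round-tripping -----------------------------------------------------

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for (year, site, kind), arr in sorted(self._events.items()):
            for lower, count in zip(self.grid.lower_bounds, arr):
                rows.append((year, lower, site, kind, count))
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def population_frame(self) -> pd.DataFrame:
        rows = []
        for year, arr in sorted(self._population.items()):
            for lower, pop in zip(self.grid.lower_bounds, arr):
                rows.append((year, lower, pop))
        return pd.DataFrame(rows, columns=POPULATION_COLUMNS)

    def to_csv(self, directory: str | Path) -> tuple[Path, Path]:
        """Write ``events.csv`` and ``population.csv`` under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        events_path = directory / "events.csv"
        population_path = directory / "population.csv"
        self.events_frame().to_csv(events_path, index=False)
        self.population_frame().to_csv(population_path, index=False)
        return events_path, population_path

    @classmethod
    def from_csv(
        cls,
        events_path: str | Path,
        population_path: str | Path,
        grid: AgeGrid | None = None,
    ) -> "RegistryDataset":
        """Read and strictly validate the long-CSV pair.

        Schema violations raise :class:`SchemaError` with the 1-based line
        number of the offending row (header is line 1).
        """
        grid = grid or AgeGrid()
        pop_df = _read_table(population_path, POPULATION_COLUMNS)
        ev_df = _read_table(events_path, EVENT_COLUMNS)

        population: dict[int, np.ndarray] = {}
        for year, sub in pop_df.groupby("year"):
            population[int(year)] = _series_vector(
                sub, "population", grid, str(population_path)
            )
        events: dict[tuple[int, str, str], np.ndarray] = {}
        for (year, site, kind), sub in ev_df.groupby(["year", "site", "kind"]):
            if kind not in KINDS:
                line = int(sub.index[0]) + 2
                raise SchemaError(f"unknown kind {kind!r}", line=line, path=str(events_path))
            events[(int(year), str(site), str(kind))] = _series_vector(
                sub, "count", grid, str(events_path)
            )
        return cls(grid, population, events)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=str(path))
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns {missing}", line=1, path=str(path))
    numeric = [c for c in columns if c not in ("site", "kind")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise SchemaError(f"non-numeric or empty value in column {col!r}", line=line,
                              path=str(path))
        df[col] = vals
    return df


def _series_vector(sub: pd.DataFrame, value_col: str, grid: AgeGrid, path: str) -> np.ndarray:
    """Order one (year[,site,kind]) block onto the grid, demanding an exact tiling."""
    sub = sub.sort_values("age_lower")
    lowers = sub["age_lower"].to_numpy(dtype=float)
    expected = np.asarray(grid.lower_bounds, dtype=float)
    if len(lowers) != len(expected) or not np.array_equal(lowers, expected):
        line = int(sub.index[0]) + 2
        raise SchemaError(
            "age rows do not tile the configured grid "
            f"(expected lower bounds {list(expected)})",
            line=line,
            path=path,
        )
    return sub[value_col].to_numpy(dtype=float)


def subset_years(data: RegistryDataset, years: Iterable[int]) -> RegistryDataset:
    """A new dataset restricted to ``years``."""
    years = set(int(y) for y in years)
    return RegistryDataset(
        data.grid,
        {y: v for y, v in data._population.items() if y in years},
        {k: v for k, v in data._events.items() if k[0] in years},
    )
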