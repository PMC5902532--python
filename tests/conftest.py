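"""Shared fixtures: tiny hand-checkable registries on small age grids."""

import numpy as np
import pytest

from radetriment import ALL_CAUSE, KIND_DEATH, KIND_INCIDENCE, AgeGrid, RegistryDataset


@pytest.fixture
def grid18():
    """The default production grid: 18 five-year groups, 85+ open."""
    return AgeGrid()


@pytest.fixture
def grid2():
    """Minimal two-group closed grid for hand arithmetic."""
    return AgeGrid(lower_bounds=(0.0, 5.0), open_top=False)


def make_dataset(grid, year=2000, population=None, all_cause=None, **site_series):
    """Build a one-year RegistryDataset from per-site (deaths, cases) pairs.

    ``site_series`` maps site name -> (death_counts, incidence_counts);
    ``all_cause`` defaults to zero deaths (flat survival).
    """
    m = grid.m
    population = np.asarray(
        population if population is not None else np.full(m, 1000.0), dtype=float
    )
    events = {
        (year, ALL_CAUSE, KIND_DEATH): np.asarray(
            all_cause if all_cause is not None else np.zeros(m), dtype=float
        )
    }
    for site, (deaths, cases) in site_series.items():
        events[(year, site, KIND_DEATH)] = np.asarray(deaths, dtype=float)
        events[(year, site, KIND_INCIDENCE)] = np.asarray(cases, dtype=float)
    return RegistryDataset(grid, {year: population}, events)


@pytest.fixture
def hand_dataset(grid2):
    """The worked two-group example used across the lethality tests.

    N=(1000, 500); all-cause rates (0.05, 0.2) -> S=(e^-0.25, e^-1.25);
    one site with deaths (10, 30) and cases (40, 40).
    """
    return make_dataset(
        grid2,
        year=2000,
        population=[1000.0, 500.0],
        all_cause=[50.0, 100.0],  # rates 0.05 and 0.2
        tumour=([10.0, 30.0], [40.0, 40.0]),
    )
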