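"""Life-table core: rates, cumulative rates, survival, life expectancy."""

import numpy as np
import pytest

from radetriment import ALL_CAUSE, KIND_DEATH, AgeGrid, DomainError, MissingSeriesError
from radetriment.demography import (
    SURVIVAL_START,
    age_specific_rates,
    cumulative_rate,
    remaining_life_expectancy,
    survival_curve,
)

from conftest import make_dataset


class TestAgeGrid:
    def test_default_geometry(self, grid18):
        assert grid18.m == 18
        assert grid18.lower_bounds[0] == 0.0
        assert grid18.lower_bounds[-1] == 85.0
        assert grid18.midpoints[0] == 2.5
        assert grid18.midpoints[-1] == 87.5  # nominal open-top midpoint
        assert grid18.nominal_upper == 90.0

    @pytest.mark.parametrize(
        "age, group",
        [(0.0, 1), (4.999, 1), (5.0, 2), (12.5, 3), (84.9, 17), (85.0, 18), (120.0, 18)],
    )
    def test_group_mapping_half_open(self, grid18, age, group):
        assert grid18.group_of(age) == group

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lower_bounds=(0.0,)),  # fewer than two groups
            dict(lower_bounds=(5.0, 10.0)),  # first group not at 0
            dict(lower_bounds=(0.0, 5.0, 15.0)),  # non-constant width
            dict(lower_bounds=(0.0, 5.0), width=-5.0),
            dict(lower_bounds=(0.0, 5.0), top_midpoint=2.0),  # below top lower bound
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(DomainError):
            AgeGrid(**kwargs)


class TestAgeSpecificRates:
    def test_direct_ratio(self, grid2):
        data = make_dataset(grid2, population=[1000.0, 1000.0],
                            s=([10.0, 10.0], [10.0, 10.0]))
        r = age_specific_rates(data, 2000, "s", KIND_DEATH)
        assert np.allclose(r.rates, 0.01)

    def test_zero_counts_give_zero_rates(self, grid2):
        data = make_dataset(grid2, s=([0.0, 0.0], [0.0, 0.0]))
        assert np.all(age_specific_rates(data, 2000, "s", KIND_DEATH).rates == 0)

    def test_hand_evaluation(self, grid2):
        data = make_dataset(grid2, population=[200.0, 350.0],
                            s=([3.0, 7.0], [3.0, 7.0]))
        r = age_specific_rates(data, 2000, "s", KIND_DEATH)
        assert np.allclose(r.rates, [0.015, 0.02], rtol=0, atol=1e-15)

    def test_missing_series_is_loud(self, grid2):
        data = make_dataset(grid2, s=([1.0, 1.0], [1.0, 1.0]))
        with pytest.raises(MissingSeriesError, match="other"):
            age_specific_rates(data, 2000, "other", KIND_DEATH)

    def test_zero_population_rejected_with_location(self, grid2):
        with pytest.raises(DomainError, match="2000.*5|5.*2000"):
            make_dataset(grid2, population=[1000.0, 0.0],
                         s=([1.0, 1.0], [1.0, 1.0]))


class TestCumulativeRate:
    def test_constant_rate_sum(self):
        grid = AgeGrid(lower_bounds=tuple(float(a) for a in range(0, 50, 5)),
                       open_top=False)
        data = make_dataset(grid, population=np.full(10, 1000.0),
                            s=(np.full(10, 10.0), np.full(10, 10.0)))
        r = age_specific_rates(data, 2000, "s", KIND_DEATH)
        assert cumulative_rate(r) == pytest.approx(0.5, abs=1e-15)

    def test_partial_sum_and_monotonicity(self, grid2):
        data = make_dataset(grid2, population=[200.0, 350.0],
                            s=([3.0, 7.0], [3.0, 7.0]))
        r = age_specific_rates(data, 2000, "s", KIND_DEATH)
        p1 = cumulative_rate(r, 1)
        p2 = cumulative_rate(r, 2)
        assert p2 == pytest.approx(0.175, abs=1e-15)
        assert p1 == pytest.approx(0.075, abs=1e-15)
        assert p1 <= p2

    def test_additive_over_disjoint_ranges(self, grid18):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 50, grid18.m).astype(float)
        data = make_dataset(grid18, population=np.full(grid18.m, 1000.0),
                            s=(counts, counts))
        r = age_specific_rates(data, 2000, "s", KIND_DEATH)
        for split in (1, 5, 17):
            head = cumulative_rate(r, split)
            total = cumulative_rate(r)
            tail = float(np.sum(r.rates[split:]) * grid18.width)
            assert head + tail == pytest.approx(total, rel=1e-12)

    def test_out_of_range_upper_group(self, grid2):
        data = make_dataset(grid2, s=([1.0, 1.0], [1.0, 1.0]))
        r = age_specific_rates(data, 2000, "s", KIND_DEATH)
        for bad in (0, 3):
            with pytest.raises(DomainError):
                cumulative_rate(r, bad)


class TestSurvivalCurve:
    def test_no_hazard_means_unit_survival(self, grid18):
        data = make_dataset(grid18)
        assert np.all(survival_curve(data, 2000).values == 1.0)

    def test_hand_product(self, grid2):
        data = make_dataset(grid2, population=[1000.0, 500.0],
                            all_cause=[50.0, 100.0])
        s = survival_curve(data, 2000)
        assert np.allclose(s.values, np.exp([-0.25, -1.25]), rtol=1e-15)

    def test_constant_hazard_closed_form(self, grid18):
        mu = 0.01
        pop = np.full(grid18.m, 10_000.0)
        data = make_dataset(grid18, population=pop, all_cause=pop * mu)
        s = survival_curve(data, 2000)
        expected = np.exp(-mu * grid18.width * np.arange(1, grid18.m + 1))
        assert np.allclose(s.values, expected, rtol=1e-12)

    def test_equals_exp_of_cumulative_all_cause_rate(self, grid18):
        rng = np.random.default_rng(3)
        pop = np.full(grid18.m, 10_000.0)
        deaths = rng.integers(1, 500, grid18.m).astype(float)
        data = make_dataset(grid18, population=pop, all_cause=deaths)
        s = survival_curve(data, 2000)
        r = age_specific_rates(data, 2000, ALL_CAUSE, KIND_DEATH)
        for i in range(1, grid18.m + 1):
            partial = r.rates.copy()
            partial[i:] = 0.0
            assert s.values[i - 1] == pytest.approx(
                np.exp(-np.sum(partial) * grid18.width), rel=1e-14
            )

    def test_start_convention_shifts_by_one_group(self, grid2):
        data = make_dataset(grid2, population=[1000.0, 500.0],
                            all_cause=[50.0, 100.0])
        end = survival_curve(data, 2000)
        start = survival_curve(data, 2000, convention=SURVIVAL_START)
        assert start.values[0] == 1.0
        assert start.values[1] == pytest.approx(end.values[0], rel=1e-15)

    def test_unknown_convention_rejected(self, grid2):
        data = make_dataset(grid2)
        with pytest.raises(DomainError):
            survival_curve(data, 2000, convention="middle")


class TestRemainingLifeExpectancy:
    def test_zero_hazard_limit(self, grid18):
        data = make_dataset(grid18)
        curve = survival_curve(data, 2000)
        m, dA = grid18.m, grid18.width
        for i in (1, 7, m):
            assert remaining_life_expectancy(curve, i) == pytest.approx(
                dA * (m - i + 1), abs=1e-12
            )

    def test_top_group_under_zero_hazard(self, grid18):
        data = make_dataset(grid18)
        curve = survival_curve(data, 2000)
        assert remaining_life_expectancy(curve, grid18.m) == pytest.approx(5.0)

    def test_constant_hazard_geometric_closed_form(self, grid18):
        mu, dA, m = 0.02, grid18.width, grid18.m
        pop = np.full(m, 10_000.0)
        data = make_dataset(grid18, population=pop, all_cause=pop * mu)
        curve = survival_curve(data, 2000)
        for i in (1, 10, 18):
            closed = dA * (1 - np.exp(-mu * dA * (m - i + 1))) / (1 - np.exp(-mu * dA))
            assert remaining_life_expectancy(curve, i) == pytest.approx(
                closed, rel=1e-12
            )

    def test_decreases_when_late_survival_drops(self, grid18):
        pop = np.full(grid18.m, 10_000.0)
        low = make_dataset(grid18, population=pop, all_cause=pop * 0.01)
        hi_deaths = pop * 0.01
        hi_deaths[10:] *= 3  # worse hazard only at older ages
        high = make_dataset(grid18, population=pop, all_cause=hi_deaths)
        a_low = remaining_life_expectancy(survival_curve(low, 2000), 3)
        a_high = remaining_life_expectancy(survival_curve(high, 2000), 3)
        assert a_high < a_low

    def test_index_out_of_range(self, grid18):
        curve = survival_curve(make_dataset(grid18), 2000)
        for bad in (0, 19):
            with pytest.raises(DomainError):
                remaining_life_expectancy(curve, bad)
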