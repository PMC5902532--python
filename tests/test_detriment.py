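"""Quality-of-life weighting, severity, per-organ and total detriment."""

import numpy as np
import pytest

from radetriment import (
    CancerSite,
    DomainError,
    delta_severity_argmax,
    detriment_row,
    detriment_vs_common_lethality,
    quality_of_life,
    severity,
    severity_curve,
    total_detriment,
    usa_2012_detriment_table,
)
from radetriment.sites import ICRP103_SITES, SITE_BY_NAME, usa_2012_reference


class TestQualityOfLife:
    @pytest.mark.parametrize(
        "k, q_min, expected_2dp",
        [(0.46, 0.1, 0.51), (0.03, 0.2, 0.22)],
    )
    def test_reference_points_at_reporting_precision(self, k, q_min, expected_2dp):
        assert round(quality_of_life(k, q_min), 2) == expected_2dp

    @pytest.mark.parametrize("q_min", [0.0, 0.1, 0.2])
    def test_endpoint_identities(self, q_min):
        assert quality_of_life(0.0, q_min) == q_min
        assert quality_of_life(1.0, q_min) == 1.0

    def test_strictly_increasing_in_k(self):
        ks = np.linspace(0, 1, 101)
        qs = quality_of_life(ks, 0.1)
        assert np.all(np.diff(qs) > 0)

    @pytest.mark.parametrize("k, q_min", [(-0.1, 0.1), (1.1, 0.1), (0.5, 1.0), (0.5, -0.1)])
    def test_domain_checks(self, k, q_min):
        with pytest.raises(DomainError):
            quality_of_life(k, q_min)


class TestSeverity:
    def test_fully_lethal_saturates_at_l_rel(self):
        assert severity(1.0, 0.3, 1.0) == pytest.approx(1.0)
        assert severity(1.0, 0.9, 2.0) == pytest.approx(2.0)

    def test_nonlethal_floor(self):
        assert severity(0.0, 0.1, 1.0) == pytest.approx(0.1)

    def test_esophagus_hand_value(self):
        d = severity(0.94, 0.95, 0.95)
        assert d == pytest.approx(0.94715, abs=1e-10)
        assert 15 * d == pytest.approx(14.2, abs=0.05)  # printed D/R consistency


class TestDetrimentRow:
    def test_breast_row(self):
        row = detriment_row(SITE_BY_NAME["breast"], k=0.16, l_rel=1.03, q_override=0.24)
        assert row.detriment == pytest.approx(41.7, abs=0.05)

    def test_skin_q_equals_k_when_q_min_is_zero(self):
        row = detriment_row(SITE_BY_NAME["skin"], k=0.0023, l_rel=0.73)
        assert row.q == pytest.approx(0.0023, abs=1e-15)
        assert row.detriment == pytest.approx(3.35, abs=0.01)

    def test_fixed_rows_bypass_to_frozen_values(self):
        gonads = detriment_row(SITE_BY_NAME["gonads"])
        assert gonads.detriment == 25.4
        assert gonads.k == 0.80 and gonads.l_rel == 1.32
        remainder = detriment_row(SITE_BY_NAME["remainder"])
        assert remainder.detriment == 113.5

    def test_detriment_is_risk_times_severity(self):
        row = detriment_row(SITE_BY_NAME["lung"], k=0.83, l_rel=0.80)
        assert row.detriment == pytest.approx(row.site.risk * row.severity, rel=1e-12)

    def test_missing_inputs_for_computed_site(self):
        with pytest.raises(DomainError):
            detriment_row(SITE_BY_NAME["lung"])


class TestTotalDetriment:
    def _rows(self, scale=1.0):
        sites = [
            CancerSite("x", None, 10.0 * scale, 0.1),
            CancerSite("y", None, 20.0 * scale, 0.1),
        ]
        return [detriment_row(s, k=0.5, l_rel=1.0) for s in sites]

    def test_total_is_sum_of_rows(self):
        table = total_detriment(self._rows())
        assert table.total == pytest.approx(
            sum(r.detriment for r in table.rows), abs=1e-9
        )

    def test_linear_in_risk_coefficients(self):
        assert total_detriment(self._rows(2.0)).total == pytest.approx(
            2.0 * total_detriment(self._rows()).total, rel=1e-12
        )

    def test_single_row_table(self):
        rows = self._rows()[:1]
        assert total_detriment(rows).total == pytest.approx(rows[0].detriment)

    def test_row_order_is_irrelevant(self):
        rows = self._rows()
        assert total_detriment(rows).total == total_detriment(rows[::-1]).total

    def test_duplicate_and_missing_sites_rejected(self):
        rows = self._rows()
        with pytest.raises(DomainError):
            total_detriment([rows[0], rows[0]])
        with pytest.raises(DomainError):
            total_detriment(rows[:1], expected_sites=[r.site for r in rows])

    def test_percent_per_sv_view(self):
        table = usa_2012_detriment_table()
        assert table.total_percent_per_sv == pytest.approx(table.total / 100.0)


class TestWorkedExample:
    def test_printed_q_mode_reproduces_the_reference_table(self):
        table = usa_2012_detriment_table(q_source="printed")
        ref = usa_2012_reference()
        by_name = {r.site.name: r for r in table.rows}
        for name in ref.index:
            assert by_name[name].detriment == pytest.approx(
                float(ref.loc[name, "detriment"]), abs=0.15
            )
        assert table.total == pytest.approx(470.4, abs=0.5)

    def test_computed_q_mode_differs_only_through_q_rounding(self):
        printed = usa_2012_detriment_table("printed")
        computed = usa_2012_detriment_table("computed")
        # breast is the documented example: computed-q gives ~42.1 vs printed 41.7
        b_printed = next(r for r in printed.rows if r.site.name == "breast")
        b_computed = next(r for r in computed.rows if r.site.name == "breast")
        assert b_computed.detriment == pytest.approx(42.1, abs=0.1)
        assert b_printed.detriment == pytest.approx(41.7, abs=0.1)
        assert abs(printed.total - computed.total) < 2.0

    def test_summary_reports_rounded_total(self):
        text = usa_2012_detriment_table().summary()
        assert "470.6" in text  # recomputed total at 1 dp
        assert "% per Sv" in text


class TestSeverityCurves:
    @pytest.mark.parametrize("q_min", [0.0, 0.1, 0.2])
    def test_endpoints(self, q_min):
        d, dd = severity_curve(np.array([0.0, 1.0]), q_min)
        assert d[0] == q_min and d[1] == 1.0
        assert dd[0] == q_min and dd[1] == 0.0

    def test_zero_q_min_algebraic_identity(self):
        k = np.linspace(0, 1, 201)
        d, dd = severity_curve(k, 0.0)
        assert np.allclose(d, 2 * k - k**2, atol=1e-15)
        assert np.allclose(dd, k * (1 - k), atol=1e-15)

    def test_argmax_formula_matches_dense_grid(self):
        k = np.linspace(0.0, 1.0, 1_000_001)
        _, dd = severity_curve(k, 0.1)
        k_star = k[np.argmax(dd)]
        assert k_star == pytest.approx(delta_severity_argmax(0.1), abs=1e-6)
        assert delta_severity_argmax(0.1) == pytest.approx(4.0 / 9.0, abs=1e-15)
        assert dd.max() == pytest.approx(5.0 / 18.0, abs=1e-6)

    def test_severity_dominates_lethality(self):
        k = np.linspace(0, 1, 101)
        d, _ = severity_curve(k, 0.1)
        assert np.all(d >= k)
        assert np.all(d[:-1] > k[:-1])  # strict below k=1 for q_min > 0


class TestDetrimentVsCommonLethality:
    def test_saturation_at_full_lethality(self):
        ref = usa_2012_reference()
        fixed_total = sum(s.detriment for s in ICRP103_SITES if s.fixed)
        expected = fixed_total + sum(
            s.risk * float(ref.loc[s.name, "l_rel"])
            for s in ICRP103_SITES if not s.fixed
        )
        assert detriment_vs_common_lethality(1.0) == pytest.approx(expected, rel=1e-12)

    def test_floor_at_zero_lethality(self):
        ref = usa_2012_reference()
        fixed_total = sum(s.detriment for s in ICRP103_SITES if s.fixed)
        expected = fixed_total + sum(
            s.risk * s.q_min * float(ref.loc[s.name, "l_rel"])
            for s in ICRP103_SITES if not s.fixed
        )
        assert detriment_vs_common_lethality(0.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_non_decreasing(self):
        k = np.linspace(0, 1, 1001)
        for include_skin in (True, False):
            D = detriment_vs_common_lethality(k, include_skin=include_skin)
            assert np.all(np.diff(D) >= -1e-12)

    def test_excluding_skin_lowers_the_curve(self):
        k = np.linspace(0, 1, 11)
        with_skin = detriment_vs_common_lethality(k, include_skin=True)
        without = detriment_vs_common_lethality(k, include_skin=False)
        # equal at k = 0 only (skin has q_min = 0, so its severity vanishes)
        assert np.all(with_skin >= without)
        assert np.all(with_skin[1:] > without[1:])

    def test_degenerates_to_total_at_per_site_lethalities(self):
        # evaluating each site's severity at its own k reproduces the
        # computed-q worked-example total
        ref = usa_2012_reference()
        fixed_total = sum(s.detriment for s in ICRP103_SITES if s.fixed)
        total = fixed_total
        for s in ICRP103_SITES:
            if s.fixed:
                continue
            total += float(
                s.risk * severity_curve(
                    float(ref.loc[s.name, "k"]), s.q_min,
                    float(ref.loc[s.name, "l_rel"])
                )[0]
            )
        assert total == pytest.approx(
            usa_2012_detriment_table("computed").total, rel=1e-12
        )
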