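"""Extrapolation routes and annualization against published values."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from climvalue import (
    AttributableFractionInput,
    AttributionEstimate,
    IntervalValue,
    PrevalenceAttributionInput,
    StudyPeriod,
    annualize_deaths,
    attributable_deaths_from_fraction,
    attributable_deaths_from_prevalence,
    dengue_fraction_input,
    malaria_prevalence_input,
    round_persons,
)


def cumulative_record(central, start, end, lower=None, upper=None):
    return AttributionEstimate(
        study_label="Study",
        cause="Heat",
        period=StudyPeriod(start_year=start, end_year=end),
        deaths=IntervalValue(central=central, lower=lower, upper=upper),
        deaths_basis="cumulative",
        estimate_type="attribution",
    )


class TestAnnualize:
    def test_heat_toll_annualizes_to_published_rate(self):
        rec = annualize_deaths(cumulative_record(271_656, 1991, 2018))
        assert rec.deaths_basis == "annual"
        assert round_persons(rec.deaths.central) == 9_702

    def test_single_year_identity(self):
        rec = annualize_deaths(cumulative_record(100.0, 2006, 2006))
        assert rec.deaths.central == 100.0

    def test_inverse_recovers_cumulative(self):
        rec = cumulative_record(271_656, 1991, 2018, lower=112_140, upper=535_780)
        annual = annualize_deaths(rec)
        back = annual.deaths.scale(rec.period.n_years)
        assert back.central == pytest.approx(rec.deaths.central)
        assert back.lower == pytest.approx(rec.deaths.lower)
        assert back.upper == pytest.approx(rec.deaths.upper)

    def test_already_annual_warns_and_returns_unchanged(self):
        rec = cumulative_record(100.0, 2000, 2009).model_copy(
            update={"deaths_basis": "annual"}
        )
        with pytest.warns(UserWarning, match="no-op"):
            out = annualize_deaths(rec)
        assert out == rec


class TestFractionRoute:
    def test_dengue_reproduces_published_interval(self):
        deaths = attributable_deaths_from_fraction(dengue_fraction_input())
        rounded = deaths.rounded()
        assert (rounded.central, rounded.lower, rounded.upper) == (3_925, 1_915, 7_028)

    def test_zero_fraction_gives_zero_deaths(self):
        inp = AttributableFractionInput(
            fraction=IntervalValue(central=0.0, lower=0.0, upper=0.0),
            baseline_deaths_annual=IntervalValue(central=1e4, lower=5e3, upper=2e4),
        )
        out = attributable_deaths_from_fraction(inp)
        assert (out.central, out.lower, out.upper) == (0.0, 0.0, 0.0)

    def test_full_fraction_returns_baseline(self):
        baseline = IntervalValue(central=1e4, lower=5e3, upper=2e4)
        inp = AttributableFractionInput(
            fraction=IntervalValue(central=1.0, lower=1.0, upper=1.0),
            baseline_deaths_annual=baseline,
        )
        out = attributable_deaths_from_fraction(inp)
        assert (out.central, out.lower, out.upper) == (1e4, 5e3, 2e4)

    def test_absent_baseline_bounds_leave_output_unbounded(self):
        inp = AttributableFractionInput(
            fraction=IntervalValue(central=0.18, lower=0.11, upper=0.27),
            baseline_deaths_annual=IntervalValue(central=21_803),
        )
        assert not attributable_deaths_from_fraction(inp).has_bounds

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AttributableFractionInput(
                fraction=IntervalValue(central=1.2, lower=1.1, upper=1.3),
                baseline_deaths_annual=IntervalValue(central=100.0),
            )


class TestPrevalenceRoute:
    def test_malaria_reproduces_published_interval(self):
        deaths = attributable_deaths_from_prevalence(malaria_prevalence_input())
        rounded = deaths.rounded()
        assert (rounded.central, rounded.lower, rounded.upper) == (2_366, -4_925, 19_423)

    def test_output_lower_bound_negative_when_pp_change_crosses_zero(self):
        deaths = attributable_deaths_from_prevalence(malaria_prevalence_input())
        assert deaths.lower < 0 < deaths.central

    def test_zero_pp_change_gives_zero(self):
        inp = PrevalenceAttributionInput(
            prevalence_pp_change=IntervalValue(central=0.0, lower=0.0, upper=0.0),
            baseline_prevalence=0.24,
            total_deaths=IntervalValue(central=631_000, lower=394_000, upper=914_000),
        )
        out = attributable_deaths_from_prevalence(inp)
        assert (out.central, out.lower, out.upper) == (0.0, 0.0, 0.0)

    def test_pp_change_equal_to_baseline_gives_full_attribution(self):
        inp = PrevalenceAttributionInput(
            prevalence_pp_change=IntervalValue(central=24.0, lower=24.0, upper=24.0),
            baseline_prevalence=0.24,
            total_deaths=IntervalValue(central=631_000, lower=394_000, upper=914_000),
        )
        out = attributable_deaths_from_prevalence(inp)
        assert out.central == pytest.approx(631_000)
        assert out.lower == pytest.approx(394_000)
        assert out.upper == pytest.approx(914_000)

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PrevalenceAttributionInput(
                prevalence_pp_change=IntervalValue(central=0.1),
                baseline_prevalence=0.0,
                total_deaths=IntervalValue(central=1000.0),
            )


class TestProperties:
    @given(
        c=st.floats(1e2, 1e6),
        scale=st.floats(0.1, 10.0),
        f=st.floats(0.01, 1.0),
    )
    def test_scale_equivariance_in_baseline(self, c, scale, f):
        """Multiplying baseline deaths by c scales every output component by c."""
        baseline = IntervalValue(central=c, lower=0.5 * c, upper=2.0 * c)
        fraction = IntervalValue(central=f, lower=0.5 * f, upper=min(1.0, 1.5 * f))
        base = attributable_deaths_from_fraction(
            AttributableFractionInput(fraction=fraction, baseline_deaths_annual=baseline)
        )
        scaled = attributable_deaths_from_fraction(
            AttributableFractionInput(
                fraction=fraction, baseline_deaths_annual=baseline.scale(scale)
            )
        )
        assert scaled.central == pytest.approx(scale * base.central)
        assert scaled.lower == pytest.approx(scale * base.lower)
        assert scaled.upper == pytest.approx(scale * base.upper)

    @given(
        f=st.floats(0.01, 0.99),
        spread=st.floats(0.0, 0.5),
        b=st.floats(1e3, 1e6),
    )
    def test_ordering_preserved_for_nonnegative_fractions(self, f, spread, b):
        fraction = IntervalValue(
            central=f, lower=max(0.0, f - spread), upper=min(1.0, f + spread)
        )
        baseline = IntervalValue(central=b, lower=0.7 * b, upper=1.4 * b)
        out = attributable_deaths_from_fraction(
            AttributableFractionInput(fraction=fraction, baseline_deaths_annual=baseline)
        )
        assert out.lower <= out.central <= out.upper
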