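import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resno2.exposure import (
    ExposureError,
    OutdoorScaling,
    PersonDayExposure,
    acute_exposure,
    chronic_exposure,
    exceedance_days_per_year,
    exceedance_fraction,
    outdoor_attributable,
    person_series,
    weekly_expectation,
)
from resno2.multizone import N_INTERVALS, OUTDOORS, ConcentrationSeries


def brute_force_acute(series):
    """Independent oracle: enumerate all complete 6-interval windows."""
    best = -np.inf
    for i in range(len(series) - 5):
        best = max(best, sum(series[i : i + 6]) / 6.0)
    return best


series_strategy = st.lists(
    st.floats(min_value=0, max_value=1e4), min_size=N_INTERVALS, max_size=N_INTERVALS
)


def test_chronic_and_acute_on_constants():
    s = np.full(N_INTERVALS, 10.0)
    assert chronic_exposure(s) == pytest.approx(10.0)
    assert acute_exposure(s) == pytest.approx(10.0)


def test_chronic_single_spike():
    s = np.zeros(N_INTERVALS)
    s[37] = 144.0
    assert chronic_exposure(s) == pytest.approx(1.0)


def test_acute_single_spike_is_window_mean():
    s = np.zeros(N_INTERVALS)
    s[80] = 600.0
    assert acute_exposure(s) == pytest.approx(100.0)  # 600 / 6


@settings(derandomize=True, max_examples=30)
@given(series_strategy)
def test_stats_match_brute_force_and_ordering(values):
    s = np.array(values)
    assert chronic_exposure(s) == pytest.approx(s.mean(), rel=1e-12, abs=1e-12)
    acute = acute_exposure(s)
    assert acute == pytest.approx(brute_force_acute(s), rel=1e-12, abs=1e-9)
    # chronic <= acute <= max single interval
    assert chronic_exposure(s) <= acute + 1e-9
    assert acute <= s.max() + 1e-9


@settings(derandomize=True, max_examples=20)
@given(series_strategy, st.floats(min_value=0, max_value=100))
def test_acute_shift_invariance(values, shift):
    s = np.array(values)
    assert acute_exposure(s + shift) == pytest.approx(acute_exposure(s) + shift, rel=1e-9, abs=1e-6)


def test_wrong_length_rejected():
    with pytest.raises(ExposureError):
        chronic_exposure(np.zeros(100))
    with pytest.raises(ExposureError):
        acute_exposure(np.zeros(145))


# -- person series ---------------------------------------------------------

def _two_zone_series():
    values = {
        "no2_stove": np.vstack([np.full(N_INTERVALS, 5.0), np.full(N_INTERVALS, 1.0)]),
        "conta": np.vstack([np.full(N_INTERVALS, 40.0), np.full(N_INTERVALS, 20.0)]),
        "contb": np.zeros((2, N_INTERVALS)),
    }
    return ConcentrationSeries(["kitchen", "living"], np.array([50.0, 100.0]), values)


def test_person_series_fixed_zone_matches_zone_series():
    series = _two_zone_series()
    out = person_series(series, ["kitchen"] * N_INTERVALS, "no2_stove")
    np.testing.assert_allclose(out, series.values["no2_stove"][0])


def test_person_series_alternating_interleaves():
    series = _two_zone_series()
    occupancy = ["kitchen" if i % 2 == 0 else "living" for i in range(N_INTERVALS)]
    out = person_series(series, occupancy, "no2_stove")
    assert all(out[i] == (5.0 if i % 2 == 0 else 1.0) for i in range(N_INTERVALS))


def test_outdoor_occupant_gets_zero_stove_and_full_tracer():
    series = _two_zone_series()
    occupancy = [OUTDOORS] * N_INTERVALS
    assert chronic_exposure(person_series(series, occupancy, "no2_stove")) == 0.0
    assert chronic_exposure(person_series(series, occupancy, "conta")) == pytest.approx(100.0)


def test_unknown_zone_rejected():
    with pytest.raises(ExposureError):
        person_series(_two_zone_series(), ["attic"] * N_INTERVALS, "no2_stove")


# -- outdoor scaling -------------------------------------------------------

@pytest.mark.parametrize(
    "conta, outdoor, expected",
    [(100.0, 8.0, 8.0), (0.0, 10.0, 0.0), (50.0, 10.0, 5.0)],
)
def test_outdoor_attributable(conta, outdoor, expected):
    assert outdoor_attributable(OutdoorScaling(conta, outdoor)) == pytest.approx(expected)


def test_outdoor_attributable_is_bilinear():
    base = outdoor_attributable(OutdoorScaling(37.0, 6.0))
    assert outdoor_attributable(OutdoorScaling(74.0, 6.0)) == pytest.approx(2 * base)
    assert outdoor_attributable(OutdoorScaling(37.0, 12.0)) == pytest.approx(2 * base)


def test_tracer_exposure_above_reference_rejected():
    with pytest.raises(ExposureError):
        OutdoorScaling(101.0, 8.0)


# -- weekly weighting ------------------------------------------------------

def test_weekly_expectation_weights_by_prevalence():
    days = [PersonDayExposure(c, c) for c in (3.0, 6.0, 12.0)]
    out = weekly_expectation(days, [2 / 7, 4 / 7, 1 / 7])
    assert out.chron == pytest.approx((2 * 3 + 4 * 6 + 1 * 12) / 7)


def test_weekly_expectation_degenerate_weight():
    days = [PersonDayExposure(1.0, 2.0), PersonDayExposure(9.0, 10.0)]
    out = weekly_expectation(days, [0.0, 1.0])
    assert (out.chron, out.acute) == (9.0, 10.0)


def test_weekly_expectation_within_day_range():
    days = [PersonDayExposure(c, c + 1) for c in (1.0, 5.0, 9.0)]
    out = weekly_expectation(days, [1 / 3, 1 / 3, 1 / 3])
    assert 1.0 <= out.chron <= 9.0


# -- exceedances -----------------------------------------------------------

def test_no_exceedances_gives_zero_days():
    days = [(50.0, 0.5), (80.0, 0.5)]
    assert exceedance_days_per_year(days, threshold=100.0) == (0.0, 0.0)


def test_two_percent_of_days_is_about_seven_per_year():
    """The short-term standard's 2%-of-days allowance corresponds to ~7
    exceedance days per year."""
    days = [(150.0, 0.02), (10.0, 0.98)]
    low, high = exceedance_days_per_year(days, threshold=100.0)
    assert low == pytest.approx(7.3)
    assert round(low) == 7


def test_heavy_week_reweighting_brackets_range():
    # all exceedances come from heavy-use weeks: halving their prevalence
    # halves the exceedance days
    days = [(150.0, 0.10), (150.0, 0.00), (10.0, 0.90)]
    heavy = [True, True, False]
    low, high = exceedance_days_per_year(days, 100.0, heavy_mask=heavy, heavy_week_weights=(0.10, 0.05))
    assert high == pytest.approx(0.10 * 365)
    assert low == pytest.approx(0.05 * 365)


def test_exceedance_fraction_matches_enumeration(rng):
    values = rng.uniform(0, 200, size=50)
    weights = rng.dirichlet(np.ones(50))
    frac = exceedance_fraction(values, weights, 100.0)
    assert frac == pytest.approx(sum(w for v, w in zip(values, weights) if v >= 100.0))


def test_empty_day_results_rejected():
    with pytest.raises(ExposureError):
        exceedance_days_per_year([], 100.0)
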