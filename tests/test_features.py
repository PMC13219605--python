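"""Feature construction: wet-bulb formula, event extraction, antecedent
differentials, adaptive means and demographic compressions, each checked
against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from lethalheat.features import (
    FEATURE_NAMES,
    CountryDemographics,
    InsufficientHistoryError,
    PopulationPyramid,
    adaptive_humidity,
    adaptive_temperature,
    age_gradient,
    build_feature_vector,
    extract_events,
    humid_differential,
    mean_age,
    nearest_demographics,
    stull_wbt,
    stull_validity_mask,
    temp_differential,
)

from conftest import make_event, make_series, random_pyramid


# ---------------------------------------------------------------------------
# Stull wet-bulb temperature
# ---------------------------------------------------------------------------


class TestStullWbt:
    @pytest.mark.parametrize(
        "t, rh, expected",
        [
            # frozen from a 30-digit evaluation of the closed form
            (20.0, 50.0, 13.6993419689881399),
            (30.0, 99.0, 29.9357349729549332),
            (35.0, 60.0, 28.4882890239131316),
            (40.0, 30.0, 25.9193992640494152),
            (25.0, 80.0, 22.3295028535907298),
        ],
    )
    def test_matches_high_precision_evaluation(self, t, rh, expected):
        assert stull_wbt(t, rh) == pytest.approx(expected, abs=1e-9)

    def test_near_saturation_approaches_dry_bulb(self):
        assert abs(stull_wbt(30.0, 99.0) - 30.0) < 1.0

    def test_monotone_in_humidity_and_bounded_by_dry_bulb(self):
        # the fit's validity region excludes the cold-and-dry corner, where
        # it is genuinely non-monotone; grid stays inside validity
        rh = np.linspace(5.0, 99.0, 300)
        for t in (15.0, 30.0, 45.0):
            tw = stull_wbt(np.full_like(rh, t), rh)
            assert np.all(np.diff(tw) >= 0.0)
            assert np.all(tw <= t + 1.0)

    def test_nonpositive_humidity_rejected(self):
        with pytest.raises(ValueError, match="humidity"):
            stull_wbt(20.0, 0.0)

    def test_validity_mask_flags_out_of_range(self):
        mask = stull_validity_mask([20.0, 60.0, 20.0], [50.0, 50.0, 2.0])
        assert mask.tolist() == [True, False, False]


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------


def brute_force_events(series, percentile=0.90, min_duration=2):
    """Day-by-day scan oracle: independent of the run-length encoding."""
    thr = np.quantile(series.tmax, percentile)
    runs, cur = [], []
    for i in range(len(series)):
        if series.tmax[i] > thr:
            cur.append(i)
        else:
            if len(cur) >= min_duration:
                runs.append((cur[0], cur[-1]))
            cur = []
    if len(cur) >= min_duration:
        runs.append((cur[0], cur[-1]))
    return runs


class TestExtractEvents:
    def test_constant_series_has_no_events(self):
        series = make_series(np.full(730, 25.0))
        assert extract_events(series) == []

    def test_isolated_spike_yields_one_event_of_its_length(self):
        tmax = np.full(730, 20.0)
        tmax[300:305] = 35.0
        series = make_series(tmax)
        events = extract_events(series, min_duration=2)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_date == series.dates[300]
        assert ev.end_date == series.dates[304]
        assert ev.duration_days == 5
        assert ev.tmax == 35.0

    def test_matches_brute_force_scan_on_random_series(self, rng):
        tmax = rng.normal(20.0, 6.0, 365 * 4)
        series = make_series(tmax)
        events = extract_events(series, min_duration=2)
        expected = brute_force_events(series, min_duration=2)
        got = [
            (series.index_of(e.start_date), series.index_of(e.end_date))
            for e in events
        ]
        assert got == expected
        for e in events:
            i0, i1 = series.index_of(e.start_date), series.index_of(e.end_date)
            assert e.tmax == pytest.approx(series.tmax[i0 : i1 + 1].max())
            assert e.rh_mean == pytest.approx(series.rh[i0 : i1 + 1].mean())

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="year"):
            extract_events(make_series(np.arange(100.0)))

    def test_extraction_idempotent(self, rng):
        series = make_series(rng.normal(20.0, 6.0, 365 * 3))
        first = extract_events(series)
        second = extract_events(series)
        assert [(e.start_date, e.end_date) for e in first] == [
            (e.start_date, e.end_date) for e in second
        ]


# ---------------------------------------------------------------------------
# Differentials
# ---------------------------------------------------------------------------


class TestDifferentials:
    def test_constant_history_arithmetic(self):
        tmax = np.full(500, 25.0)
        tmax[400:403] = 35.0
        series = make_series(tmax)
        ev = make_event(series, series.dates[400], series.dates[402])
        assert temp_differential(series, ev, 30) == pytest.approx(10.0)

    def test_zero_when_event_equals_preceding_mean(self):
        series = make_series(np.full(500, 25.0), rh=np.full(500, 60.0))
        ev = make_event(series, series.dates[400], series.dates[402])
        assert temp_differential(series, ev, 30) == pytest.approx(0.0)
        assert humid_differential(series, ev, 30) == pytest.approx(0.0)

    def test_humidity_shift_arithmetic(self):
        rh = np.full(500, 60.0)
        rh[400:403] = 80.0
        series = make_series(np.full(500, 25.0), rh=rh)
        ev = make_event(series, series.dates[400], series.dates[402])
        assert humid_differential(series, ev, 30) == pytest.approx(20.0)

    @pytest.mark.parametrize("n", [30, 90, 180])
    def test_matches_brute_force_on_random_series(self, rng, n):
        series = make_series(
            rng.normal(20.0, 6.0, 800), rh=np.clip(rng.normal(60, 15, 800), 0, 100)
        )
        ev = make_event(series, series.dates[700], series.dates[705])
        i0 = 700
        expected_t = ev.tmax - sum(series.tmax[i0 - n : i0]) / n
        expected_h = ev.rh_mean - sum(series.rh[i0 - n : i0]) / n
        assert temp_differential(series, ev, n) == pytest.approx(expected_t, abs=1e-9)
        assert humid_differential(series, ev, n) == pytest.approx(expected_h, abs=1e-9)

    def test_insufficient_history_names_window(self):
        series = make_series(np.full(400, 25.0))
        ev = make_event(series, series.dates[20], series.dates[21])
        with pytest.raises(InsufficientHistoryError, match="90 days"):
            temp_differential(series, ev, 90)

    def test_translation_invariance_of_differential(self, rng):
        tmax = rng.normal(20.0, 6.0, 800)
        s1 = make_series(tmax)
        s2 = make_series(tmax + 7.5)
        e1 = make_event(s1, s1.dates[700], s1.dates[703])
        e2 = make_event(s2, s2.dates[700], s2.dates[703])
        for n in (30, 90, 180):
            assert temp_differential(s1, e1, n) == pytest.approx(
                temp_differential(s2, e2, n), abs=1e-9
            )
        assert e2.tmax == pytest.approx(e1.tmax + 7.5)

    def test_seasonal_sinusoid_dT180_peaks_near_seasonal_maximum(self):
        # the winter-to-summer transition maximises the 180-day
        # differential: the peak sits in the run-up to the seasonal
        # temperature maximum (a few weeks ahead of it), never in winter
        t = np.arange(365 * 3, dtype=float)
        tmax = 20.0 + 10.0 * np.sin(2 * np.pi * t / 365.25)
        series = make_series(tmax)
        vals = {}
        for d in range(400, 1050, 5):
            ev = make_event(series, series.dates[d], series.dates[d + 1])
            vals[d] = temp_differential(series, ev, 180)
        best_day = max(vals, key=vals.get)
        phase = best_day % 365.25
        # seasonal maxima sit at phase ≈ 91; winter minimum at ≈ 274
        assert min(abs(phase - 91.3), abs(phase - 91.3 + 365.25)) < 60
        assert vals[best_day] > 0


# ---------------------------------------------------------------------------
# Adaptive variables
# ---------------------------------------------------------------------------


class TestAdaptiveVariables:
    def test_constant_series_returns_constant(self):
        series = make_series(np.full(365 * 12, 20.0), rh=np.full(365 * 12, 55.0))
        ev = make_event(series, series.dates[4200], series.dates[4201])
        assert adaptive_temperature(series, ev, 30, 10) == pytest.approx(20.0)
        assert adaptive_humidity(series, ev, 30, 10) == pytest.approx(55.0)

    def test_matches_brute_force_double_sum(self, rng):
        tmax = rng.normal(18.0, 5.0, 365 * 12 + 3)
        series = make_series(tmax)
        ev = make_event(series, series.dates[4100], series.dates[4101])
        n, m = 30, 10
        total, count = 0.0, 0
        for j in range(m):
            anchor = ev.start_date - pd.DateOffset(years=j)
            end = (anchor - series.dates[0]).days
            total += sum(series.tmax[end - n : end])
            count += n
        assert adaptive_temperature(series, ev, n, m) == pytest.approx(
            total / count, abs=1e-9
        )

    def test_truncates_to_available_years(self, rng):
        # event in year 5 of a 6-year record: only 5 windows exist
        tmax = rng.normal(18.0, 5.0, 365 * 6)
        series = make_series(tmax)
        ev = make_event(series, series.dates[int(365 * 4.6)], series.dates[int(365 * 4.6) + 1])
        n = 30
        total, count = 0.0, 0
        for j in range(5):
            anchor = ev.start_date - pd.DateOffset(years=j)
            end = (anchor - series.dates[0]).days
            total += sum(series.tmax[end - n : end])
            count += n
        assert adaptive_temperature(series, ev, n, 10) == pytest.approx(
            total / count, abs=1e-9
        )

    def test_errors_below_three_years(self, rng):
        # only two complete annual windows fit before this event
        series = make_series(rng.normal(18.0, 5.0, 365 * 3))
        ev = make_event(series, series.dates[740], series.dates[741])
        with pytest.raises(InsufficientHistoryError, match="3 years"):
            adaptive_temperature(series, ev, 30, 10)

    def test_translation_shifts_adaptive_mean_exactly(self, rng):
        tmax = rng.normal(18.0, 5.0, 365 * 12)
        s1, s2 = make_series(tmax), make_series(tmax + 4.0)
        e1 = make_event(s1, s1.dates[4100], s1.dates[4101])
        e2 = make_event(s2, s2.dates[4100], s2.dates[4101])
        assert adaptive_temperature(s2, e2, 30, 10) == pytest.approx(
            adaptive_temperature(s1, e1, 30, 10) + 4.0, abs=1e-9
        )


# ---------------------------------------------------------------------------
# Demographic compressions
# ---------------------------------------------------------------------------


class TestPyramidCompressions:
    def test_two_bracket_midpoint_convention(self):
        pyr = PopulationPyramid([0.0, 5.0, 10.0], [0.5, 0.5, 0.0])
        assert mean_age(pyr) == pytest.approx(5.0)

    def test_all_mass_in_one_bracket(self):
        pyr = PopulationPyramid([0.0, 5.0, 10.0], [0.0, 0.0, 1.0])
        assert mean_age(pyr) == pytest.approx(12.5)

    def test_mean_age_matches_weighted_sum_oracle(self, rng):
        pyr = random_pyramid(rng)
        expected = sum(
            (lb + 2.5) * p for lb, p in zip(pyr.bracket_lower_bounds, pyr.proportions)
        )
        assert mean_age(pyr) == pytest.approx(expected, abs=1e-12)

    def test_uniform_pyramid_slope_undefined(self):
        pyr = PopulationPyramid([0.0, 5.0, 10.0, 15.0], [0.25] * 4)
        with pytest.raises(ValueError, match="undefined"):
            age_gradient(pyr)

    def test_decreasing_pyramid_has_negative_gradient(self):
        # young population: proportions fall with age, so cov(x, y) < 0
        props = np.array([0.4, 0.3, 0.2, 0.1])
        pyr = PopulationPyramid([0.0, 5.0, 10.0, 15.0], props)
        assert age_gradient(pyr) < 0.0

    def test_gradient_equals_ols_slope_of_age_on_proportion(self, rng):
        pyr = random_pyramid(rng)
        x, y = pyr.proportions, pyr.midpoints
        slope = np.polyfit(x, y, 1)[0]  # generic least-squares oracle
        assert age_gradient(pyr) == pytest.approx(slope, rel=1e-9)

    def test_pyramid_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationPyramid([0.0, 5.0, 10.0], [0.5, 0.4, 0.2])

    def test_nearest_year_ties_to_earlier(self, rng):
        recs = [
            CountryDemographics("c", y, 25.0, random_pyramid(rng), 0.5)
            for y in (1990, 2000)
        ]
        assert nearest_demographics(recs, 1995).year == 1990
        assert nearest_demographics(recs, 1996).year == 2000


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


class TestFeatureVector:
    def test_constant_corpus_gives_zero_differentials(self, rng):
        series = make_series(np.full(365 * 12, 22.0), rh=np.full(365 * 12, 55.0))
        ev = make_event(series, series.dates[4200], series.dates[4202])
        demo = {
            "countryA": [
                CountryDemographics("countryA", 1990, 26.0, random_pyramid(rng), 0.7)
            ]
        }
        vec = build_feature_vector(ev, series, demo)
        assert vec.dT30 == vec.dT90 == vec.dT180 == pytest.approx(0.0)
        assert vec.dH30 == vec.dH90 == vec.dH180 == pytest.approx(0.0)
        assert vec.adaptive_temp == pytest.approx(22.0)
        assert vec.adaptive_humid == pytest.approx(55.0)
        assert vec.max_temp == pytest.approx(22.0)

    def test_field_order_and_length_stable(self, rng):
        series = make_series(rng.normal(20, 5, 365 * 12))
        ev = make_event(series, series.dates[4100], series.dates[4101])
        demo = {
            "countryA": [
                CountryDemographics("countryA", 1991, 27.0, random_pyramid(rng), 0.6)
            ]
        }
        vec = build_feature_vector(ev, series, demo)
        assert len(FEATURE_NAMES) == 15
        assert list(vec.as_dict()) == list(FEATURE_NAMES)
        assert vec.as_array().shape == (15,)

    def test_composition_matches_component_oracles(self, rng):
        tmax = rng.normal(20, 5, 365 * 12)
        rh = np.clip(rng.normal(60, 12, 365 * 12), 1, 100)
        series = make_series(tmax, rh=rh)
        ev = make_event(series, series.dates[4150], series.dates[4153])
        pyr = random_pyramid(rng)
        demo = {"countryA": [CountryDemographics("countryA", 1991, 27.0, pyr, 0.6)]}
        vec = build_feature_vector(ev, series, demo)
        assert vec.dT90 == pytest.approx(temp_differential(series, ev, 90), abs=1e-12)
        assert vec.dH180 == pytest.approx(humid_differential(series, ev, 180), abs=1e-12)
        assert vec.adaptive_temp == pytest.approx(
            adaptive_temperature(series, ev, 30, 10), abs=1e-12
        )
        assert vec.mean_age == pytest.approx(mean_age(pyr), abs=1e-12)
        assert vec.age_gradient == pytest.approx(age_gradient(pyr), abs=1e-12)

    def test_city_mismatch_rejected(self, rng):
        series = make_series(np.full(365 * 12, 22.0))
        other = make_series(np.full(365 * 12, 22.0), city_id="cityB")
        ev = make_event(series, series.dates[4100], series.dates[4101])
        demo = {
            "countryA": [
                CountryDemographics("countryA", 1990, 26.0, random_pyramid(rng), 0.7)
            ]
        }
        with pytest.raises(ValueError, match="cityB"):
            build_feature_vector(ev, other, demo)
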