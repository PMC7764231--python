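"""National hourly means, daily maxima, peak ratios, and the three-rule
city response classification."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from lunarpm.effects import (
    city_hourly_series,
    classify_response,
    daily_max_series,
    national_hourly_mean,
    peak_ratio,
)
from lunarpm.io_formats import StationSeries
from lunarpm.periods import build_divisions

ANCHORS = [dt.date(2013, 2, 10), dt.date(2014, 1, 31)]
DIVISION = build_divisions(ANCHORS)[0]
NY = dt.date(2013, 2, 10)


def series_of(values_by_station, start="2013-02-01"):
    n = len(next(iter(values_by_station.values())))
    idx = pd.date_range(start, periods=n, freq="h")
    frame = pd.DataFrame(values_by_station, index=idx)
    stations = pd.DataFrame(
        {"lon": np.linspace(100, 101, len(values_by_station)),
         "lat": np.linspace(30, 31, len(values_by_station))},
        index=pd.Index(list(values_by_station)),
    )
    return StationSeries(stations, frame)


def test_national_mean_identity_and_two_station_average():
    one = series_of({"A": np.full(24, 33.0)})
    pd.testing.assert_series_equal(national_hourly_mean(one), one.frame["A"],
                                   check_names=False)
    two = series_of({"A": np.full(24, 10.0), "B": np.full(24, 30.0)})
    assert (national_hourly_mean(two) == 20.0).all()


def test_national_mean_matches_brute_force_on_random_fixture():
    rng = np.random.default_rng(6)
    data = {f"S{i}": rng.uniform(5, 150, 72) for i in range(5)}
    series = series_of(data)
    # knock out some observations
    frame = series.frame.copy()
    mask = rng.random(frame.shape) < 0.2
    frame[mask] = np.nan
    series = StationSeries(series.stations, frame)
    got = national_hourly_mean(series)
    for t in series.frame.index:
        vals = [series.frame.loc[t, s] for s in series.station_ids
                if not np.isnan(series.frame.loc[t, s])]
        if vals:
            assert got.loc[t] == pytest.approx(np.mean(vals))
        else:
            assert np.isnan(got.loc[t])


def test_daily_max_constant_day_ties_to_hour_zero():
    nat = national_hourly_mean(series_of({"A": np.full(24, 50.0)}))
    (rec,) = daily_max_series(nat)
    assert rec.max_hour == 0
    assert rec.max_value == 50.0


def test_daily_max_spike_at_2am_and_brute_force_agreement():
    rng = np.random.default_rng(3)
    vals = rng.uniform(20, 80, 10 * 24)
    start = pd.Timestamp("2013-02-05")
    idx = pd.date_range(start, periods=vals.size, freq="h")
    nat = pd.Series(vals, index=idx)
    nat.loc[pd.Timestamp("2013-02-10 02:00")] = 300.0
    records = daily_max_series(nat)
    by_date = {r.date: r for r in records}
    assert by_date[NY].max_hour == 2
    for r in records:
        day = nat[nat.index.normalize() == pd.Timestamp(r.date)]
        assert r.max_value == day.max()
        assert r.max_hour == int(day.idxmax().hour)


def test_daily_max_flags_fully_missing_day():
    idx = pd.date_range("2013-02-05", periods=48, freq="h")
    vals = np.full(48, np.nan)
    vals[24:] = 40.0
    records = daily_max_series(pd.Series(vals, index=idx))
    assert records[0].missing
    assert not records[1].missing


def test_peak_ratio_arithmetic_and_errors():
    idx = pd.date_range("2013-02-09", periods=72, freq="h")
    vals = np.full(72, 0.0)
    vals[0] = 100.0  # Feb 9 max
    vals[24] = 220.0  # Feb 10 max
    vals[48] = 120.0  # Feb 11 max
    daily = daily_max_series(pd.Series(vals, index=idx))
    assert peak_ratio(daily, NY) == pytest.approx(200.0)
    with pytest.raises(ValueError, match="flanking"):
        peak_ratio(daily, dt.date(2013, 2, 11))


def test_peak_ratio_equal_days_is_100_and_scale_invariant():
    rng = np.random.default_rng(8)
    vals = rng.uniform(30, 90, 5 * 24)
    idx = pd.date_range("2013-02-08", periods=vals.size, freq="h")
    daily_1 = daily_max_series(pd.Series(vals, index=idx))
    daily_c = daily_max_series(pd.Series(vals * 3.7, index=idx))
    assert peak_ratio(daily_c, NY) == pytest.approx(peak_ratio(daily_1, NY))
    flat = daily_max_series(pd.Series(np.tile(vals[:24], 5), index=idx))
    assert peak_ratio(flat, NY) == pytest.approx(100.0)


def test_peak_ratio_matches_tuned_spike_regime():
    """With the spike sized so the event-day maximum is 2.09x the flanking
    baseline, the measured ratio lands on 209%."""
    import dataclasses

    from lunarpm.effects import daily_max_series as dms
    from lunarpm.synthetic import SimulationConfig, generate_station_series

    base_cfg = SimulationConfig(
        n_stations=4,
        start_date=dt.date(2013, 2, 1),
        end_date=dt.date(2013, 2, 20),
        new_year_dates=(NY,),
        noise_sd=0.0,
        spike_peak=0.0,
        holiday_reduction=0.0,
        rng_seed=5,
    )
    series0, _ = generate_station_series(base_cfg)
    daily0 = {r.date: r for r in dms(national_hourly_mean(series0))}
    flank = np.mean(
        [daily0[NY - dt.timedelta(days=1)].max_value,
         daily0[NY + dt.timedelta(days=1)].max_value]
    )
    at_2am = national_hourly_mean(series0).loc[pd.Timestamp("2013-02-10 02:00")]
    spike = 2.09 * flank - at_2am
    series1, _ = generate_station_series(
        dataclasses.replace(base_cfg, spike_peak=float(spike))
    )
    daily1 = dms(national_hourly_mean(series1))
    assert peak_ratio(daily1, NY) == pytest.approx(209.0, rel=1e-6)


# ---------------------------------------------------------------------------
# classification


def celebration_series(fill=50.0):
    idx = pd.date_range("2013-02-09", periods=17 * 24, freq="h")
    return pd.Series(np.full(idx.size, fill), index=idx)


def test_rule1_spike_in_discharge_window_is_significant():
    city = celebration_series()
    city.loc[pd.Timestamp("2013-02-10 02:00")] = 300.0
    label = classify_response(city, DIVISION, city="X")
    assert label.category == "significant"


def test_rule2_dominant_increase_and_rate_is_obvious():
    city = celebration_series()
    # global max on a pre-New-Year evening, outside the discharge window
    city.loc[pd.Timestamp("2013-02-09 20:00")] = 400.0
    # New Year's 00:00-04:00 has the strictly largest increase and rate
    city.loc[pd.Timestamp("2013-02-10 04:00")] = 120.0
    label = classify_response(city, DIVISION, city="X")
    assert label.category == "obvious"
    assert label.evidence["ny_increase"] == pytest.approx(70.0)
    assert label.evidence["ny_increase_rate"] == pytest.approx(1.4)


def test_constant_series_is_weak():
    assert classify_response(celebration_series(), DIVISION).category == "weak"


def test_lantern_festival_days_are_excluded():
    city = celebration_series()
    # huge maximum during the Lantern period (lunar days 14-16) must not
    # prevent rule 1 from seeing the New-Year-window maximum
    city.loc[pd.Timestamp("2013-02-24 20:00")] = 500.0
    city.loc[pd.Timestamp("2013-02-10 02:00")] = 300.0
    assert classify_response(city, DIVISION).category == "significant"


def test_significant_invariant_under_increasing_transforms():
    rng = np.random.default_rng(12)
    city = celebration_series()
    city.iloc[:] = rng.uniform(20, 80, city.size)
    city.loc[pd.Timestamp("2013-02-10 02:00")] = 200.0
    assert classify_response(city, DIVISION).category == "significant"
    for k in range(20):
        a = rng.uniform(0.5, 3.0)
        b = rng.uniform(0, 50)
        c = rng.uniform(0.1, 2.0)
        transformed = a * city**1.0 + b + c * np.sqrt(city)  # strictly increasing
        assert classify_response(transformed, DIVISION).category == "significant"


def test_incomplete_new_year_window_warns():
    city = celebration_series()
    city.loc[pd.Timestamp("2013-02-10 00:00")] = np.nan
    with pytest.warns(UserWarning, match="incomplete"):
        classify_response(city, DIVISION)


def test_city_series_is_station_mean():
    series = series_of({"A": np.full(24, 10.0), "B": np.full(24, 50.0)})
    assert (city_hourly_series(series, ["A", "B"]) == 30.0).all()
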