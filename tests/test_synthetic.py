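"""Recovery-oriented checks of the synthetic world generator."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from lunarpm.periods import celebration_window
from lunarpm.retrieval import grid_feature_table
from lunarpm.aod_merge import merge_daily_aod
from lunarpm.synthetic import (
    SimulationConfig,
    generate_grids,
    generate_station_series,
    make_training_samples,
)


def flat_config(**kw) -> SimulationConfig:
    base = dict(
        n_stations=3,
        grid_extent=(100.0, 101.0, 30.0, 31.0),
        start_date=dt.date(2013, 1, 25),
        end_date=dt.date(2013, 3, 10),
        new_year_dates=(dt.date(2013, 2, 10),),
        seasonal_amplitude=0.0,
        diurnal_amplitude=0.0,
        spatial_amplitude=0.0,
        noise_sd=0.0,
        spike_peak=0.0,
        holiday_reduction=0.0,
        baseline_mean=50.0,
        rng_seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_degenerate_config_gives_exact_constant():
    series, _ = generate_station_series(flat_config())
    assert (series.frame.to_numpy() == 50.0).all()


def test_spike_puts_global_maximum_at_2am_new_year():
    cfg = flat_config(
        seasonal_amplitude=30.0, diurnal_amplitude=15.0, spatial_amplitude=8.0,
        noise_sd=10.0, spike_peak=250.0, holiday_reduction=0.1,
    )
    series, truth = generate_station_series(cfg)
    national = series.frame.mean(axis=1)
    at = national.idxmax()
    assert at == pd.Timestamp("2013-02-10 02:00")
    assert truth.event_calendar == [{"date": dt.date(2013, 2, 10), "magnitude": 250.0}]


def test_seed_determinism_and_sensitivity():
    cfg = flat_config(noise_sd=10.0, spike_peak=100.0)
    s1, _ = generate_station_series(cfg)
    s2, _ = generate_station_series(dataclasses.replace(cfg))
    pd.testing.assert_frame_equal(s1.frame, s2.frame)
    s3, _ = generate_station_series(dataclasses.replace(cfg, rng_seed=4))
    assert not s1.frame.equals(s3.frame)


def test_concentrations_are_non_negative():
    cfg = flat_config(baseline_mean=10.0, noise_sd=40.0, ar1_coefficient=0.8)
    series, _ = generate_station_series(cfg)
    assert (series.frame.to_numpy() >= 0).all()


def test_holiday_reduction_lowers_celebration_mean():
    """With emission reduction and no spike, the celebration-period mean sits
    strictly below the mean of equal-length flanking windows."""
    cfg = flat_config(
        seasonal_amplitude=20.0, diurnal_amplitude=10.0, spatial_amplitude=5.0,
        holiday_reduction=0.15, spike_peak=0.0, noise_sd=0.0,
    )
    series, _ = generate_station_series(cfg)
    win = celebration_window(cfg.new_year_dates[0])
    daily = series.frame.mean(axis=1)
    dates = daily.index.normalize()

    def mean_between(a, b):
        sel = np.asarray((dates >= pd.Timestamp(a)) & (dates <= pd.Timestamp(b)))
        return daily[sel].mean()

    cel = mean_between(win.start_date, win.end_date)
    pre = mean_between(win.start_date - dt.timedelta(days=17),
                       win.start_date - dt.timedelta(days=1))
    post = mean_between(win.end_date + dt.timedelta(days=1),
                        win.end_date + dt.timedelta(days=17))
    assert cel < (pre + post) / 2


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="n_stations"):
        flat_config(n_stations=0).validate()
    with pytest.raises(ValueError, match="spike_hours"):
        flat_config(spike_hours=(25,)).validate()
    with pytest.raises(ValueError, match="resolution"):
        flat_config(grid_resolution=0.0).validate()
    with pytest.raises(ValueError, match="span"):
        flat_config(new_year_dates=(dt.date(2020, 1, 1),)).validate()


@pytest.fixture(scope="module")
def short_world():
    cfg = flat_config(
        seasonal_amplitude=20.0, spatial_amplitude=8.0, diurnal_amplitude=10.0,
        grid_extent=(100.0, 102.0, 30.0, 32.0),
        end_date=dt.date(2013, 2, 20), cloud_missing_prob=0.0,
    )
    series, truth = generate_station_series(cfg)
    return cfg, truth


def test_all_aod_missing_when_cloud_prob_is_one(short_world):
    cfg, truth = short_world
    cfg1 = dataclasses.replace(cfg, cloud_missing_prob=1.0)
    grids = generate_grids(cfg1, truth)
    for fields in grids.values():
        assert np.isnan(fields["terra_aod"].data).all()
        assert np.isnan(fields["aqua_aod"].data).all()


def test_noiseless_features_reproduce_truth_exactly(short_world):
    cfg, truth = short_world
    grids = generate_grids(cfg, truth)
    for fields in grids.values():
        merged = merge_daily_aod(fields["terra_aod"], fields["aqua_aod"])
        tbl = grid_feature_table(
            {"aod": merged,
             **{k: fields[k] for k in ("rh", "temp", "ws", "sp", "hpbl")}}
        )
        np.testing.assert_allclose(
            truth.true_mapping(tbl), fields["pm25_true"].data.ravel(), rtol=1e-10
        )


def test_missing_fraction_matches_binomial_expectation(short_world):
    cfg, truth = short_world
    p = 0.5
    cfg2 = dataclasses.replace(cfg, cloud_missing_prob=p)
    grids = generate_grids(cfg2, truth)
    flags = np.concatenate(
        [np.isnan(f["terra_aod"].data).ravel() for f in grids.values()]
        + [np.isnan(f["aqua_aod"].data).ravel() for f in grids.values()]
    )
    n = flags.size
    assert n >= 10_000
    se = np.sqrt(p * (1 - p) / n)
    assert abs(flags.mean() - p) < 3 * se


def test_training_samples_have_complete_predictors(short_world):
    cfg, truth = short_world
    cfg3 = dataclasses.replace(cfg, cloud_missing_prob=0.3)
    grids = generate_grids(cfg3, truth)
    tbl = make_training_samples(grids, 500, seed=0)
    assert len(tbl) == 500
    assert not tbl.isna().any().any()
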