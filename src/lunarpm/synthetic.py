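"""Synthetic station networks, PM2.5 series, and AOD/meteorology grids.

The generator emulates the statistical structure the downstream analysis
assumes, with known ground truth so every stage can be checked by recovery:

* hourly station PM2.5 = baseline + winter-peaking seasonal cosine +
  bimodal diurnal term (morning and late-evening maxima) + AR(1) noise,
  multiplied by a holiday emission-reduction factor over each 17-day
  celebration window, plus a firework spike in the configured hours of
  each New Year's Day (peaking at 02:00 by default);
* daily 0.1-degree meteorology fields, smooth in space and AR(1) in time;
* Terra-like and Aqua-like AOD fields obtained by *inverting* a known
  smooth nonlinear mapping at the daily PM2.5 level, with independent
  cloud-driven missingness per overpass.

The true AOD/meteorology -> PM2.5 mapping is

    PM2.5 = AOD * (c0 + c_rh * RH + c_hpbl * exp(-HPBL / s))

so retrieval models can be scored against an exactly known answer.
Concentrations are truncated at zero (a multiplicative log-normal noise
model is available as an option).  All output is bit-reproducible from
``rng_seed``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_formats import GridField, StationSeries, UNITS
from .periods import celebration_window

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_station_series",
    "generate_grids",
    "make_training_samples",
]

_DAYS_PER_YEAR = 365.25


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults give a winter-China-like regime."""

    n_stations: int = 20
    grid_extent: tuple[float, float, float, float] = (100.0, 105.0, 30.0, 35.0)
    #: (lon_min, lon_max, lat_min, lat_max) in degrees
    grid_resolution: float = 0.1
    start_date: dt.date = dt.date(2013, 1, 18)
    end_date: dt.date = dt.date(2013, 4, 30)
    new_year_dates: tuple[dt.date, ...] = (dt.date(2013, 2, 10),)
    seasonal_amplitude: float = 30.0  # ug/m3
    diurnal_amplitude: float = 15.0  # ug/m3
    baseline_mean: float = 55.0  # ug/m3
    spatial_amplitude: float = 8.0  # ug/m3, smooth station-to-station contrast
    noise_sd: float = 10.0  # ug/m3, stationary AR(1) SD
    ar1_coefficient: float = 0.6
    spike_peak: float = 250.0  # ug/m3 added at the spike's central hour
    spike_hours: tuple[int, ...] = (0, 1, 2, 3, 4)
    holiday_reduction: float = 0.1  # fractional emission cut in celebration window
    cloud_missing_prob: float = 0.3
    aod_noise_sd: float = 0.0  # dimensionless, per-overpass AOD error
    noise_model: str = "truncate"  # or "lognormal"
    spiked_stations: Optional[Sequence[int]] = None  # indices; None = all
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be at least 1")
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        for d in self.new_year_dates:
            if not self.start_date <= d <= self.end_date:
                raise ValueError(f"new_year_date {d} outside simulated span")
        if any(not 0 <= h <= 23 for h in self.spike_hours):
            raise ValueError("spike_hours must lie in 0-23")
        for name in ("seasonal_amplitude", "diurnal_amplitude", "noise_sd",
                     "spike_peak", "spatial_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if not 0 <= self.holiday_reduction < 1:
            raise ValueError("holiday_reduction must be in [0, 1)")
        if not 0 <= self.cloud_missing_prob <= 1:
            raise ValueError("cloud_missing_prob must be in [0, 1]")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        if self.noise_model not in ("truncate", "lognormal"):
            raise ValueError("noise_model must be 'truncate' or 'lognormal'")


#: coefficients of the true AOD/meteorology -> PM2.5 mapping
MAPPING_COEFS = {"c0": 80.0, "c_rh": 0.5, "c_hpbl": 25.0, "hpbl_scale": 1000.0}


def _smooth_field(rng: np.random.Generator, n_modes: int = 3) -> np.ndarray:
    """Coefficients (amp, kx, ky, phase) of a low-order sinusoid sum."""
    amps = rng.uniform(0.4, 1.0, n_modes)
    amps /= np.abs(amps).sum()
    kx = rng.uniform(0.5, 2.0, n_modes)
    ky = rng.uniform(0.5, 2.0, n_modes)
    ph = rng.uniform(0, 2 * np.pi, n_modes)
    return np.stack([amps, kx, ky, ph], axis=1)


def _eval_field(coefs: np.ndarray, lon, lat, extent) -> np.ndarray:
    lon_min, lon_max, lat_min, lat_max = extent
    u = (np.asarray(lon, dtype=float) - lon_min) / (lon_max - lon_min)
    v = (np.asarray(lat, dtype=float) - lat_min) / (lat_max - lat_min)
    out = np.zeros(np.broadcast(u, v).shape)
    for amp, kx, ky, ph in coefs:
        out = out + amp * np.sin(2 * np.pi * (kx * u + ky * v) + ph)
    return out


def _seasonal(doy, amplitude: float) -> np.ndarray:
    """Winter-peaking annual cycle, maximum on 15 January (day-of-year 15)."""
    return amplitude * np.cos(2 * np.pi * (np.asarray(doy, dtype=float) - 15.0) / _DAYS_PER_YEAR)


def _diurnal(hour, amplitude: float) -> np.ndarray:
    """Two Gaussian bumps: morning (09:00) and late evening (22:30)."""
    h = np.asarray(hour, dtype=float)
    out = np.zeros_like(h)
    for centre, sd in ((9.0, 2.0), (22.5, 1.5)):
        d = np.abs(h - centre)
        d = np.minimum(d, 24.0 - d)  # circular distance
        out = out + np.exp(-0.5 * (d / sd) ** 2)
    return amplitude * out


def _spike_weight(hour, spike_hours: Sequence[int]) -> np.ndarray:
    """Gaussian discharge profile over the configured hours, peak at centre."""
    hours = np.sort(np.asarray(spike_hours))
    centre = float(np.median(hours))
    h = np.asarray(hour, dtype=float)
    w = np.exp(-0.5 * ((h - centre) / 1.3) ** 2)
    return np.where(np.isin(h, hours), w, 0.0)


@dataclass
class GroundTruth:
    """Everything needed to score a recovery of the synthetic world."""

    config: SimulationConfig
    station_locations: list[tuple[float, float]]
    event_calendar: list[dict]
    spatial_coefs: np.ndarray
    mapping_coefs: dict = field(default_factory=lambda: dict(MAPPING_COEFS))

    def spatial(self, lon, lat) -> np.ndarray:
        return self.config.spatial_amplitude * _eval_field(
            self.spatial_coefs, lon, lat, self.config.grid_extent
        )

    def true_mapping(self, features: pd.DataFrame) -> np.ndarray:
        """Evaluate the known mapping on rows with aod, rh, hpbl columns."""
        c = self.mapping_coefs
        aod = features["aod"].to_numpy(dtype=float)
        rh = features["rh"].to_numpy(dtype=float)
        hpbl = features["hpbl"].to_numpy(dtype=float)
        return aod * (c["c0"] + c["c_rh"] * rh
                      + c["c_hpbl"] * np.exp(-hpbl / c["hpbl_scale"]))

    def _holiday_factor(self, date: dt.date) -> float:
        for ny in self.config.new_year_dates:
            if date in celebration_window(ny):
                return 1.0 - self.config.holiday_reduction
        return 1.0

    def daily_truth(self, date: dt.date, lon, lat) -> np.ndarray:
        """Deterministic daily-mean PM2.5 at the given locations (ug/m3)."""
        cfg = self.config
        doy = date.timetuple().tm_yday
        diurnal_mean = float(np.mean(_diurnal(np.arange(24), cfg.diurnal_amplitude)))
        det = (
            cfg.baseline_mean
            + self.spatial(lon, lat)
            + _seasonal(doy, cfg.seasonal_amplitude)
            + diurnal_mean
        ) * self._holiday_factor(date)
        spike = 0.0
        if cfg.spike_peak > 0 and date in set(cfg.new_year_dates):
            w = _spike_weight(np.arange(24), cfg.spike_hours)
            spike = cfg.spike_peak * float(w.sum()) / 24.0
        return np.maximum(det + spike, 0.0)


# ---------------------------------------------------------------------------


def _hourly_index(cfg: SimulationConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start_date)
    end = pd.Timestamp(cfg.end_date) + pd.Timedelta(hours=23)
    return pd.date_range(start, end, freq="h")


def generate_station_series(
    config: SimulationConfig,
) -> tuple[StationSeries, GroundTruth]:
    """Simulate the hourly station network; returns the series and its truth."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 1])
    lon_min, lon_max, lat_min, lat_max = config.grid_extent
    lons = rng.uniform(lon_min, lon_max, config.n_stations)
    lats = rng.uniform(lat_min, lat_max, config.n_stations)
    spatial_coefs = _smooth_field(rng)
    truth = GroundTruth(
        config=config,
        station_locations=list(zip(lons.tolist(), lats.tolist())),
        event_calendar=[
            {"date": d, "magnitude": config.spike_peak}
            for d in config.new_year_dates
            if config.spike_peak > 0
        ],
        spatial_coefs=spatial_coefs,
    )

    idx = _hourly_index(config)
    hours = idx.hour.to_numpy()
    doy = idx.dayofyear.to_numpy()
    dates = idx.normalize()
    n_t, n_s = len(idx), config.n_stations

    base = (
        config.baseline_mean
        + _seasonal(doy, config.seasonal_amplitude)[:, None]
        + _diurnal(hours, config.diurnal_amplitude)[:, None]
        + truth.spatial(lons, lats)[None, :]
    )

    holiday = np.ones(n_t)
    for ny in config.new_year_dates:
        win = celebration_window(ny)
        in_win = np.asarray(
            (dates >= pd.Timestamp(win.start_date))
            & (dates <= pd.Timestamp(win.end_date))
        )
        holiday[in_win] = 1.0 - config.holiday_reduction
    det = base * holiday[:, None]

    if config.spike_peak > 0:
        spiked = (
            np.arange(n_s)
            if config.spiked_stations is None
            else np.asarray(list(config.spiked_stations), dtype=int)
        )
        w = _spike_weight(hours, config.spike_hours)
        for ny in config.new_year_dates:
            on_day = np.asarray(dates == pd.Timestamp(ny))
            det[np.ix_(on_day, spiked)] += config.spike_peak * w[on_day][:, None]

    if config.noise_sd > 0:
        z = rng.standard_normal((n_t, n_s))
        phi = config.ar1_coefficient
        innov_sd = config.noise_sd * np.sqrt(1.0 - phi**2)
        noise = lfilter([1.0], [1.0, -phi], z * innov_sd, axis=0)
    else:
        noise = np.zeros((n_t, n_s))

    if config.noise_model == "lognormal":
        values = det * np.exp(noise / max(config.baseline_mean, 1.0))
    else:
        values = np.maximum(det + noise, 0.0)

    ids = [f"S{i:03d}" for i in range(n_s)]
    stations = pd.DataFrame({"lon": lons, "lat": lats}, index=pd.Index(ids))
    frame = pd.DataFrame(values, index=idx, columns=ids)
    return StationSeries(stations, frame), truth


# ---------------------------------------------------------------------------
# gridded fields

# per-variable climatology: (mean, spatial amp, daily AR(1) anomaly SD,
# seasonal amp with summer maximum, clip bounds)
_MET_SPEC = {
    "rh": (60.0, 10.0, 8.0, 0.0, (5.0, 100.0)),
    "temp": (280.0, 4.0, 3.0, 8.0, None),
    "ws": (3.0, 1.0, 0.8, 0.0, (0.2, None)),
    "sp": (101325.0, 300.0, 150.0, 0.0, None),
    "hpbl": (600.0, 150.0, 120.0, 250.0, (80.0, None)),
}

_VAR_UNITS = {"rh": UNITS["RH"], "temp": UNITS["TEMP"], "ws": UNITS["WS"],
              "sp": UNITS["SP"], "hpbl": UNITS["HPBL"]}


def _grid_axes(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lon_min, lon_max, lat_min, lat_max = cfg.grid_extent
    res = cfg.grid_resolution
    lons = np.arange(lon_min + res / 2, lon_max, res)
    lats = np.arange(lat_min + res / 2, lat_max, res)
    return lats, lons


def generate_grids(
    config: SimulationConfig, truth: GroundTruth
) -> dict[dt.date, dict[str, GridField]]:
    """Daily Terra/Aqua AOD and meteorology grids consistent with the truth.

    Returns, per day, fields keyed ``terra_aod``, ``aqua_aod``, ``rh``,
    ``temp``, ``ws``, ``sp``, ``hpbl`` plus the noiseless ``pm25_true``
    target used by recovery tests.  AOD is the true mapping inverted at the
    daily PM2.5 level, with optional noise and independent per-overpass
    cloud masking.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 2])
    lats, lons = _grid_axes(config)
    lon2d, lat2d = np.meshgrid(lons, lats)
    days = pd.date_range(config.start_date, config.end_date, freq="D")
    n_d = len(days)

    met_patterns = {k: _smooth_field(rng) for k in _MET_SPEC}
    phi = 0.7  # day-to-day persistence of meteorology
    met_anom = {
        k: lfilter([1.0], [1.0, -phi],
                   rng.standard_normal(n_d) * _MET_SPEC[k][2] * np.sqrt(1 - phi**2))
        for k in _MET_SPEC
    }

    c = truth.mapping_coefs
    out: dict[dt.date, dict[str, GridField]] = {}
    for i, ts in enumerate(days):
        day = ts.date()
        doy = ts.dayofyear
        fields: dict[str, GridField] = {}
        met_vals = {}
        for k, (mean, s_amp, _t_sd, seas_amp, clip) in _MET_SPEC.items():
            f = (
                mean
                + s_amp * _eval_field(met_patterns[k], lon2d, lat2d, config.grid_extent)
                + seas_amp * np.cos(2 * np.pi * (doy - 196.0) / _DAYS_PER_YEAR)
                + met_anom[k][i]
            )
            if clip is not None:
                f = np.clip(f, clip[0], clip[1])
            met_vals[k] = f
            fields[k] = GridField(k.upper() if k != "temp" else "TEMP",
                                  _VAR_UNITS[k], day, f, lats, lons)

        pm_true = truth.daily_truth(day, lon2d, lat2d)
        a = (c["c0"] + c["c_rh"] * met_vals["rh"]
             + c["c_hpbl"] * np.exp(-met_vals["hpbl"] / c["hpbl_scale"]))
        aod_true = pm_true / a
        for sat in ("terra", "aqua"):
            aod = aod_true.copy()
            if config.aod_noise_sd > 0:
                aod = np.maximum(
                    aod + rng.normal(0.0, config.aod_noise_sd, aod.shape), 0.0
                )
            if config.cloud_missing_prob > 0:
                cloud = rng.random(aod.shape) < config.cloud_missing_prob
                aod = np.where(cloud, np.nan, aod)
            fields[f"{sat}_aod"] = GridField("AOD", UNITS["AOD"], day, aod, lats, lons)
        fields["pm25_true"] = GridField("PM2.5", UNITS["PM2.5"], day, pm_true,
                                        lats, lons)
        out[day] = fields
    return out


def make_training_samples(
    daily_grids: dict[dt.date, dict[str, GridField]],
    n_samples: int,
    seed: int = 0,
    label_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Draw a retrieval training table from generated grids.

    Pools all pixels with a complete predictor set (merged Terra/Aqua AOD,
    all meteorology), labels them with the noiseless daily truth plus
    optional Gaussian noise, and samples ``n_samples`` rows without
    replacement.
    """
    from .aod_merge import merge_daily_aod
    from .retrieval import grid_feature_table

    rng = np.random.default_rng(seed)
    tables = []
    for day, fields in daily_grids.items():
        merged = merge_daily_aod(fields["terra_aod"], fields["aqua_aod"])
        tbl = grid_feature_table(
            {"aod": merged, **{k: fields[k] for k in ("rh", "temp", "ws", "sp", "hpbl")}}
        )
        tbl["pm25"] = fields["pm25_true"].data.ravel()
        tbl["year"] = day.year
        tables.append(tbl.dropna())
    pool = pd.concat(tables, ignore_index=True)
    if len(pool) < n_samples:
        raise ValueError(f"only {len(pool)} complete pixels available")
    pick = rng.choice(len(pool), size=n_samples, replace=False)
    samples = pool.iloc[pick].reset_index(drop=True)
    if label_noise_sd > 0:
        samples["pm25"] = np.maximum(
            samples["pm25"] + rng.normal(0.0, label_noise_sd, len(samples)), 0.0
        )
    return samples
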