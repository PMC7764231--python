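"""Standard on-disk formats for station series and gridded fields.

Two containers travel through the whole pipeline:

``StationSeries``
    Hourly surface PM2.5 observations for a network of located monitoring
    stations, stored wide (one column per station) on a naive hourly
    ``DatetimeIndex``.  All stations share a single national clock.

``GridField``
    One georeferenced raster (0.1 degree by default) of a single variable
    for a single calendar day, with explicit missingness encoded as NaN.
    Registration is pixel-center: the ``lats``/``lons`` coordinate vectors
    give cell centres.

Serialization: station series go to CSV in long form
(``station_id, lon, lat, timestamp, pm25``), grids to NetCDF through
xarray with CF-style ``lat``/``lon`` coordinates.  Both round-trip exactly,
including the missing mask.  Timestamps are written ISO-8601 with no
timezone suffix and interpreted in the configured national time zone.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "StationSeries",
    "GridField",
    "FormatError",
    "ValidationError",
    "read_station_csv",
    "write_station_csv",
    "read_grid",
    "write_grid",
    "UNITS",
]

#: canonical units per variable name
UNITS = {
    "AOD": "1",
    "RH": "%",
    "TEMP": "K",
    "WS": "m/s",
    "SP": "Pa",
    "HPBL": "m",
    "PM2.5": "ug/m3",
}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """In-memory data violate a container invariant."""


@dataclass
class StationSeries:
    """Hourly PM2.5 for a located station network.

    Parameters
    ----------
    stations : pandas.DataFrame
        Indexed by ``station_id`` (str), columns ``lon`` and ``lat`` in
        degrees.
    frame : pandas.DataFrame
        Wide hourly values in ug/m3: index is a naive hourly
        ``DatetimeIndex``, one column per station id, NaN marks missing.
    """

    stations: pd.DataFrame
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        st = self.stations
        if st.index.has_duplicates:
            dup = st.index[st.index.duplicated()][0]
            raise ValidationError(f"duplicate station id {dup!r}")
        if ((st["lon"] < -180) | (st["lon"] > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        if ((st["lat"] < -90) | (st["lat"] > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError("series index must be a DatetimeIndex")
        if len(idx) > 1:
            steps = np.diff(idx.asi8)
            if (steps <= 0).any():
                raise ValidationError("timestamps must be strictly increasing")
            if (steps != 3_600_000_000_000).any():
                raise ValidationError("timestamps must be hourly")
        missing_cols = set(self.frame.columns) - set(st.index)
        if missing_cols:
            raise ValidationError(f"values for unknown stations: {sorted(missing_cols)}")
        vals = self.frame.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative PM2.5 concentration")
        # normalise metadata so round-trips compare equal
        self.stations.index.name = "station_id"
        self.frame.columns.name = None
        self.frame.index.name = None

    @property
    def station_ids(self) -> list[str]:
        return list(self.stations.index)

    def subset(self, station_ids) -> "StationSeries":
        ids = list(station_ids)
        return StationSeries(self.stations.loc[ids], self.frame[ids])

    def to_long(self) -> pd.DataFrame:
        """Long-form view with columns station_id, lon, lat, timestamp, pm25."""
        long = (
            self.frame.rename_axis("timestamp")
            .reset_index()
            .melt(id_vars="timestamp", var_name="station_id", value_name="pm25")
        )
        long = long.merge(self.stations, left_on="station_id", right_index=True)
        return long[["station_id", "lon", "lat", "timestamp", "pm25"]].sort_values(
            ["station_id", "timestamp"], kind="stable", ignore_index=True
        )


@dataclass
class GridField:
    """A single-variable daily raster with explicit missingness (NaN)."""

    variable: str
    units: str
    date: dt.date
    data: np.ndarray  # shape (nlat, nlon), float, NaN = missing
    lats: np.ndarray  # cell-centre latitudes, ascending
    lons: np.ndarray  # cell-centre longitudes, ascending

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.data.shape != (self.lats.size, self.lons.size):
            raise ValidationError(
                f"raster shape {self.data.shape} does not match coordinates "
                f"({self.lats.size}, {self.lons.size})"
            )
        if self.variable == "AOD" and np.nanmin(self.data, initial=np.inf) < 0:
            raise ValidationError("AOD must be non-negative where present")

    @property
    def mask(self) -> np.ndarray:
        """Boolean missing mask (True = missing)."""
        return np.isnan(self.data)

    def same_geometry(self, other: "GridField") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.lats, other.lats)
            and np.allclose(self.lons, other.lons)
        )

    def copy_with(self, data: np.ndarray, variable: str | None = None,
                  units: str | None = None) -> "GridField":
        return GridField(
            variable=variable or self.variable,
            units=units if units is not None else (UNITS.get(variable or self.variable, self.units)),
            date=self.date,
            data=data,
            lats=self.lats.copy(),
            lons=self.lons.copy(),
        )

    def to_dataarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.data,
            dims=("lat", "lon"),
            coords={"lat": self.lats, "lon": self.lons},
            name=self.variable,
            attrs={"units": self.units, "date": self.date.isoformat()},
        )
        da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return da


# ---------------------------------------------------------------------------
# station CSV


def write_station_csv(series: StationSeries, path) -> None:
    long = series.to_long()
    long = long.copy()
    long["timestamp"] = long["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    long.to_csv(path, index=False, float_format="%.17g")  # exact round-trip


def read_station_csv(path) -> StationSeries:
    try:
        raw = pd.read_csv(path, dtype={"station_id": str}, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed CSV: {exc}") from exc
    required = {"station_id", "lon", "lat", "timestamp", "pm25"}
    if not required.issubset(raw.columns):
        raise FormatError(f"missing columns: {sorted(required - set(raw.columns))}")
    for col in ("lon", "lat", "pm25"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"malformed value in column {col!r} at line {line}")
        raw[col] = coerced
    if (raw["pm25"] < 0).any():
        line = int(np.flatnonzero((raw["pm25"] < 0).to_numpy())[0]) + 2
        raise ValidationError(f"negative concentration at line {line}")
    raw["timestamp"] = pd.to_datetime(raw["timestamp"], format="ISO8601")
    if raw.duplicated(["station_id", "timestamp"]).any():
        row = raw[raw.duplicated(["station_id", "timestamp"])].iloc[0]
        raise ValidationError(
            f"duplicate key ({row['station_id']}, {row['timestamp']})"
        )
    stations = (
        raw[["station_id", "lon", "lat"]]
        .drop_duplicates("station_id")
        .set_index("station_id")
    )
    wide = raw.pivot(index="timestamp", columns="station_id", values="pm25")
    wide.columns.name = None
    wide.index.name = None
    return StationSeries(stations, wide[stations.index])


# ---------------------------------------------------------------------------
# grid NetCDF

_FILL = -9999.0


def write_grid(fld: GridField, path) -> None:
    da = fld.to_dataarray()
    da.to_netcdf(
        path,
        engine="scipy",
        encoding={fld.variable: {"_FillValue": _FILL}},
    )


def read_grid(path) -> GridField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if "lat" not in ds.coords or "lon" not in ds.coords:
            raise FormatError("missing lat/lon coordinate variables")
        data_vars = [v for v in ds.data_vars if ds[v].dims == ("lat", "lon")]
        if len(data_vars) != 1:
            raise FormatError(f"expected one (lat, lon) variable, found {data_vars}")
        name = data_vars[0]
        da = ds[name].load()
    date = dt.date.fromisoformat(da.attrs["date"])
    return GridField(
        variable=name,
        units=da.attrs.get("units", ""),
        date=date,
        data=da.values,
        lats=da["lat"].values,
        lons=da["lon"].values,
    )
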