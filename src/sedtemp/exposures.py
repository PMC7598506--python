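"""Per-child-day environmental covariates.

Builds the covariate vector used by the additive mixed models: daily
temperature metrics (maximum, mean, minimum, diurnal variation), total
precipitation interpolated from ground monitors, residential greenness
(NDVI) averaged in a buffer around the home, astronomical daylight hours,
and the school-day/holiday classification.

Conventions
-----------
* Coordinates are decimal degrees (WGS84); distances use a local
  equirectangular approximation, which is accurate to <0.1% over the
  ~50 km extent of a single metropolitan study area.
* Rasters are simple row-major 2-D arrays anchored at a south-west origin
  with a fixed metric cell size; row 0 is the southernmost row.
* NDVI is dimensionless in [-1, 1]; precipitation is mm/day; temperature
  is degrees Celsius.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "RasterGrid",
    "MissingExposureError",
    "CoverageError",
    "daylight_hours",
    "idw_interpolate",
    "season_for_date",
    "ndvi_buffer_mean",
    "assign_temperature",
    "nearest_station",
    "build_exposure_table",
    "local_xy",
]


class MissingExposureError(ValueError):
    """No source data available for a requested date/location."""


class CoverageError(ValueError):
    """A point falls outside the spatial coverage of a raster."""


def local_xy(lat, lon, ref_lat, ref_lon):
    """Project lat/lon to metres east/north of a reference point.

    Equirectangular: x = R·cos(ref_lat)·Δλ, y = R·Δφ. Adequate at city
    scale; do not use for continental distances.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    x = EARTH_RADIUS_M * np.cos(np.deg2rad(ref_lat)) * np.deg2rad(lon - ref_lon)
    y = EARTH_RADIUS_M * np.deg2rad(lat - ref_lat)
    return x, y


def _distance_m(lat1, lon1, lat2, lon2):
    ref_lat = (np.mean(np.asarray(lat1)) + np.mean(np.asarray(lat2))) / 2.0
    x1, y1 = local_xy(lat1, lon1, ref_lat, 0.0)
    x2, y2 = local_xy(lat2, lon2, ref_lat, 0.0)
    return np.hypot(x1 - x2, y1 - y2)


# ---------------------------------------------------------------------------
# Daylight (NOAA solar geometry)
# ---------------------------------------------------------------------------

#: Solar zenith for sunrise/sunset: 90° plus atmospheric refraction (34')
#: plus the solar semidiameter (16').
SUNRISE_ZENITH_DEG = 90.833


def _solar_declination(day_of_year: np.ndarray, year_length: float = 365.0):
    """Solar declination (radians) from the NOAA Fourier expansion."""
    g = 2.0 * np.pi / year_length * (day_of_year - 1)
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def daylight_hours(date, lat: float, lon: float = 0.0) -> float:
    """Hours between sunrise and sunset on `date` at (lat, lon).

    Uses the NOAA solar position equations with the standard
    sunrise/sunset zenith of 90.833° (refraction + solar radius). The
    duration of daylight is longitude-invariant to first order; `lon` is
    accepted for interface symmetry.

    Raises
    ------
    ValueError
        For |lat| >= 66°: polar day/night is out of scope.
    """
    if abs(lat) >= 66.0:
        raise ValueError(f"polar latitude {lat!r} unsupported (|lat| must be < 66)")
    date = pd.Timestamp(date)
    doy = float(date.dayofyear)
    year_length = 366.0 if date.is_leap_year else 365.0
    decl = _solar_declination(np.array(doy), year_length)
    phi = np.deg2rad(lat)
    cos_ha = np.cos(np.deg2rad(SUNRISE_ZENITH_DEG)) / (
        np.cos(phi) * np.cos(decl)
    ) - np.tan(phi) * np.tan(decl)
    ha = np.arccos(np.clip(cos_ha, -1.0, 1.0))
    return float(2.0 * np.rad2deg(ha) / 15.0)


# ---------------------------------------------------------------------------
# Inverse distance weighting
# ---------------------------------------------------------------------------

def idw_interpolate(
    stations: pd.DataFrame,
    lat: float,
    lon: float,
    date=None,
    power: float = 2.0,
    eps_m: float = 1.0,
) -> float:
    """Inverse-distance-weighted station value at a point.

    `stations` needs columns ``lat``, ``lon``, ``value`` and, if `date` is
    given, a ``date`` column to subset on. Weights are proportional to
    d^(-power) and normalised to sum to one; a station within `eps_m`
    metres of the target returns its value exactly (the d -> 0 limit).
    """
    df = stations
    if date is not None:
        df = df[pd.to_datetime(df["date"]).dt.normalize() == pd.Timestamp(date).normalize()]
    if len(df) == 0:
        raise MissingExposureError(f"no station observations for {date!r}")
    d = _distance_m(df["lat"].to_numpy(), df["lon"].to_numpy(), lat, lon)
    values = df["value"].to_numpy(dtype=float)
    hit = d < eps_m
    if hit.any():
        return float(values[np.argmax(hit)])
    w = d ** (-power)
    w = w / w.sum()
    return float(w @ values)


# ---------------------------------------------------------------------------
# NDVI rasters and buffers
# ---------------------------------------------------------------------------

Season = Literal["cold_dry", "warm_dry", "rainy"]


def season_for_date(date) -> Season:
    """Season classification: cold-dry Nov–Feb, warm-dry Mar–Apr, rainy May–Oct."""
    month = pd.Timestamp(date).month
    if month in (11, 12, 1, 2):
        return "cold_dry"
    if month in (3, 4):
        return "warm_dry"
    return "rainy"


@dataclasses.dataclass(frozen=True)
class RasterGrid:
    """Row-major raster anchored at a south-west origin.

    ``values[i, j]`` is the cell whose south-west corner sits
    ``j * cell_size_m`` east and ``i * cell_size_m`` north of
    (origin_lat, origin_lon). Cell membership uses the half-open
    convention [edge, edge + size): a point exactly on a shared corner
    belongs to the cell to its north-east.
    """

    origin_lat: float
    origin_lon: float
    cell_size_m: float
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size_m <= 0:
            raise ValueError("cell size must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self):
        return self.values.shape

    def _xy(self, lat, lon):
        return local_xy(lat, lon, self.origin_lat, self.origin_lon)

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; CoverageError outside."""
        x, y = self._xy(lat, lon)
        # nudge by a relative epsilon so a point on a shared cell corner
        # lands deterministically in the north-east cell despite fp error
        eps = 1e-9 * self.cell_size_m
        i = int(np.floor((y + eps) / self.cell_size_m))
        j = int(np.floor((x + eps) / self.cell_size_m))
        nrow, ncol = self.shape
        if not (0 <= i < nrow and 0 <= j < ncol):
            raise CoverageError(
                f"point ({lat:.5f}, {lon:.5f}) outside raster {self.name!r}"
            )
        return i, j

    def value_at(self, lat: float, lon: float) -> float:
        i, j = self.cell_index(lat, lon)
        return float(self.values[i, j])

    def cell_centers_xy(self):
        """Cell-centre coordinates in the raster's local metric frame."""
        nrow, ncol = self.shape
        cx = (np.arange(ncol) + 0.5) * self.cell_size_m
        cy = (np.arange(nrow) + 0.5) * self.cell_size_m
        return cx, cy


BUFFER_RADII_M = {"pixel": 0.0, "250m": 250.0, "500m": 500.0}


def ndvi_buffer_mean(
    grid: RasterGrid,
    lat: float,
    lon: float,
    buffer: str = "250m",
) -> float:
    """Mean NDVI of cells whose centres fall within the buffer radius.

    ``buffer`` is one of ``pixel`` (value of the containing cell),
    ``250m`` or ``500m``.
    """
    if buffer not in BUFFER_RADII_M:
        raise ValueError(f"unknown buffer {buffer!r}; expected one of {sorted(BUFFER_RADII_M)}")
    if buffer == "pixel":
        return grid.value_at(lat, lon)
    radius = BUFFER_RADII_M[buffer]
    i0, j0 = grid.cell_index(lat, lon)  # coverage check
    x, y = grid._xy(lat, lon)
    # restrict to the window of cells that could possibly intersect
    halo = int(np.ceil(radius / grid.cell_size_m)) + 1
    nrow, ncol = grid.shape
    r0, r1 = max(i0 - halo, 0), min(i0 + halo + 1, nrow)
    c0, c1 = max(j0 - halo, 0), min(j0 + halo + 1, ncol)
    cx, cy = grid.cell_centers_xy()
    within = (cx[None, c0:c1] - x) ** 2 + (cy[r0:r1, None] - y) ** 2 <= radius**2
    if not within.any():
        # buffer smaller than half a cell: fall back to the containing cell
        return grid.value_at(lat, lon)
    return float(grid.values[r0:r1, c0:c1][within].mean())


# ---------------------------------------------------------------------------
# Temperature assignment
# ---------------------------------------------------------------------------

def nearest_station(stations: pd.DataFrame, lat: float, lon: float) -> str:
    """station_id of the geodesically nearest station; ties go to the
    lexicographically smaller station_id."""
    sites = stations[["station_id", "lat", "lon"]].drop_duplicates("station_id")
    d = _distance_m(sites["lat"].to_numpy(), sites["lon"].to_numpy(), lat, lon)
    order = np.lexsort((sites["station_id"].astype(str).to_numpy(), np.round(d, 6)))
    return sites["station_id"].to_numpy()[order[0]]


def assign_temperature(
    source,
    lat: float,
    lon: float,
    date,
    mode: Literal["grid", "nearest_station"] = "grid",
) -> dict[str, float]:
    """Daily temperature metrics at a home location.

    ``mode='grid'``: `source` maps dates to dicts of metric -> RasterGrid
    (tmax/tmean/tmin); returns the containing 1-km cell's values.
    ``mode='nearest_station'``: `source` is a station table with columns
    station_id, lat, lon, date, tmax, tmean, tmin; returns the nearest
    station's record for the date.

    Diurnal variation is always recomputed as tmax - tmin.
    """
    date = pd.Timestamp(date).normalize()
    if mode == "grid":
        try:
            grids = source[date]
        except KeyError:
            raise MissingExposureError(f"no temperature grids for {date.date()}")
        out = {m: grids[m].value_at(lat, lon) for m in ("tmax", "tmean", "tmin")}
    elif mode == "nearest_station":
        sid = nearest_station(source, lat, lon)
        rows = source[
            (source["station_id"] == sid)
            & (pd.to_datetime(source["date"]).dt.normalize() == date)
        ]
        if len(rows) == 0:
            raise MissingExposureError(f"station {sid} has no record for {date.date()}")
        row = rows.iloc[0]
        out = {m: float(row[m]) for m in ("tmax", "tmean", "tmin")}
    else:
        raise ValueError(f"unknown temperature source mode {mode!r}")
    out["diurnal"] = out["tmax"] - out["tmin"]
    return out


# ---------------------------------------------------------------------------
# Exposure table assembly
# ---------------------------------------------------------------------------

def day_type_for(date, calendar: pd.DataFrame | None) -> str:
    """school_day vs holiday_or_weekend; school holidays count as the
    weekend class, and a weekend date is never a school day."""
    ts = pd.Timestamp(date).normalize()
    if ts.dayofweek >= 5:
        return "holiday_or_weekend"
    if calendar is not None:
        cal = calendar.set_index(pd.to_datetime(calendar["date"]).dt.normalize())
        if ts in cal.index and not bool(cal.loc[ts, "is_school_day"]):
            return "holiday_or_weekend"
    return "school_day"


def build_exposure_table(
    cohort: pd.DataFrame,
    dates: Sequence,
    *,
    temperature_source,
    temperature_mode: Literal["grid", "nearest_station"] = "grid",
    precip_stations: pd.DataFrame | None = None,
    ndvi_grids: dict[str, RasterGrid] | None = None,
    ndvi_buffer: str = "250m",
    calendar: pd.DataFrame | None = None,
    child_dates: pd.DataFrame | None = None,
    idw_power: float = 2.0,
) -> pd.DataFrame:
    """One covariate row per child-day.

    If `child_dates` (columns child_id, date) is given only those pairs are
    built, otherwise the full cohort × dates product. Child-days whose
    exposure sources are missing are dropped with a count attached to the
    result as ``result.attrs['n_dropped']``.
    """
    if child_dates is None:
        child_dates = pd.MultiIndex.from_product(
            [cohort["child_id"], pd.to_datetime(pd.Index(dates))],
            names=["child_id", "date"],
        ).to_frame(index=False)
    else:
        child_dates = child_dates[["child_id", "date"]].copy()
        child_dates["date"] = pd.to_datetime(child_dates["date"])

    homes = cohort.set_index("child_id")[["home_lat", "home_lon"]]
    rows, n_dropped = [], 0
    day_type_cache: dict[pd.Timestamp, str] = {}
    for child_id, date in child_dates.itertuples(index=False):
        lat, lon = homes.loc[child_id]
        date = pd.Timestamp(date).normalize()
        try:
            temps = assign_temperature(
                temperature_source, lat, lon, date, mode=temperature_mode
            )
            row = {"child_id": child_id, "date": date, **temps}
            if precip_stations is not None:
                row["precip_mm"] = idw_interpolate(
                    precip_stations, lat, lon, date=date, power=idw_power
                )
            if ndvi_grids is not None:
                grid = ndvi_grids[season_for_date(date)]
                row["ndvi"] = ndvi_buffer_mean(grid, lat, lon, buffer=ndvi_buffer)
            row["daylight_hours"] = daylight_hours(date, lat, lon)
            if date not in day_type_cache:
                day_type_cache[date] = day_type_for(date, calendar)
            row["day_type"] = day_type_cache[date]
        except (MissingExposureError, CoverageError, KeyError):
            n_dropped += 1
            continue
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    return out
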