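"""Synthetic cohort, weather, exposure, sleep and accelerometer generators.

Everything downstream of raw data collection can be exercised on data from
this module. The generators are calibrated so that their default output
reproduces the summary statistics of the study cohort they emulate —
559 Mexico City children aged 4–6, one week of wrist accelerometry each,
daily sedentary time averaging 56.0% (SD 6.0) of awake time, a tropical-
highland climate with mean daily maximum temperature 22.1 °C — while the
planted effect sizes (percent sedentary per unit covariate), the random-
intercept SD and the residual SD are free parameters, which makes
parameter-recovery experiments possible with known ground truth.

Two outcome paths exist, sharing one model family:

* :func:`generate_daily_direct` draws day-level percent sedentary directly
  from Y = intercept + beta'x + f(x) + u_child + eps (fast path);
* :func:`generate_epoch_stream` emits a full 10-s triaxial count stream
  whose awake epochs follow a two-state (sedentary/active) Markov chain
  with stationary sedentary occupancy equal to the same linear predictor,
  plus sleep epochs with low counts and optional inserted zero-count
  non-wear runs. Processing that stream with :mod:`sedtemp.accelerometry`
  converges to the direct path's daily means.

All randomness flows from an explicit integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give identical
output at every operation.
"""

from __future__ import annotations

import dataclasses
import functools as _functools
import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .accelerometry import CUTPOINT, EPOCH_SECONDS, EpochStream
from .exposures import RasterGrid, _solar_declination, local_xy

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "WeatherConfig",
    "SleepConfig",
    "EpochSimConfig",
    "PlantedTruth",
    "DEFAULT_BETA",
    "DEFAULT_COVARIATE_MEANS",
    "generate_cohort",
    "generate_weather",
    "generate_sleep_intervals",
    "generate_epoch_stream",
    "generate_daily_direct",
    "generate_school_calendar",
    "generate_stations",
    "generate_station_weather",
    "generate_ndvi_grids",
    "SyntheticTemperatureGrids",
    "sample_wear_dates",
    "build_synthetic_exposures",
    "generate_daily_dataset",
    "person_day_anchor_means",
    "daily_sleep_minutes",
    "daylight_hours_vec",
    "DEFAULT_BBOX",
    "STUDY_PERIOD",
]

#: lat_min, lat_max, lon_min, lon_max around the study area (Mexico City).
DEFAULT_BBOX = (19.30, 19.55, -99.25, -98.95)
STUDY_PERIOD = ("2013-01-01", "2015-12-31")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CohortConfig:
    """Cohort sampling distribution (defaults match the emulated cohort's
    published profile: age 4.8 (0.5) years on [4, 6.99], 51% male,
    maternal education 39.9/36.5/23.6%, BMI z 0.2 (1.1))."""

    age_mean: float = 4.8
    age_sd: float = 0.5
    age_range: tuple[float, float] = (4.0, 6.99)
    p_female: float = 0.49
    edu_probs: tuple[float, float, float] = (0.399, 0.365, 0.236)  # LHS, HS, MHS
    bmi_mean: float = 0.2
    bmi_sd: float = 1.1
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    bbox_margin: float = 0.08  # keep homes off the raster edge

    def validate(self):
        if not np.isclose(sum(self.edu_probs), 1.0, atol=1e-6):
            raise ValueError("maternal education proportions must sum to 1")
        if not (0.0 <= self.p_female <= 1.0):
            raise ValueError("p_female must be a probability")
        lat0, lat1, lon0, lon1 = self.bbox
        if lat0 >= lat1 or lon0 >= lon1:
            raise ValueError("empty bounding box")


@dataclasses.dataclass
class WeatherConfig:
    """Daily weather model: sinusoidal seasonal mean plus AR(1) anomalies
    for mean temperature and diurnal range; tmax/tmin are placed inside
    the range so that tmin <= tmean <= tmax holds by construction.
    Precipitation is hurdle-gamma, concentrated in the May–October rainy
    season. Defaults reproduce the study's climatology (tmax 22.1,
    tmean 15.4, tmin 10.2, diurnal 11.9 °C; ~2.8 mm/day)."""

    tmean_mean: float = 15.4
    tmean_seasonal_amp: float = 1.8
    tmean_peak_doy: float = 140.0  # warmest in May, before the rains
    tmean_ar_sd: float = 1.6
    ar_phi: float = 0.7
    diurnal_mean: float = 11.9
    diurnal_seasonal_amp: float = 2.0
    diurnal_peak_doy: float = 355.0  # widest range in the dry winter
    diurnal_ar_sd: float = 1.8
    diurnal_min: float = 0.5
    tmax_position: float = 0.5630  # (22.1 - 15.4) / 11.9
    wet_prob_rainy: float = 0.65
    wet_prob_dry: float = 0.10
    precip_shape: float = 0.9
    precip_mean_wet: float = 7.4


@dataclasses.dataclass
class SleepConfig:
    """Night sleep crossing midnight plus an optional afternoon nap;
    expected total 450 + 0.35*57 = 470 min/day, the cohort calibration."""

    night_mean: float = 450.0
    night_sd: float = 60.0
    bed_hour: float = 21.0
    bed_jitter_min: float = 40.0
    nap_prob: float = 0.35
    nap_mean: float = 57.0
    nap_sd: float = 20.0
    nap_hour: float = 14.5


@dataclasses.dataclass
class EpochSimConfig:
    """Epoch-level simulation knobs.

    ``mixing_epochs`` sets the Markov-chain time scale (mean epochs to
    leave the current behavioural regime); the within-day autocorrelation
    of activity is not identified by the day-level analysis, so it is an
    artifact choice exposed here. Non-wear runs are zero counts on all
    axes with lengths spanning both the 20- and 30-minute detector
    thresholds."""

    mixing_epochs: float = 12.0
    nonwear_runs_per_day: float = 0.8
    nonwear_min_minutes: float = 20.0
    nonwear_max_minutes: float = 180.0
    sleep_count_max: int = 30
    active_count_max: int = 3000
    occupancy_clip: tuple[float, float] = (1.0, 99.0)


DEFAULT_BETA = {
    "tmax": -0.26,
    "ndvi": 0.0004,
    "daylight_hours": -1.20,
    "sleep_minutes": -0.004,
    "bmi_z": -0.17,
    "sex[female]": 0.21,
    "maternal_edu[HS]": 0.42,
    "maternal_edu[more_than_HS]": 2.41,
    "day_type[holiday_or_weekend]": -0.42,
}

#: Long-run covariate means implied by the generator defaults, used to
#: anchor the intercept so the outcome mean lands on its target. Values
#: that depend on the seasonal sampling pattern (temperatures, daylight,
#: day type) are refined by :func:`person_day_anchor_means`.
DEFAULT_COVARIATE_MEANS = {
    "tmax": 22.1,
    "tmean": 15.4,
    "tmin": 10.2,
    "diurnal": 11.9,
    "ndvi": 0.19,
    "daylight_hours": 12.143,  # NOAA annual mean at 19.43 N
    "sleep_minutes": 470.0,
    "bmi_z": 0.2,
    "age": 4.8,
    "precip_mm": 2.8,
    "sex[female]": 0.49,
    "maternal_edu[HS]": 0.365,
    "maternal_edu[more_than_HS]": 0.236,
    "day_type[holiday_or_weekend]": 0.44,  # weekends plus school holidays
}


@_functools.lru_cache(maxsize=2)
def person_day_anchor_means(uneven_months: bool = True) -> dict[str, float]:
    """Expected covariate means over sampled person-days.

    Wear windows are drawn with the campaign's uneven monthly weights, so
    person-day expectations of seasonal covariates (temperature metrics,
    daylight, school-day share) differ slightly from plain annual means;
    the intercept calibration anchors on these so the outcome mean lands
    on its target under the default sampling."""
    cfg = WeatherConfig()
    days = pd.date_range(STUDY_PERIOD[0], STUDY_PERIOD[1], freq="D")[:-7]
    if uneven_months:
        w = MONTH_WEIGHTS[days.month - 1]
        w = w / w.sum()
    else:
        w = np.full(len(days), 1.0 / len(days))
    doy = days.dayofyear.to_numpy(float)
    tmean = _seasonal(doy, cfg.tmean_mean, cfg.tmean_seasonal_amp, cfg.tmean_peak_doy)
    diurnal = _seasonal(doy, cfg.diurnal_mean, cfg.diurnal_seasonal_amp, cfg.diurnal_peak_doy)
    tmax = tmean + cfg.tmax_position * diurnal
    lat_c = (DEFAULT_BBOX[0] + DEFAULT_BBOX[1]) / 2
    daylight = daylight_hours_vec(days, np.full(len(days), lat_c))
    cal = generate_school_calendar(tuple(sorted(days.year.unique())))
    cal_idx = cal.set_index(pd.to_datetime(cal["date"]))["is_school_day"]
    school = days.map(cal_idx).to_numpy(bool) & (days.dayofweek < 5)
    return {
        "tmax": float(w @ tmax),
        "tmean": float(w @ tmean),
        "tmin": float(w @ (tmax - diurnal)),
        "diurnal": float(w @ diurnal),
        "daylight_hours": float(w @ daylight),
        "day_type[holiday_or_weekend]": float(w @ (~school)),
    }


@dataclasses.dataclass
class PlantedTruth:
    """Ground-truth parameters of the outcome model.

    ``beta`` maps covariate names (dummy levels as ``col[level]``) to
    percent-sedentary-per-unit coefficients; ``smooth_functions`` maps
    covariate names to true nonlinear effects (centred contributions in
    percent). ``sigma_u`` and ``sigma_e`` are the participant and
    day-level SDs; the defaults 4.0/4.5 combine to about the observed
    total SD of 6 percent, which the study does not decompose.
    """

    intercept: float
    beta: dict[str, float] = dataclasses.field(default_factory=dict)
    smooth_functions: dict[str, Callable] = dataclasses.field(default_factory=dict)
    sigma_u: float = 4.0
    sigma_e: float = 4.5

    def __post_init__(self):
        if self.sigma_u < 0 or self.sigma_e <= 0:
            raise ValueError("sigma_u must be >= 0 and sigma_e > 0")

    @classmethod
    def calibrated(
        cls,
        beta: Mapping[str, float] | None = None,
        target_mean: float = 56.0,
        covariate_means: Mapping[str, float] | None = None,
        smooth_functions: dict[str, Callable] | None = None,
        sigma_u: float = 4.0,
        sigma_e: float = 4.5,
    ) -> "PlantedTruth":
        """Anchor the intercept so E[Y] at covariate means equals
        ``target_mean`` (56.0% by default)."""
        beta = dict(DEFAULT_BETA if beta is None else beta)
        means = dict(DEFAULT_COVARIATE_MEANS)
        means.update(person_day_anchor_means())
        if covariate_means:
            means.update(covariate_means)
        intercept = target_mean - sum(
            b * means.get(name, 0.0) for name, b in beta.items()
        )
        return cls(intercept, beta, smooth_functions or {}, sigma_u, sigma_e)

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        """Fixed-effect part of the outcome (no random intercept, no noise)."""
        eta = np.full(len(frame), self.intercept, dtype=float)
        for name, b in self.beta.items():
            if "[" in name:
                col, level = name[:-1].split("[")
                eta += b * (frame[col].astype(str) == level).to_numpy(float)
            else:
                eta += b * frame[name].to_numpy(float)
        for col, fn in self.smooth_functions.items():
            eta += np.asarray(fn(frame[col].to_numpy(float)), dtype=float)
        return eta


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _truncnorm_parent_params(mean, sd, lo, hi):
    """Parent (mu, sigma) so the [lo, hi]-truncated normal has the given
    mean and SD."""

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = scipy.stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    mu, log_sigma = scipy.optimize.fsolve(moments, [mean, np.log(sd)])
    return float(mu), float(np.exp(log_sigma))


def generate_cohort(
    n_children: int, config: CohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Sample a cohort table (child_id, age, sex, bmi_z, maternal_edu,
    home_lat, home_lon)."""
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.age_range
    mu, sigma = _truncnorm_parent_params(cfg.age_mean, cfg.age_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    age = scipy.stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                    size=n_children, random_state=rng)
    sex = np.where(rng.random(n_children) < cfg.p_female, "female", "male")
    edu = rng.choice(
        ["less_than_HS", "HS", "more_than_HS"], size=n_children, p=cfg.edu_probs
    )
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, n_children)
    lat0, lat1, lon0, lon1 = cfg.bbox
    m = cfg.bbox_margin
    lat = rng.uniform(lat0 + m * (lat1 - lat0), lat1 - m * (lat1 - lat0), n_children)
    lon = rng.uniform(lon0 + m * (lon1 - lon0), lon1 - m * (lon1 - lon0), n_children)
    return pd.DataFrame(
        {
            "child_id": [f"c{i:04d}" for i in range(n_children)],
            "age": age,
            "sex": sex,
            "bmi_z": bmi,
            "maternal_edu": edu,
            "home_lat": lat,
            "home_lon": lon,
        }
    )


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def _seasonal(doy: np.ndarray, mean: float, amp: float, peak_doy: float):
    return mean + amp * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(rng, n, phi, sd):
    """Stationary AR(1) anomalies; long series are recentred on zero so
    the realised climatological mean matches the configured one (the
    generator's contract is that long-run means equal the config)."""
    innov_sd = sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, n - 1) if n > 1 else []
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    if n >= 180:
        x -= x.mean()
    return x


def generate_weather(
    dates, config: WeatherConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """City-wide daily weather series over contiguous ``dates``.

    Returns date, tmax, tmean, tmin, diurnal, precip_mm with
    tmin <= tmean <= tmax and diurnal = tmax - tmin >= 0 on every day.
    """
    cfg = config or WeatherConfig()
    dates = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    if len(dates) > 1 and not (np.diff(dates.to_numpy()) == np.timedelta64(1, "D")).all():
        raise ValueError("dates must be contiguous daily")
    n = len(dates)
    rng = np.random.default_rng(seed)
    doy = dates.dayofyear.to_numpy(dtype=float)
    tmean = _seasonal(doy, cfg.tmean_mean, cfg.tmean_seasonal_amp, cfg.tmean_peak_doy)
    tmean = tmean + _ar1(rng, n, cfg.ar_phi, cfg.tmean_ar_sd) if cfg.tmean_ar_sd > 0 else tmean
    diurnal = _seasonal(doy, cfg.diurnal_mean, cfg.diurnal_seasonal_amp, cfg.diurnal_peak_doy)
    if cfg.diurnal_ar_sd > 0:
        diurnal = diurnal + _ar1(rng, n, cfg.ar_phi, cfg.diurnal_ar_sd)
    diurnal = np.maximum(diurnal, cfg.diurnal_min)
    tmax = tmean + cfg.tmax_position * diurnal
    tmin = tmax - diurnal
    rainy = np.isin(dates.month, (5, 6, 7, 8, 9, 10))
    p_wet = np.where(rainy, cfg.wet_prob_rainy, cfg.wet_prob_dry)
    wet = rng.random(n) < p_wet
    amounts = rng.gamma(
        cfg.precip_shape, cfg.precip_mean_wet / cfg.precip_shape, n
    )
    precip = np.where(wet, amounts, 0.0)
    return pd.DataFrame(
        {
            "date": dates,
            "tmax": tmax,
            "tmean": tmean,
            "tmin": tmin,
            "diurnal": diurnal,
            "precip_mm": precip,
        }
    )


def _spatial_anomaly(lat, lon, scale=1.2):
    """Deterministic smooth within-city temperature anomaly (°C)."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat0 = (DEFAULT_BBOX[0] + DEFAULT_BBOX[1]) / 2
    lon0 = (DEFAULT_BBOX[2] + DEFAULT_BBOX[3]) / 2
    return scale * (
        np.sin(2 * np.pi * (lon - lon0) / 0.6) * np.cos(2 * np.pi * (lat - lat0) / 0.5)
    )


def generate_stations(n_stations: int = 8, bbox=DEFAULT_BBOX, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    lat0, lat1, lon0, lon1 = bbox
    return pd.DataFrame(
        {
            "station_id": [f"st{i:02d}" for i in range(n_stations)],
            "lat": rng.uniform(lat0, lat1, n_stations),
            "lon": rng.uniform(lon0, lon1, n_stations),
        }
    )


def generate_station_weather(
    stations: pd.DataFrame, weather: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Per-station daily observations consistent with the city series:
    temperatures offset by the deterministic spatial anomaly, precipitation
    scaled by a smooth spatial factor."""
    rows = []
    for _, st in stations.iterrows():
        anom = float(_spatial_anomaly(st["lat"], st["lon"]))
        pfac = 1.0 + 0.3 * float(_spatial_anomaly(st["lat"], st["lon"], scale=1.0))
        df = weather.copy()
        for m in ("tmax", "tmean", "tmin"):
            df[m] = df[m] + anom
        df["diurnal"] = df["tmax"] - df["tmin"]
        df["precip_mm"] = np.maximum(df["precip_mm"] * pfac, 0.0)
        df.insert(0, "station_id", st["station_id"])
        df.insert(1, "lat", st["lat"])
        df.insert(2, "lon", st["lon"])
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class SyntheticTemperatureGrids:
    """Lazy date -> {metric: RasterGrid} mapping over a 1-km grid.

    Grid values are the city series for the day plus the deterministic
    spatial anomaly at each cell centre, so grid and station sources are
    mutually consistent.
    """

    def __init__(self, weather: pd.DataFrame, bbox=DEFAULT_BBOX, cell_km: float = 1.0):
        self._weather = weather.set_index(pd.to_datetime(weather["date"]).dt.normalize())
        self.bbox = bbox
        self.cell_m = cell_km * 1000.0
        lat0, lat1, lon0, lon1 = bbox
        x1, y1 = local_xy(lat1, lon1, lat0, lon0)
        self._nrow = int(np.ceil(y1 / self.cell_m))
        self._ncol = int(np.ceil(x1 / self.cell_m))
        cx = (np.arange(self._ncol) + 0.5) * self.cell_m
        cy = (np.arange(self._nrow) + 0.5) * self.cell_m
        clat = lat0 + np.rad2deg(cy / 6_371_000.0)
        clon = lon0 + np.rad2deg(cx / (6_371_000.0 * np.cos(np.deg2rad(lat0))))
        self._anom = _spatial_anomaly(clat[:, None], clon[None, :])
        self._cache: dict[pd.Timestamp, dict[str, RasterGrid]] = {}

    def __getitem__(self, date) -> dict[str, RasterGrid]:
        key = pd.Timestamp(date).normalize()
        if key not in self._cache:
            if key not in self._weather.index:
                raise KeyError(key)
            row = self._weather.loc[key]
            lat0, _, lon0, _ = self.bbox
            self._cache[key] = {
                m: RasterGrid(lat0, lon0, self.cell_m, row[m] + self._anom, name=m)
                for m in ("tmax", "tmean", "tmin")
            }
            if len(self._cache) > 64:  # bound memory
                self._cache.pop(next(iter(self._cache)))
        return self._cache[key]


def generate_ndvi_grids(
    bbox=DEFAULT_BBOX, cell_m: float = 30.0, seed: int = 0,
    mean: float = 0.19, spatial_sd: float = 0.07,
) -> dict[str, RasterGrid]:
    """Three seasonal NDVI rasters (cold_dry, warm_dry, rainy) with a
    smooth low-frequency greenness field around the configured mean."""
    rng = np.random.default_rng(seed)
    lat0, lat1, lon0, lon1 = bbox
    x1, y1 = local_xy(lat1, lon1, lat0, lon0)
    nrow = int(np.ceil(y1 / cell_m))
    ncol = int(np.ceil(x1 / cell_m))
    cx = (np.arange(ncol) + 0.5) / (x1 / cell_m) * 2 * np.pi
    cy = (np.arange(nrow) + 0.5) / (y1 / cell_m) * 2 * np.pi
    phases = rng.uniform(0, 2 * np.pi, 6)
    field = (
        np.sin(1.0 * cy[:, None] + phases[0]) * np.cos(1.0 * cx[None, :] + phases[1])
        + 0.6 * np.sin(2.0 * cy[:, None] + phases[2]) * np.sin(1.5 * cx[None, :] + phases[3])
        + 0.4 * np.cos(2.5 * cy[:, None] + phases[4]) * np.cos(2.2 * cx[None, :] + phases[5])
    )
    field = field / field.std() * spatial_sd if spatial_sd > 0 else np.zeros_like(field)
    offsets = {"cold_dry": -0.02, "warm_dry": -0.04, "rainy": 0.05}
    return {
        season: RasterGrid(
            lat0, lon0, cell_m, np.clip(mean + off + field, -1.0, 1.0), name=f"ndvi_{season}"
        )
        for season, off in offsets.items()
    }


# ---------------------------------------------------------------------------
# Calendar, wear periods, sleep
# ---------------------------------------------------------------------------

def generate_school_calendar(years=(2013, 2014, 2015)) -> pd.DataFrame:
    """Deterministic school calendar: weekdays are school days except the
    summer break (Jul 8 – Aug 23), winter break (Dec 20 – Jan 6) and a
    two-week spring break around Easter (first half of April)."""
    frames = []
    for year in years:
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        is_school = dates.dayofweek < 5
        holiday = (
            ((dates >= f"{year}-07-08") & (dates <= f"{year}-08-23"))
            | (dates >= f"{year}-12-20")
            | (dates <= f"{year}-01-06")
            | ((dates >= f"{year}-04-01") & (dates <= f"{year}-04-14"))
        )
        frames.append(pd.DataFrame({"date": dates, "is_school_day": is_school & ~holiday}))
    return pd.concat(frames, ignore_index=True)


#: Relative person-day sampling weight per calendar month (uneven
#: collection with a November–January trough, as in the field campaign).
MONTH_WEIGHTS = np.array([200, 260, 300, 349, 330, 300, 320, 310, 300, 280, 190, 157], float)


def sample_wear_dates(
    cohort: pd.DataFrame,
    seed: int = 0,
    n_days: int = 7,
    period=STUDY_PERIOD,
    uneven_months: bool = True,
) -> pd.DataFrame:
    """One contiguous wear window per child; start months follow the
    campaign's uneven seasonal distribution unless ``uneven_months`` is
    off. Returns (child_id, date) pairs."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(period[0])
    end = pd.Timestamp(period[1]) - pd.Timedelta(days=n_days)
    all_days = pd.date_range(start, end, freq="D")
    if uneven_months:
        w = MONTH_WEIGHTS[all_days.month - 1]
        w = w / w.sum()
    else:
        w = np.full(len(all_days), 1.0 / len(all_days))
    starts = rng.choice(len(all_days), size=len(cohort), p=w)
    rows = []
    for cid, s in zip(cohort["child_id"], starts):
        for d in range(n_days):
            rows.append((cid, all_days[s] + pd.Timedelta(days=d)))
    return pd.DataFrame(rows, columns=["child_id", "date"])


def generate_sleep_intervals(
    child_id: str, dates, config: SleepConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Night sleep (crossing midnight into each date) plus optional naps.

    The night interval attributed to date d starts on the evening of d-1;
    per-day totals follow the configured distribution (default mean 470
    minutes)."""
    cfg = config or SleepConfig()
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    rows = []
    for d in dates:
        bed_offset = rng.normal(0.0, cfg.bed_jitter_min)
        bed = d - pd.Timedelta(days=1) + pd.Timedelta(
            minutes=round(cfg.bed_hour * 60 + bed_offset)
        )
        night = float(np.clip(rng.normal(cfg.night_mean, cfg.night_sd),
                              cfg.night_mean - 3 * cfg.night_sd,
                              cfg.night_mean + 3 * cfg.night_sd))
        rows.append((child_id, bed, bed + pd.Timedelta(minutes=round(night)), "night"))
        if rng.random() < cfg.nap_prob:
            nap_start = d + pd.Timedelta(
                minutes=round(cfg.nap_hour * 60 + rng.normal(0, 30))
            )
            nap = float(np.clip(rng.normal(cfg.nap_mean, cfg.nap_sd), 10.0, 150.0))
            rows.append((child_id, nap_start, nap_start + pd.Timedelta(minutes=round(nap)), "nap"))
    return pd.DataFrame(rows, columns=["child_id", "start", "end", "kind"])


def daily_sleep_minutes(intervals: pd.DataFrame, dates) -> pd.Series:
    """Sleep minutes attributed per date: night intervals to their end
    date, naps to their start date."""
    dates = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    out = pd.Series(0.0, index=dates)
    for _, row in intervals.iterrows():
        minutes = (pd.Timestamp(row["end"]) - pd.Timestamp(row["start"])).total_seconds() / 60
        day = pd.Timestamp(row["end" if row["kind"] == "night" else "start"]).normalize()
        if day in out.index:
            out[day] += minutes
    return out


# ---------------------------------------------------------------------------
# Exposure assembly (fast synthetic path)
# ---------------------------------------------------------------------------

def daylight_hours_vec(dates, lat) -> np.ndarray:
    """Vectorised NOAA daylength (hours) for paired dates/latitudes."""
    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    doy = dates.dayofyear.to_numpy(float)
    year_len = np.where(dates.is_leap_year, 366.0, 365.0)
    g = 2.0 * np.pi / year_len * (doy - 1)
    decl = (
        0.006918
        - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
    )
    phi = np.deg2rad(np.asarray(lat, float))
    cos_ha = np.cos(np.deg2rad(90.833)) / (np.cos(phi) * np.cos(decl)) - np.tan(
        phi
    ) * np.tan(decl)
    return 2.0 * np.rad2deg(np.arccos(np.clip(cos_ha, -1, 1))) / 15.0


def build_synthetic_exposures(
    cohort: pd.DataFrame,
    child_dates: pd.DataFrame,
    weather: pd.DataFrame,
    ndvi_grids: dict[str, RasterGrid] | None = None,
    ndvi_buffer: str = "250m",
    calendar: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorised exposure rows for synthetic studies.

    Temperatures are the city series plus the home's spatial anomaly
    (identical to what the 1-km grid source returns at the home cell, up
    to within-cell position); NDVI is looked up in the seasonal grids
    when provided, else a constant placeholder is used.
    """
    from .exposures import ndvi_buffer_mean, season_for_date

    df = child_dates.merge(weather, on="date", how="inner").merge(
        cohort[["child_id", "home_lat", "home_lon"]], on="child_id", how="left"
    )
    anom = _spatial_anomaly(df["home_lat"].to_numpy(), df["home_lon"].to_numpy())
    for m in ("tmax", "tmean", "tmin"):
        df[m] = df[m] + anom
    df["diurnal"] = df["tmax"] - df["tmin"]
    df["daylight_hours"] = daylight_hours_vec(df["date"], df["home_lat"])
    df["day_of_year"] = pd.DatetimeIndex(df["date"]).dayofyear.astype(float)
    if ndvi_grids is not None:
        cache: dict[tuple[str, str], float] = {}
        vals = np.empty(len(df))
        seasons = [season_for_date(d) for d in df["date"]]
        for i, (cid, season, lat, lon) in enumerate(
            zip(df["child_id"], seasons, df["home_lat"], df["home_lon"])
        ):
            key = (cid, season)
            if key not in cache:
                cache[key] = ndvi_buffer_mean(ndvi_grids[season], lat, lon, ndvi_buffer)
            vals[i] = cache[key]
        df["ndvi"] = vals
    else:
        # no rasters: deterministic greenness field at the home, with the
        # seasonal offsets the raster generator would apply
        season_off = {"cold_dry": -0.02, "warm_dry": -0.04, "rainy": 0.05}
        off = np.array([season_off[season_for_date(d)] for d in df["date"]])
        lat0 = (DEFAULT_BBOX[0] + DEFAULT_BBOX[1]) / 2
        lon0 = (DEFAULT_BBOX[2] + DEFAULT_BBOX[3]) / 2
        lat_h = df["home_lat"].to_numpy()
        lon_h = df["home_lon"].to_numpy()
        # odd in latitude about the box centre: zero mean over the cohort,
        # near-orthogonal to the (odd-in-longitude) temperature anomaly
        field = np.sin(2 * np.pi * (lat_h - lat0) / 0.5) * np.cos(
            2 * np.pi * (lon_h - lon0) / 0.6
        )
        df["ndvi"] = np.clip(
            DEFAULT_COVARIATE_MEANS["ndvi"] + off + 0.07 * field, -1.0, 1.0
        )
    if calendar is None:
        calendar = generate_school_calendar(
            tuple(sorted(pd.DatetimeIndex(df["date"]).year.unique()))
        )
    cal = calendar.set_index(pd.to_datetime(calendar["date"]).dt.normalize())[
        "is_school_day"
    ]
    is_school = pd.DatetimeIndex(df["date"]).normalize().map(cal).fillna(False)
    weekday = pd.DatetimeIndex(df["date"]).dayofweek < 5
    df["day_type"] = np.where(
        weekday & is_school.to_numpy(bool), "school_day", "holiday_or_weekend"
    )
    return df


# ---------------------------------------------------------------------------
# Outcome generation
# ---------------------------------------------------------------------------

def generate_daily_direct(
    cohort: pd.DataFrame,
    truth: PlantedTruth,
    exposures: pd.DataFrame,
    seed: int = 0,
    sleep_config: SleepConfig | None = None,
    mean_awake_minutes: float = 846.4,
    awake_sd_minutes: float = 90.0,
) -> pd.DataFrame:
    """Day-level outcomes drawn directly from the planted model.

    Returns the merged modelling frame: cohort covariates, exposure row,
    daily sleep minutes (drawn N(470, 72) unless a sleep config says
    otherwise), awake/sedentary minutes and pct_sedentary in [0, 100].
    Same seed, same output, bit for bit.
    """
    rng = np.random.default_rng(seed)
    frame = exposures.merge(cohort, on="child_id", how="left", suffixes=("", "_cohort"))
    scfg = sleep_config or SleepConfig()
    sleep_mean = scfg.night_mean + scfg.nap_prob * scfg.nap_mean
    frame["sleep_minutes"] = rng.normal(sleep_mean, 72.0, len(frame))
    children = pd.unique(frame["child_id"])
    u = pd.Series(rng.normal(0.0, truth.sigma_u, len(children)), index=children)
    eta = truth.linear_predictor(frame)
    y = eta + u[frame["child_id"]].to_numpy() + rng.normal(0.0, truth.sigma_e, len(frame))
    frame["pct_sedentary"] = np.clip(y, 0.0, 100.0)
    frame["awake_minutes"] = np.clip(
        rng.normal(mean_awake_minutes, awake_sd_minutes, len(frame)), 600.0, 1100.0
    )
    frame["sedentary_minutes"] = frame["pct_sedentary"] / 100.0 * frame["awake_minutes"]
    return frame


def _markov_occupancy_path(rng, n_epochs: int, pi: float, tau: float) -> np.ndarray:
    """Two-state chain (True = sedentary) with stationary occupancy pi and
    mean regime-exit scale tau epochs, simulated by alternating geometric
    dwell times."""
    p_exit_sed = min(max((1 - pi) / tau, 1e-6), 1.0)
    p_exit_act = min(max(pi / tau, 1e-6), 1.0)
    state = bool(rng.random() < pi)
    out = np.empty(n_epochs, dtype=bool)
    pos = 0
    while pos < n_epochs:
        dwell = rng.geometric(p_exit_sed if state else p_exit_act)
        out[pos : pos + dwell] = state
        pos += dwell
        state = not state
    return out


def generate_epoch_stream(
    child: pd.Series,
    truth: PlantedTruth,
    exposures: pd.DataFrame,
    sleep: pd.DataFrame,
    config: EpochSimConfig | None = None,
    seed: int = 0,
    u: float | None = None,
) -> tuple[EpochStream, pd.DataFrame]:
    """Full 10-s count stream for one child across their wear dates.

    Awake epochs follow the two-state Markov chain whose stationary
    sedentary occupancy on each day equals the planted linear predictor
    (plus the child intercept and day noise), clipped to [1, 99]%;
    sedentary epochs draw x-counts uniformly on [0, 356] and active on
    [357, active_count_max], so the cut-point boundary is exercised.
    Sleep epochs draw low counts; optional non-wear runs overwrite all
    axes with zeros. Returns the stream and the per-day planted occupancy
    table used by recovery tests.
    """
    cfg = config or EpochSimConfig()
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(pd.to_datetime(exposures["date"])).normalize()
    frame = exposures.copy()
    for col in ("sex", "maternal_edu", "bmi_z", "age"):
        if col not in frame.columns and col in child.index:
            frame[col] = child[col]
    if "sleep_minutes" not in frame.columns:
        frame["sleep_minutes"] = daily_sleep_minutes(sleep, dates).to_numpy()
    eta = truth.linear_predictor(frame)
    if u is None:
        u = float(rng.normal(0.0, truth.sigma_u))
    day_noise = rng.normal(0.0, truth.sigma_e, len(frame))
    raw = eta + u + day_noise
    lo, hi = cfg.occupancy_clip
    if ((raw <= 0) | (raw >= 100)).any():
        logger.warning(
            "child %s: %d day(s) with linear predictor outside (0, 100); clipping",
            child.get("child_id", "?"),
            int(((raw <= 0) | (raw >= 100)).sum()),
        )
    occupancy = np.clip(raw, lo, hi)

    epd = 24 * 3600 // EPOCH_SECONDS  # epochs per day
    n = epd * len(dates)
    x = np.empty(n, dtype=np.int64)
    sedentary_path = np.empty(n, dtype=bool)
    for d, occ in enumerate(occupancy):
        sl = slice(d * epd, (d + 1) * epd)
        sedentary_path[sl] = _markov_occupancy_path(rng, epd, occ / 100.0, cfg.mixing_epochs)
    n_sed = int(sedentary_path.sum())
    x[sedentary_path] = rng.integers(0, CUTPOINT + 1, n_sed)
    x[~sedentary_path] = rng.integers(CUTPOINT + 1, cfg.active_count_max + 1, n - n_sed)
    y_counts = (x * rng.uniform(0.6, 1.0, n)).astype(np.int64)
    z_counts = (x * rng.uniform(0.4, 0.9, n)).astype(np.int64)

    timestamps = pd.date_range(
        dates[0], periods=n, freq=f"{EPOCH_SECONDS}s"
    )
    # sleep epochs: low but mostly non-zero counts
    sleep_mask = np.zeros(n, dtype=bool)
    ts = timestamps.to_numpy()
    for _, row in sleep.iterrows():
        sleep_mask |= (ts >= pd.Timestamp(row["start"]).to_numpy()) & (
            ts < pd.Timestamp(row["end"]).to_numpy()
        )
    n_sleep = int(sleep_mask.sum())
    x[sleep_mask] = rng.integers(0, cfg.sleep_count_max + 1, n_sleep)
    y_counts[sleep_mask] = rng.integers(0, cfg.sleep_count_max + 1, n_sleep)
    z_counts[sleep_mask] = rng.integers(0, cfg.sleep_count_max + 1, n_sleep)
    # inserted non-wear: zero counts on all axes
    n_runs = rng.poisson(cfg.nonwear_runs_per_day * len(dates))
    for _ in range(n_runs):
        run_min = rng.uniform(cfg.nonwear_min_minutes, cfg.nonwear_max_minutes)
        run_epochs = int(round(run_min * 60 / EPOCH_SECONDS))
        start = int(rng.integers(0, max(n - run_epochs, 1)))
        x[start : start + run_epochs] = 0
        y_counts[start : start + run_epochs] = 0
        z_counts[start : start + run_epochs] = 0

    records = pd.DataFrame(
        {"timestamp": timestamps, "x": x, "y": y_counts, "z": z_counts}
    )
    stream = EpochStream(str(child["child_id"]), records)
    planted = pd.DataFrame(
        {
            "child_id": str(child["child_id"]),
            "date": dates,
            "occupancy_pct": occupancy,
            "u": u,
        }
    )
    return stream, planted


# ---------------------------------------------------------------------------
# One-call study dataset
# ---------------------------------------------------------------------------

def generate_daily_dataset(
    n_children: int = 559,
    n_days: int = 6,
    seed: int = 0,
    truth: PlantedTruth | None = None,
    cohort_config: CohortConfig | None = None,
    weather_config: WeatherConfig | None = None,
    ndvi_grids: dict[str, RasterGrid] | None = None,
    uneven_months: bool = True,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Cohort + wear windows + weather + exposures + direct outcomes in
    one deterministic call; the workhorse for calibration checks and
    parameter-recovery simulations."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_dates, s_weather, s_outcome = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    truth = truth or PlantedTruth.calibrated()
    cohort = generate_cohort(n_children, cohort_config, seed=s_cohort)
    child_dates = sample_wear_dates(
        cohort, seed=s_dates, n_days=n_days, uneven_months=uneven_months
    )
    weather = generate_weather(
        pd.date_range(*STUDY_PERIOD, freq="D"), weather_config, seed=s_weather
    )
    exposures = build_synthetic_exposures(cohort, child_dates, weather, ndvi_grids)
    data = generate_daily_direct(cohort, truth, exposures, seed=s_outcome)
    return data, truth
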