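"""End-to-end study orchestration.

``run_study`` assembles (or simulates) the full analysis: cohort and
exposure construction, accelerometry processing, the four temperature
models (maximum, mean, minimum, diurnal variation), univariable fits, the
smooth-vs-linear hypothesis test, and a one-at-a-time sensitivity grid
over the processing decisions (non-wear signal and run length, NDVI
buffer, temperature source, inclusion criteria). Every run writes a
machine-readable manifest (config, seed, library versions) and is
byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import accelerometry as acc
from . import exposures as expo
from . import synthetic as syn
from .gamm import (
    AdditiveMixedModel,
    GAMMResults,
    TEMPERATURE_METRICS,
    compare_smooth_vs_linear,
    fit_univariable,
    minutes_equivalent,
    sedentary_model_spec,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "run_sensitivity_grid", "StudyArtifacts"]

NONWEAR_VARIANTS = [("x_axis", 20), ("x_axis", 30), ("vector_magnitude", 20), ("vector_magnitude", 30)]


@dataclasses.dataclass
class RunConfig:
    """Configuration for one synthetic study run.

    The reference configuration mirrors the main analysis: x-axis
    non-wear signal, 20-minute runs, 250-m NDVI buffer, gridded
    temperature, default validity profile (>= 600 min, >= 3 weekdays +
    >= 1 weekend day).
    """

    n_children: int = 559
    n_days: int = 7
    seed: int = 11
    outcome_mode: Literal["direct", "epochs"] = "direct"
    signal: Literal["x_axis", "vector_magnitude"] = "x_axis"
    min_run_minutes: int = 20
    validity_profile: Literal["default", "strict"] = "default"
    ndvi_buffer: Literal["pixel", "250m", "500m"] = "250m"
    ndvi_cell_m: float = 30.0
    temperature_source: Literal["grid", "nearest_station"] = "grid"
    criterion: Literal["reml", "gcv"] = "reml"
    k_day: int = 10
    k_spatial: int = 30
    uneven_months: bool = True
    sensitivity: bool = True
    out_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class StudyArtifacts:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    data: pd.DataFrame
    summary: pd.DataFrame
    fits: dict[str, GAMMResults]
    univariable: pd.DataFrame
    smooth_vs_linear: pd.DataFrame
    sensitivity: pd.DataFrame | None
    out_dir: Path


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

def _idw_precip_at_homes(cohort, station_sites, station_precip_wide, power=2.0):
    """Vectorised IDW: child x date precipitation from station series."""
    sx, sy = expo.local_xy(
        station_sites["lat"].to_numpy(), station_sites["lon"].to_numpy(),
        cohort["home_lat"].mean(), cohort["home_lon"].mean(),
    )
    hx, hy = expo.local_xy(
        cohort["home_lat"].to_numpy(), cohort["home_lon"].to_numpy(),
        cohort["home_lat"].mean(), cohort["home_lon"].mean(),
    )
    d = np.hypot(hx[:, None] - sx[None, :], hy[:, None] - sy[None, :])
    d = np.maximum(d, 1.0)
    w = d ** (-power)
    w = w / w.sum(axis=1, keepdims=True)  # (children, stations)
    vals = station_precip_wide.to_numpy()  # (dates, stations)
    out = pd.DataFrame(
        vals @ w.T, index=station_precip_wide.index, columns=cohort["child_id"]
    )
    return out  # date x child


def _build_study_frame(cfg: RunConfig):
    """Cohort, exposures (all sensitivity codings) and outcomes."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    s_cohort, s_dates, s_weather, s_ndvi, s_station, s_sleep, s_outcome, s_epoch = seeds

    cohort = syn.generate_cohort(cfg.n_children, seed=s_cohort)
    child_dates = syn.sample_wear_dates(
        cohort, seed=s_dates, n_days=cfg.n_days, uneven_months=cfg.uneven_months
    )
    weather = syn.generate_weather(
        pd.date_range(*syn.STUDY_PERIOD, freq="D"), seed=s_weather
    )
    calendar = syn.generate_school_calendar((2013, 2014, 2015))
    ndvi_grids = syn.generate_ndvi_grids(cell_m=cfg.ndvi_cell_m, seed=s_ndvi)
    stations = syn.generate_stations(seed=s_station)
    station_weather = syn.generate_station_weather(stations, weather)

    frame = syn.build_synthetic_exposures(
        cohort, child_dates, weather, ndvi_grids=None, calendar=calendar
    )
    # NDVI under all three buffer codings
    for buffer in ("pixel", "250m", "500m"):
        cache: dict[tuple[str, str], float] = {}
        vals = np.empty(len(frame))
        seasons = [expo.season_for_date(d) for d in frame["date"]]
        for i, (cid, season, lat, lon) in enumerate(
            zip(frame["child_id"], seasons, frame["home_lat"], frame["home_lon"])
        ):
            key = (cid, season)
            if key not in cache:
                cache[key] = expo.ndvi_buffer_mean(ndvi_grids[season], lat, lon, buffer)
            vals[i] = cache[key]
        frame[f"ndvi_{buffer}"] = vals
    frame["ndvi"] = frame[f"ndvi_{cfg.ndvi_buffer}"]
    # nearest-station temperature coding
    nearest = {
        cid: expo.nearest_station(stations, lat, lon)
        for cid, lat, lon in zip(cohort["child_id"], cohort["home_lat"], cohort["home_lon"])
    }
    st = station_weather[["station_id", "date", "tmax", "tmean", "tmin", "diurnal"]]
    frame["_station"] = frame["child_id"].map(nearest)
    frame = frame.merge(
        st.rename(
            columns={m: f"{m}_station" for m in ("tmax", "tmean", "tmin", "diurnal")}
        ),
        left_on=["_station", "date"],
        right_on=["station_id", "date"],
        how="left",
    ).drop(columns=["station_id", "_station"])
    # IDW precipitation from station network
    precip_wide = station_weather.pivot(index="date", columns="station_id", values="precip_mm")
    idw = _idw_precip_at_homes(cohort, stations, precip_wide)
    frame["precip_mm"] = [
        idw.at[d, c] for d, c in zip(frame["date"], frame["child_id"])
    ]
    if cfg.temperature_source == "nearest_station":
        for m in TEMPERATURE_METRICS:
            frame[m] = frame[f"{m}_station"]

    truth = syn.PlantedTruth.calibrated()
    if cfg.outcome_mode == "direct":
        data = syn.generate_daily_direct(cohort, truth, frame, seed=s_outcome)
        data["weekday_flag"] = pd.DatetimeIndex(data["date"]).dayofweek < 5
        day_tables = {v: data for v in NONWEAR_VARIANTS}
    else:
        data, day_tables = _epoch_outcomes(cfg, cohort, frame, truth, s_sleep, s_epoch)
    return cohort, frame, truth, data, day_tables


def _epoch_outcomes(cfg, cohort, frame, truth, s_sleep, s_epoch):
    """Full epoch simulation and processing, all four non-wear variants."""
    per_variant: dict[tuple, list] = {v: [] for v in NONWEAR_VARIANTS}
    ss_sleep = np.random.SeedSequence(s_sleep).spawn(len(cohort))
    ss_ep = np.random.SeedSequence(s_epoch).spawn(len(cohort))
    for i, (_, child) in enumerate(cohort.iterrows()):
        sub = frame[frame["child_id"] == child["child_id"]].sort_values("date")
        if sub.empty:
            continue
        sleep = syn.generate_sleep_intervals(
            child["child_id"], sub["date"], seed=int(ss_sleep[i].generate_state(1)[0] % 2**31)
        )
        stream, _ = syn.generate_epoch_stream(
            child, truth, sub, sleep, seed=int(ss_ep[i].generate_state(1)[0] % 2**31)
        )
        sleep_by_day = syn.daily_sleep_minutes(sleep, sub["date"])
        for variant in NONWEAR_VARIANTS:
            days = acc.process_stream(
                stream, sleep, signal=variant[0], min_run_minutes=variant[1]
            )
            days["sleep_minutes"] = days["date"].map(sleep_by_day)
            per_variant[variant].append(days)
    day_tables = {}
    for variant, chunks in per_variant.items():
        days = pd.concat(chunks, ignore_index=True)
        days = acc.filter_valid(days, profile=cfg.validity_profile)
        merged = days.drop(columns=["valid_flag"]).merge(
            frame, on=["child_id", "date"], how="inner"
        ).merge(cohort, on="child_id", how="left", suffixes=("", "_cohort"))
        day_tables[variant] = merged
    data = day_tables[(cfg.signal, cfg.min_run_minutes)]
    return data, day_tables


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _summary_table(data: pd.DataFrame) -> pd.DataFrame:
    cont = [
        ("Daily Sedentary Time (%)", "pct_sedentary"),
        ("Daily Maximum Temperature (C)", "tmax"),
        ("Daily Mean Temperature (C)", "tmean"),
        ("Daily Minimum Temperature (C)", "tmin"),
        ("Daily Diurnal Variation (C)", "diurnal"),
        ("Mean NDVI", "ndvi"),
        ("Daily Daylight (hours)", "daylight_hours"),
        ("Daily Total Precipitation (mm)", "precip_mm"),
        ("Age (years)", "age"),
        ("BMI Z-Score", "bmi_z"),
        ("Daily Sleep (minutes)", "sleep_minutes"),
    ]
    rows = [
        {"variable": label, "mean": data[col].mean(), "sd": data[col].std(), "n": len(data)}
        for label, col in cont
        if col in data
    ]
    per_child = data.drop_duplicates("child_id")
    for col, label in (("sex", "Sex"), ("maternal_edu", "Maternal Education")):
        for level, count in per_child[col].value_counts().items():
            rows.append(
                {
                    "variable": f"{label}: {level}",
                    "mean": count,
                    "sd": 100.0 * count / len(per_child),
                    "n": len(per_child),
                }
            )
    for level, count in data["day_type"].value_counts().items():
        rows.append(
            {
                "variable": f"Type of Day: {level}",
                "mean": count,
                "sd": 100.0 * count / len(data),
                "n": len(data),
            }
        )
    return pd.DataFrame(rows)


def _fit_to_dict(res: GAMMResults) -> dict:
    ci = res.conf_int()
    return {
        "params": res.params.to_dict(),
        "se": res.bse.to_dict(),
        "ci_lower": ci["lower"].to_dict(),
        "ci_upper": ci["upper"].to_dict(),
        "p": res.pvalues.to_dict(),
        "edf_by_term": res.edf_by_term,
        "lambdas": res.lambdas,
        "sigma_u": res.sigma_u,
        "scale": res.scale,
        "aic": res.aic,
        "reml": res.reml,
        "rsquared_adj": res.rsquared_adj,
        "n": int(res.model.nobs),
    }


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_study(cfg: RunConfig) -> StudyArtifacts:
    """Run the full study and write its artifact directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, frame, truth, data, day_tables = _build_study_frame(cfg)
    logger.info("study frame: %d child-days, %d children", len(data), data["child_id"].nunique())

    summary = _summary_table(data)
    _write_csv(summary, out / "cohort_summary.csv")

    fits: dict[str, GAMMResults] = {}
    mean_awake = float(data["awake_minutes"].mean()) if "awake_minutes" in data else float("nan")
    for metric in TEMPERATURE_METRICS:
        spec = sedentary_model_spec(metric, k_day=cfg.k_day, k_spatial=cfg.k_spatial)
        res = AdditiveMixedModel(data, spec).fit(criterion=cfg.criterion)
        fits[metric] = res
        _write_csv(
            res.to_frame().reset_index(names="term"), out / f"model_{metric}_coefficients.csv"
        )
        (out / f"model_{metric}_summary.txt").write_text(
            res.summary()
            + f"\n\nminutes-equivalent of the {metric} coefficient: "
            f"{minutes_equivalent(res.linear_coef(metric), mean_awake):+.2f}"
            " min per unit (at the cohort mean awake time)\n"
        )
        with open(out / f"model_{metric}_fit.json", "w") as fh:
            json.dump(_fit_to_dict(res), fh, indent=1, sort_keys=True)

    uni_rows = []
    for cov in [*TEMPERATURE_METRICS, "ndvi", "daylight_hours", "precip_mm",
                "sleep_minutes", "age", "bmi_z"]:
        lin = fit_univariable(data, cov, criterion=cfg.criterion)
        smo = fit_univariable(data, cov, smooth=True, criterion=cfg.criterion)
        ci = lin.conf_int().loc[cov]
        uni_rows.append(
            {
                "covariate": cov,
                "estimate": lin.linear_coef(cov),
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "p": lin.pvalues[cov],
                "edf_smooth": smo.edf_by_term[f"s({cov})"],
                "aic_linear": lin.aic,
                "aic_smooth": smo.aic,
            }
        )
    univariable = pd.DataFrame(uni_rows)
    _write_csv(univariable, out / "univariable.csv")

    svl_rows = []
    for metric in TEMPERATURE_METRICS:
        spec = sedentary_model_spec(metric, k_day=cfg.k_day, k_spatial=cfg.k_spatial)
        c = compare_smooth_vs_linear(data, spec, metric, criterion=cfg.criterion)
        svl_rows.append(
            {
                "metric": metric,
                "aic_smooth": c["aic_smooth"],
                "aic_linear": c["aic_linear"],
                "edf_smooth": c["edf_smooth"],
                "preferred": c["preferred"],
            }
        )
    smooth_vs_linear = pd.DataFrame(svl_rows)
    _write_csv(smooth_vs_linear, out / "smooth_vs_linear.csv")

    sensitivity = None
    if cfg.sensitivity:
        sensitivity = run_sensitivity_grid(cfg, data, day_tables, fits)
        _write_csv(sensitivity, out / "sensitivity.csv")

    month_hist = (
        pd.DatetimeIndex(data["date"]).month.value_counts().sort_index().rename("person_days")
    )
    month_hist.rename_axis("month").reset_index().to_csv(
        out / "person_days_by_month.csv", index=False
    )

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "package_version": _pkg_version,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_child_days": int(len(data)),
        "n_children": int(data["child_id"].nunique()),
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in cfg.to_dict().items() if k != "out_dir"},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return StudyArtifacts(cfg, data, summary, fits, univariable, smooth_vs_linear,
                          sensitivity, out)


# ---------------------------------------------------------------------------
# sensitivity grid
# ---------------------------------------------------------------------------

def _temperature_row(name, metric, res: GAMMResults, ref: GAMMResults | None):
    coef = res.linear_coef(metric)
    se = float(res.bse[metric])
    p = float(res.pvalues[metric])
    row = {
        "variant": name,
        "metric": metric,
        "estimate": coef,
        "se": se,
        "p": p,
        "reject_null": p < 0.05,
    }
    if ref is not None:
        row["delta_estimate"] = coef - ref.linear_coef(metric)
        row["delta_se"] = se - float(ref.bse[metric])
        row["concordant_rejection"] = (p < 0.05) == (float(ref.pvalues[metric]) < 0.05)
    return row


def run_sensitivity_grid(
    cfg: RunConfig,
    data: pd.DataFrame,
    day_tables: dict,
    reference_fits: dict[str, GAMMResults],
) -> pd.DataFrame:
    """One-at-a-time sensitivity variants against the reference run.

    Axes: the four non-wear (signal, run-length) combinations, the three
    NDVI buffers, strict inclusion criteria, and nearest-station
    temperature. Variant failures are recorded and do not stop the grid.
    """
    rows = []
    for metric, ref in reference_fits.items():
        rows.append(_temperature_row("reference", metric, ref, ref))

    def fit_variant(name, vdata, metric_cols=None, ndvi_col="ndvi"):
        for metric in TEMPERATURE_METRICS:
            try:
                mcol = (metric_cols or {}).get(metric, metric)
                vframe = vdata
                if mcol != metric:
                    vframe = vdata.drop(columns=[metric]).rename(columns={mcol: metric})
                spec = sedentary_model_spec(
                    metric, ndvi_col=ndvi_col, k_day=cfg.k_day, k_spatial=cfg.k_spatial
                )
                res = AdditiveMixedModel(vframe, spec).fit(criterion=cfg.criterion)
                rows.append(_temperature_row(name, metric, res, reference_fits[metric]))
            except Exception as exc:  # noqa: BLE001 - grid must continue
                logger.warning("sensitivity variant %s/%s failed: %s", name, metric, exc)
                rows.append(
                    {"variant": name, "metric": metric, "error": str(exc)}
                )

    for variant in NONWEAR_VARIANTS:
        if variant == (cfg.signal, cfg.min_run_minutes):
            continue
        fit_variant(f"nonwear_{variant[0]}_{variant[1]}min", day_tables[variant])
    for buffer in ("pixel", "250m", "500m"):
        if buffer == cfg.ndvi_buffer:
            continue
        fit_variant(f"ndvi_{buffer}", data, ndvi_col=f"ndvi_{buffer}")
    alt_profile = "strict" if cfg.validity_profile == "default" else "default"
    strict = acc.filter_valid(
        data.assign(valid_flag=True), profile=alt_profile
    ) if "awake_minutes" in data else None
    if strict is not None and len(strict):
        fit_variant(f"inclusion_{alt_profile}", strict)
    if cfg.temperature_source == "grid" and "tmax_station" in data:
        fit_variant(
            "temperature_nearest_station",
            data,
            metric_cols={m: f"{m}_station" for m in TEMPERATURE_METRICS},
        )
    return pd.DataFrame(rows)
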