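"""End-to-end orchestration: simulate -> micromet -> flux -> partition -> analyze.

Every stage reads and writes plain CSV (UTF-8, comma-separated, ISO-8601
timestamps, "." decimal) under one output directory, so stages can also be
run independently on externally produced files that follow the same
schemas.  A machine-readable run report (stage statuses, record counts,
collected warnings — no wall-clock times, so reruns are byte-identical)
is written as ``run_report.json``.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chamber_flux, dendro, micromet, stats
from .exceptions import MissingInputError, StemfluxError, ValidationError
from .synthetic import ScenarioConfig, generate_campaign_dataset

__all__ = ["RunConfig", "run_pipeline", "run_analysis", "fluxes_from_bundle"]

log = logging.getLogger("stemflux")

STAGES = ("simulate", "micromet", "flux", "partition", "analyze")


@dataclass
class RunConfig:
    """Parameters forwarded to each pipeline stage.

    ``input_dir`` holds the raw inputs (written there by the simulate stage,
    or supplied externally); derived tables land in ``out_dir``.
    """

    out_dir: str = "stemflux_out"
    input_dir: str | None = None      # default: <out_dir>/inputs
    seed: int = 0
    stages: tuple = STAGES
    # micromet
    vpd_units: str = "hpa"
    swc_match_tolerance_minutes: float = 30.0
    # chamber flux
    q10: float = 2.0
    t_ref: float = 15.0
    literal_exponent: bool = False
    deadband_s: float = 0.0
    r2_threshold: float = 0.9
    # dendrometer
    ma_window_days: int = 7
    ma_min_periods: int = 4
    ma_center: bool = True
    gap_hours: float = 6.0
    # analysis
    reference_year: int = 2016
    drought_year: int = 2017
    # scenario overrides for the simulate stage (ScenarioConfig field names)
    scenario: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved_input_dir(self) -> Path:
        return Path(self.input_dir) if self.input_dir else Path(self.out_dir) / "inputs"


def _record(report, stage, status, n_records=0, warnings_list=(), error=None):
    report["stages"][stage] = {
        "status": status,
        "n_records": int(n_records),
        "warnings": list(warnings_list),
        **({"error": error} if error else {}),
    }


def _stage_simulate(cfg: RunConfig):
    scenario = ScenarioConfig(seed=cfg.seed, **cfg.scenario)
    bundle = generate_campaign_dataset(scenario, out_dir=cfg.resolved_input_dir())
    n = sum(len(m) for m in bundle.manifests.values())
    log.info("simulate: %d campaign measurements, %d dendrometer series",
             n, len(bundle.dendro))
    return n


def _stage_micromet(cfg: RunConfig, out: Path):
    inp = cfg.resolved_input_dir()
    files = sorted(glob.glob(str(inp / "micromet_*.csv")))
    if not files:
        raise MissingInputError(f"no micromet_*.csv under {inp}")
    n, warns = 0, []
    for path in files:
        df = pd.read_csv(path, parse_dates=["timestamp"])
        calibration = None
        if "swc_shallow_pct" in df.columns and df["swc_pct"].isna().any():
            both = df.dropna(subset=["swc_pct", "swc_shallow_pct"])
            if len(both) >= 2:
                calibration = micromet.fit_swc_calibration(
                    both["swc_shallow_pct"], both["swc_pct"], treatment_id="site"
                )
                log.info("micromet: SWC calibration slope=%.3f intercept=%.3f R2=%.3f (n=%d)",
                         calibration.slope, calibration.intercept,
                         calibration.r_squared, calibration.n_points)
            else:
                warns.append(f"{Path(path).name}: SWC gap but <2 calibration pairs")
        derived = micromet.derive_micromet(
            df, vpd_units=cfg.vpd_units, calibration=calibration
        )
        year = re.search(r"micromet_(\w+)\.csv$", path).group(1)
        derived.to_csv(out / f"micromet_{year}_derived.csv", index=False)
        n += len(derived)
    return n, warns


def _stage_flux(cfg: RunConfig, out: Path):
    inp = cfg.resolved_input_dir()
    files = sorted(glob.glob(str(inp / "manifest_*.csv")))
    if not files:
        raise MissingInputError(f"no manifest_*.csv under {inp}")
    frames = []
    for path in files:
        manifest = pd.read_csv(path)
        fluxes = chamber_flux.process_manifest(
            manifest,
            trace_dir=inp / "traces",
            q10=cfg.q10,
            t_ref=cfg.t_ref,
            deadband_s=cfg.deadband_s,
            r2_threshold=cfg.r2_threshold,
            literal_exponent=cfg.literal_exponent,
        )
        frames.append(fluxes)
        log.info("flux: %s -> %d measurements", Path(path).name, len(fluxes))
    all_fluxes = pd.concat(frames, ignore_index=True)
    all_fluxes.to_csv(out / "fluxes.csv", index=False)
    return len(all_fluxes)


def _stage_partition(cfg: RunConfig, out: Path):
    inp = cfg.resolved_input_dir()
    files = sorted(glob.glob(str(inp / "dendro_*.csv")))
    if not files:
        raise MissingInputError(f"no dendro_*.csv under {inp}")
    part_dir = out / "partitioned"
    part_dir.mkdir(exist_ok=True)
    daily_frames, annual_rows = [], []
    for path in files:
        stem = Path(path).stem  # dendro_<sprout>_<year>
        m = re.match(r"dendro_(.+)_(\d+)$", stem)
        sprout_id, year = (m.group(1), int(m.group(2))) if m else (stem, -1)
        series = pd.read_csv(path, parse_dates=["timestamp"])
        part = dendro.zero_growth_partition(series)
        part_out = part.rename(columns={"gro": "gro_um", "twd": "twd_um"})
        part_out[["timestamp", "gro_um", "twd_um"]].to_csv(
            part_dir / f"{stem}_partitioned.csv", index=False
        )
        daily = dendro.daily_stats(part, gap_hours=cfg.gap_hours)
        daily = dendro.add_moving_averages(
            daily, cfg.ma_window_days, cfg.ma_min_periods, cfg.ma_center
        )
        daily.insert(0, "sprout_id", sprout_id)
        daily.insert(1, "year", year)
        daily_frames.append(daily)
        annual_rows.append(
            {"sprout_id": sprout_id, "year": year,
             "annual_gro_um": float(part["gro"].iloc[-1])}
        )
    all_daily = pd.concat(daily_frames, ignore_index=True)
    all_daily.to_csv(out / "daily_stats.csv", index=False)
    pd.DataFrame(annual_rows).to_csv(out / "annual_growth.csv", index=False)
    log.info("partition: %d series, %d daily records", len(files), len(all_daily))
    return len(all_daily)


def fluxes_from_bundle(bundle, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Compute the flux table for an in-memory synthetic bundle (no files)."""
    cfg = cfg or RunConfig()
    frames = [
        chamber_flux.process_manifest(
            manifest,
            traces=bundle.traces,
            q10=cfg.q10,
            t_ref=cfg.t_ref,
            deadband_s=cfg.deadband_s,
            r2_threshold=cfg.r2_threshold,
            literal_exponent=cfg.literal_exponent,
        )
        for manifest in bundle.manifests.values()
    ]
    return pd.concat(frames, ignore_index=True)


def run_analysis(
    fluxes: pd.DataFrame,
    daily_stats: pd.DataFrame | None = None,
    reference_year: int = 2016,
    drought_year: int = 2017,
) -> dict:
    """Regression analysis on a flux table (and optional daily growth stats).

    Returns a dict of DataFrames: ``reference_fits`` (linear and exponential
    efflux-temperature fits per species on reference-year campaign/plot
    means), ``drought_effect`` (per-date residual and percent-of-expected
    summaries for the drought year), ``growth_fit`` (species comparison of
    R15 vs mean increment rate, when daily stats are available),
    ``correlations`` (per-campaign Pearson tests of R15 against sprout
    diameter and recent increment) and ``mixedmodel_input`` (the long-format
    per-sprout export).
    """
    fluxes = fluxes.copy()
    fluxes["year"] = pd.to_datetime(fluxes["date"]).dt.year
    means = stats.campaign_plot_means(fluxes)
    means["year"] = pd.to_datetime(means["date"]).dt.year

    ref_rows, eff_rows = [], []
    linear_fits = {}
    for sp, grp in means[means["year"] == reference_year].groupby("species"):
        lin = stats.fit_linear(grp["tstem_c"], grp["rs_volume"])
        linear_fits[sp] = lin
        ref_rows.append({
            "species": sp, "model": "linear", "slope": lin.slope,
            "slope_se": lin.slope_se, "intercept": lin.intercept,
            "intercept_se": lin.intercept_se, "r_squared": lin.r_squared,
            "n": lin.n,
        })
        try:
            expf = stats.fit_exponential(grp["tstem_c"], grp["rs_volume"])
            ref_rows.append({
                "species": sp, "model": "exponential", "slope": expf.rate,
                "slope_se": expf.rate_se, "intercept": expf.scale,
                "intercept_se": np.nan, "r_squared": expf.r_squared, "n": expf.n,
            })
        except (ValidationError, StemfluxError) as exc:
            log.warning("exponential fit skipped for %s: %s", sp, exc)

    drought_means = means[means["year"] == drought_year]
    for sp, grp in drought_means.groupby("species"):
        if sp not in linear_fits:
            continue
        points = grp.rename(columns={"rs_volume": "rs"})[
            ["date", "plot_id", "tstem_c", "rs"]
        ].assign(species=sp)
        for eff in stats.drought_effect(linear_fits[sp], points):
            eff_rows.append(dataclasses.asdict(eff))

    tables = {
        "reference_fits": pd.DataFrame(ref_rows),
        "drought_effect": pd.DataFrame(eff_rows),
    }

    corr_rows = []
    if daily_stats is not None and len(daily_stats):
        ds = daily_stats.copy()
        ds["date"] = ds["date"].astype(str)
        inc = ds[["sprout_id", "date", "increment_um_d_ma7"]]
        # plot/species mean increment rate on each campaign date
        per_sprout = fluxes.merge(inc, on=["sprout_id", "date"], how="left")
        growth_means = (
            per_sprout.groupby(["species", "plot_id", "date"], sort=True)
            .agg(r15=("r15", "mean"), increment_rate=("increment_um_d_ma7", "mean"))
            .dropna()
            .reset_index()
        )
        if len(growth_means) and growth_means["species"].nunique() == 2:
            gf = stats.compare_species_growth_fit(growth_means)
            rows = []
            for sp in gf.species:
                rows.append({
                    "species": sp, "intercept": gf.intercepts[sp],
                    "slope": gf.slopes[sp],
                    "intercept_diff": gf.intercept_diff,
                    "intercept_diff_p": gf.intercept_diff_p,
                    "slope_diff": gf.slope_diff, "slope_diff_p": gf.slope_diff_p,
                    "r_squared": gf.r_squared, "n": gf.n,
                })
            tables["growth_fit"] = pd.DataFrame(rows)
        # per-campaign correlations of R15 with size and recent growth
        for date, grp in per_sprout.groupby("date"):
            for var in ("d1_mm", "increment_um_d_ma7"):
                sub = grp.dropna(subset=[var, "r15"])
                if len(sub) >= 3 and np.ptp(sub[var]) > 0 and np.ptp(sub["r15"]) > 0:
                    r, p = stats.pearson_correlation(sub[var], sub["r15"])
                    corr_rows.append(
                        {"date": date, "variable": var, "r": r, "p": p,
                         "n": len(sub)}
                    )
        tables["mixedmodel_input"] = stats.mixed_model_table(fluxes, inc)
    else:
        tables["mixedmodel_input"] = stats.mixed_model_table(fluxes)
    tables["correlations"] = pd.DataFrame(corr_rows)
    return tables


def _stage_analyze(cfg: RunConfig, out: Path):
    fluxes_path = out / "fluxes.csv"
    if not fluxes_path.exists():
        raise MissingInputError(f"{fluxes_path} missing; run the flux stage first")
    fluxes = pd.read_csv(fluxes_path)
    daily_path = out / "daily_stats.csv"
    daily = pd.read_csv(daily_path) if daily_path.exists() else None
    tables = run_analysis(
        fluxes, daily, reference_year=cfg.reference_year,
        drought_year=cfg.drought_year,
    )
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
        log.info("analyze: %s -> %d rows", name, len(df))
    return sum(len(df) for df in tables.values())


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; abort downstream on failure.

    Returns the run report dict (also written to ``<out_dir>/run_report.json``).
    Raises the first stage error after recording it, so callers control the
    exit status.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not any(log.handlers):
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    report = {"seed": cfg.seed, "stages": {}, "status": "ok"}
    failure = None
    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                _record(report, stage, "skipped")
                continue
            if failure is not None:
                _record(report, stage, "aborted")
                continue
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    if stage == "simulate":
                        n = _stage_simulate(cfg)
                        warns = []
                    elif stage == "micromet":
                        n, warns = _stage_micromet(cfg, out)
                    elif stage == "flux":
                        n, warns = _stage_flux(cfg, out), []
                    elif stage == "partition":
                        n, warns = _stage_partition(cfg, out), []
                    elif stage == "analyze":
                        n, warns = _stage_analyze(cfg, out), []
                    warns = list(warns) + [str(w.message) for w in caught]
                    _record(report, stage, "ok", n, warns)
                except Exception as exc:  # recorded, then re-raised at the end
                    _record(report, stage, "failed", error=f"{type(exc).__name__}: {exc}")
                    report["status"] = "failed"
                    failure = exc
                    log.error("stage %s failed: %s", stage, exc)
    finally:
        log.removeHandler(fh)
        fh.close()
        with open(out / "run_report.json", "w") as fp:
            json.dump(report, fp, indent=1, sort_keys=True)
    if failure is not None:
        raise failure
    return report
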