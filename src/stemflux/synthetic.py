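"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a two-season coppice experiment: two species (oak,
hornbeam) on four treatment plots (C-0, T-0, C-r, T-r), six sprouts per
species per plot, one wet season and one with a rainless, high-VPD summer.
It produces

* hourly micrometeorology (Ta, RH, precipitation, soil water content from a
  simple bucket model, with an early-season deep-SWC outage bridged by
  sparse shallow manual readings),
* hourly dendrometer diameter series per sprout — a double-peaked seasonal
  growth curve (peaks near day-of-year 160 and 240, halved in the drought
  year) minus VPD-scaled diel shrinkage and a sustained drought shrinkage,
  plus observation noise,
* campaign chamber traces whose 1 Hz CO2 rise encodes a known true efflux
  through the exact inverse of the chamber flux equation, following a linear
  efflux-temperature reference relationship multiplied by a suppression
  factor f during the drought window,
* a ground-truth record (true growth, true fluxes, imposed f) consumed only
  by tests, never by the pipeline.

Everything derives from one seeded NumPy generator in a fixed order, so a
fixed seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber_flux import R_GAS, segment_geometry
from .exceptions import ValidationError

__all__ = [
    "ScenarioConfig",
    "SyntheticBundle",
    "generate_micromet",
    "generate_diameter_series",
    "generate_chamber_trace",
    "generate_campaign_dataset",
]

_PLOT_ORDER = ("C-0", "T-0", "T-r", "C-r")  # measurement order within campaigns


@dataclass
class ScenarioConfig:
    """Study-condition parameters of the synthetic scenario.

    Defaults encode the emulated experiment: 4 plots x 2 species x 6
    sprouts, six wet-year and four drought-year campaigns, first growth peak
    ~150 (oak) / 130 (hornbeam) um/day halved in the drought year, and a
    July-August flux suppression factor ``suppression_f`` in drought years.
    Noise scales are order-of-magnitude choices (no within-plot variance
    estimates exist to copy) and are documented in docs/methods.md.
    """

    seed: int = 0
    n_sprouts: int = 6  # per species per plot
    plots: tuple = _PLOT_ORDER
    species: tuple = ("oak", "hornbeam")
    seasons: tuple = ((2016, False), (2017, True))  # (year, drought)
    campaign_dates: dict = field(default_factory=lambda: {
        2016: ["2016-05-10", "2016-06-07", "2016-06-29",
               "2016-08-05", "2016-09-06", "2016-10-04"],
        2017: ["2017-06-07", "2017-07-04", "2017-08-01", "2017-09-04"],
    })
    season_start: str = "04-01"  # month-day, hourly records
    season_end: str = "10-31"
    drought_window: tuple = ("07-01", "08-31")  # month-day span of suppression

    # growth model (um/day): two Gaussian pulses in day-of-year
    growth_peaks: dict = field(default_factory=lambda: {
        "oak":      {"amp1": 150.0, "doy1": 166.0, "w1": 12.0,
                     "amp2": 120.0, "doy2": 240.0, "w2": 10.0},
        "hornbeam": {"amp1": 130.0, "doy1": 152.0, "w1": 12.0,
                     "amp2": 120.0, "doy2": 240.0, "w2": 10.0},
    })
    drought_growth_scale: float = 0.5   # peak amplitudes halved in drought year
    suppression_f: float = 0.3          # flux & growth factor in drought window
    sprout_growth_sigma: float = 0.15   # lognormal spread of annual growth

    # stem water dynamics (um)
    diel_amp_um: dict = field(default_factory=lambda: {"oak": 35.0, "hornbeam": 20.0})
    vpd_ref_hpa: float = 10.0           # daily VPD at which the diel amp is nominal
    sustained_twd_um: dict = field(default_factory=lambda: {"oak": 250.0, "hornbeam": 70.0})
    diameter_noise_um: float = 2.0

    # flux model: reference-year Rs = slope * Tstem + intercept (umol m-3 s-1)
    flux_slope: dict = field(default_factory=lambda: {"oak": 23.3, "hornbeam": 30.5})
    flux_intercept: dict = field(default_factory=lambda: {"oak": -271.5, "hornbeam": -374.2})
    min_flux: float = 5.0
    sprout_flux_sigma: float = 0.25     # mean-one lognormal, fixed per sprout
    plot_flux_sigma: float = 0.08       # mean-one lognormal, fixed per plot
    measurement_flux_sigma: float = 0.05

    # chamber geometry and trace
    diameter_range_mm: dict = field(default_factory=lambda: {
        "oak": (46.0, 58.0), "hornbeam": (35.0, 48.0)})
    segment_length_range_mm: tuple = (50.0, 80.0)
    system_volume_m3: float = 0.002
    pressure_pa: float = 101325.0
    trace_seconds: int = 60
    trace_noise_ppm: float = 0.5
    trace_c0_ppm: float = 420.0
    plot_temp_offsets_c: tuple = (0.0, 0.8, 1.6, 2.4)  # C-0 < T-0 < T-r < C-r

    # SWC bucket model and gap emulation
    swc_init_pct: float = 20.0
    swc_min_pct: float = 3.0
    swc_max_pct: float = 35.0
    swc_refill_pct_per_mm: float = 0.9
    swc_drawdown_pct_per_hpa_h: float = 0.012
    swc_gap_until: str = "07-10"        # deep sensor outage in the first wet year
    swc_calibration_slope: float = 0.8  # deep = slope * shallow + intercept
    swc_calibration_intercept: float = 3.0
    swc_shallow_noise_pct: float = 0.3

    def validate(self):
        if not (0.0 < self.suppression_f <= 1.0):
            raise ValidationError("suppression_f must lie in (0, 1]")
        for name in ("sprout_flux_sigma", "plot_flux_sigma", "measurement_flux_sigma",
                     "diameter_noise_um", "trace_noise_ppm", "sprout_growth_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for sp, amp in self.diel_amp_um.items():
            if amp < 0:
                raise ValidationError(f"diel amplitude for {sp} must be >= 0")
        return self


def _season_index(config: ScenarioConfig, year: int) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{year}-{config.season_start} 00:00",
        f"{year}-{config.season_end} 23:00",
        freq="h",
    )


def _in_window(index: pd.DatetimeIndex, year: int, window) -> np.ndarray:
    start = pd.Timestamp(f"{year}-{window[0]}")
    end = pd.Timestamp(f"{year}-{window[1]} 23:59")
    return (index >= start) & (index <= end)


def _lognormal_mean_one(rng: np.random.Generator, sigma: float, size=None):
    """Lognormal multiplier with expectation exactly 1."""
    return np.exp(rng.normal(0.0, sigma, size=size) - sigma**2 / 2.0)


# ---------------------------------------------------------------------------
# Micrometeorology
# ---------------------------------------------------------------------------

def generate_micromet(
    config: ScenarioConfig, year: int, drought: bool, rng: np.random.Generator
) -> pd.DataFrame:
    """Hourly Ta, RH, precipitation and bucket-model SWC for one season.

    Ta combines a seasonal and a diel sinusoid with smooth day-level noise;
    RH is anticorrelated with Ta; precipitation is a marked Poisson process
    (suppressed to zero in the drought window of drought years, which also
    gets hotter and drier air); SWC follows a rain-refill / VPD-drawdown
    bucket bounded to the physical range.  In the first configured wet year
    the deep SWC before ``swc_gap_until`` is masked (sensor outage) and
    sparse shallow manual readings are emitted on campaign-day mornings.
    """
    idx = _season_index(config, year)
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy().astype(float)
    n = len(idx)

    # air temperature: seasonal + diel + smoothed daily noise
    ta = 7.5 + 11.0 * np.sin(2 * np.pi * (doy - 105.0) / 365.0)
    ta = ta + 5.0 * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    daily_noise = rng.normal(0.0, 2.0, size=int(np.ceil(n / 24)) + 1)
    ta = ta + np.repeat(daily_noise, 24)[:n]
    in_window = _in_window(idx, year, config.drought_window)
    if drought:
        ta = ta + 3.0 * in_window  # heat-wave summer

    # relative humidity anticorrelated with Ta
    rh = 95.0 - 2.2 * (ta - 5.0) + rng.normal(0.0, 3.0, size=n)
    if drought:
        rh = rh - 12.0 * in_window
    rh = np.clip(rh, 15.0, 100.0)

    # precipitation: marked Poisson, rainless drought window
    wet_hour = rng.random(n) < 0.045
    amount = rng.exponential(1.5, size=n)
    precip = np.where(wet_hour, amount, 0.0)
    if drought:
        precip = np.where(in_window, 0.0, precip)

    # VPD drives the soil-water drawdown (Magnus, hPa)
    es_kpa = 0.6108 * np.exp(17.2694 * ta / (237.3 + ta))
    vpd = 10.0 * es_kpa * (1.0 - rh / 100.0)

    swc = np.empty(n)
    s = config.swc_init_pct
    for i in range(n):
        refill = config.swc_refill_pct_per_mm * precip[i] * (1.0 - s / config.swc_max_pct)
        draw = (
            config.swc_drawdown_pct_per_hpa_h
            * vpd[i]
            * (s - config.swc_min_pct)
            / (config.swc_init_pct - config.swc_min_pct)
        )
        s = float(np.clip(s + refill - draw, config.swc_min_pct, config.swc_max_pct))
        swc[i] = s

    df = pd.DataFrame(
        {
            "timestamp": idx,
            "ta_c": np.round(ta, 3),
            "rh_pct": np.round(rh, 3),
            "precip_mm": np.round(precip, 3),
            "swc_pct": np.round(swc, 3),
        }
    )

    # deep-sensor outage in the first wet year, bridged by shallow readings
    first_wet_year = next((y for y, dr in config.seasons if not dr), None)
    if year == first_wet_year:
        gap = idx < pd.Timestamp(f"{year}-{config.swc_gap_until}")
        shallow = np.full(n, np.nan)
        campaign_days = {pd.Timestamp(d).date() for d in config.campaign_dates.get(year, [])}
        on_campaign = np.array(
            [(t.date() in campaign_days) and (9 <= t.hour <= 13) for t in idx]
        )
        shallow_true = (swc - config.swc_calibration_intercept) / config.swc_calibration_slope
        noise = rng.normal(0.0, config.swc_shallow_noise_pct, size=n)
        shallow[on_campaign] = np.round(shallow_true[on_campaign] + noise[on_campaign], 3)
        df["swc_shallow_pct"] = shallow
        df.loc[gap, "swc_pct"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Dendrometer series
# ---------------------------------------------------------------------------

def _growth_rate_um_per_day(doy, peaks: dict) -> np.ndarray:
    g1 = peaks["amp1"] * np.exp(-0.5 * ((doy - peaks["doy1"]) / peaks["w1"]) ** 2)
    g2 = peaks["amp2"] * np.exp(-0.5 * ((doy - peaks["doy2"]) / peaks["w2"]) ** 2)
    return g1 + g2


def generate_diameter_series(
    config: ScenarioConfig,
    micromet: pd.DataFrame,
    species: str,
    year: int,
    drought: bool,
    rng: np.random.Generator,
    growth_scale: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """One sprout's hourly diameter series plus its ground truth.

    diameter = cumulative growth - diel shrink - sustained drought shrink
    + observation noise, in um of dendrometer displacement from the
    season-start zero.  ``growth_scale`` is the sprout's lognormal growth
    multiplier (drawn by the caller so truth can be recorded).
    """
    idx = pd.DatetimeIndex(micromet["timestamp"])
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy().astype(float)
    n = len(idx)

    rate = _growth_rate_um_per_day(doy, config.growth_peaks[species]) * growth_scale
    if drought:
        rate = rate * config.drought_growth_scale
        in_window = _in_window(idx, year, config.drought_window)
        rate = np.where(in_window, rate * config.suppression_f, rate)
    growth = np.cumsum(rate / 24.0)

    # diel shrink: zero at 06:00, peak at 18:00, amplitude scaled by daily VPD
    es_kpa = 0.6108 * np.exp(
        17.2694 * micromet["ta_c"].to_numpy() / (237.3 + micromet["ta_c"].to_numpy())
    )
    vpd = 10.0 * es_kpa * (1.0 - micromet["rh_pct"].to_numpy() / 100.0)
    vpd_daily = pd.Series(vpd, index=idx).groupby(idx.date).transform("mean").to_numpy()
    amp = config.diel_amp_um[species] * np.clip(vpd_daily / config.vpd_ref_hpa, 0.2, 2.5)
    diel = amp * 0.5 * (1.0 - np.cos(2 * np.pi * (hour - 6.0) / 24.0))

    # sustained drought shrinkage: ramps up inside the window, relaxes after
    sustained = np.zeros(n)
    if drought:
        w = _in_window(idx, year, config.drought_window)
        ramp = np.cumsum(w) / max(w.sum(), 1)
        after = np.cumsum(~w & (np.cumsum(w) > 0))  # hours since window end
        relax = np.exp(-after / (15.0 * 24.0))
        sustained = config.sustained_twd_um[species] * np.minimum(ramp, 1.0) * relax

    noise = rng.normal(0.0, config.diameter_noise_um, size=n)
    diameter = growth - diel - sustained + noise
    truth = {
        "true_annual_growth_um": float(growth[-1]),
        "max_diel_amp_um": float(amp.max()),
        "growth_scale": float(growth_scale),
    }
    series = pd.DataFrame({"timestamp": idx, "diameter": np.round(diameter, 3)})
    return series, truth


# ---------------------------------------------------------------------------
# Chamber traces and campaigns
# ---------------------------------------------------------------------------

def generate_chamber_trace(
    true_flux: float,
    v2_m3: float,
    v1_m3: float,
    pressure_pa: float,
    tair_k: float,
    noise_sd_ppm: float,
    rng: np.random.Generator | None = None,
    duration_s: int = 60,
    c0_ppm: float = 420.0,
) -> pd.DataFrame:
    """1 Hz chamber trace encoding a known true efflux.

    The concentration slope is the exact inverse of the chamber flux
    equation: slope = true_flux * R * T * V2 / (P * V1), so recomputing the
    flux from a noise-free trace returns ``true_flux`` identically.
    """
    if not np.isfinite(true_flux):
        raise ValidationError("true_flux must be finite")
    if v2_m3 <= 0 or v1_m3 <= 0 or pressure_pa <= 0 or tair_k <= 0:
        raise ValidationError("chamber geometry and conditions must be > 0")
    slope = true_flux * R_GAS * tair_k * v2_m3 / (pressure_pa * v1_m3)
    t = np.arange(duration_s, dtype=float)
    c = c0_ppm + slope * t
    if noise_sd_ppm > 0:
        if rng is None:
            raise ValidationError("an rng is required for noisy traces")
        c = c + rng.normal(0.0, noise_sd_ppm, size=t.size)
    # full precision: the noise-free trace must invert to the flux exactly
    return pd.DataFrame({"time_s": t, "co2_ppm": c})


@dataclass
class SyntheticBundle:
    """In-memory synthetic dataset: inputs plus the ground-truth record."""

    config: ScenarioConfig
    micromet: dict            # year -> DataFrame
    dendro: dict              # (sprout_id, year) -> DataFrame
    manifests: dict           # year -> DataFrame
    traces: dict              # trace_file -> DataFrame
    ground_truth: dict

    def write(self, out_dir) -> None:
        """Write the bundle in the pipeline's CSV interchange formats."""
        out = Path(out_dir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        for year, df in self.micromet.items():
            df.to_csv(out / f"micromet_{year}.csv", index=False)
        for (sprout_id, year), df in self.dendro.items():
            df.to_csv(out / f"dendro_{sprout_id}_{year}.csv", index=False)
        for year, df in self.manifests.items():
            df.to_csv(out / f"manifest_{year}.csv", index=False)
        for name, df in self.traces.items():
            df.to_csv(out / "traces" / name, index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def generate_campaign_dataset(
    config: ScenarioConfig | None = None,
    out_dir=None,
    include_dendrometer: bool = True,
) -> SyntheticBundle:
    """Generate the full two-season input bundle.

    Campaign fluxes follow the configured linear efflux-temperature
    reference relationship per species, multiplied by ``suppression_f`` on
    drought-window dates of drought years, with mean-one lognormal plot,
    sprout and measurement multipliers.  Optionally writes all files to
    ``out_dir`` (see :meth:`SyntheticBundle.write`).
    """
    config = (config or ScenarioConfig()).validate()
    rng = np.random.default_rng(config.seed)

    micromet = {
        year: generate_micromet(config, year, drought, rng)
        for year, drought in config.seasons
    }

    # per-sprout static properties, in a fixed order
    sprout_ids, sprout_meta = [], {}
    for plot in config.plots:
        for sp in config.species:
            for k in range(1, config.n_sprouts + 1):
                sid = f"{plot}-{sp}-{k}"
                lo, hi = config.diameter_range_mm[sp]
                d1 = rng.uniform(lo, hi)
                d2 = d1 * rng.uniform(0.9, 1.1)
                length = rng.uniform(*config.segment_length_range_mm)
                sprout_meta[sid] = {
                    "plot_id": plot,
                    "species": sp,
                    "d1_mm": round(d1, 2),
                    "d2_mm": round(d2, 2),
                    "length_mm": round(length, 2),
                    "flux_factor": float(
                        _lognormal_mean_one(rng, config.sprout_flux_sigma)
                    ),
                    "growth_scale": float(
                        _lognormal_mean_one(rng, config.sprout_growth_sigma)
                    ),
                }
                sprout_ids.append(sid)
    plot_factor = {
        (plot, sp): float(_lognormal_mean_one(rng, config.plot_flux_sigma))
        for plot in config.plots
        for sp in config.species
    }

    dendro, truth_dendro = {}, {}
    if include_dendrometer:
        for year, drought in config.seasons:
            for sid in sprout_ids:
                meta = sprout_meta[sid]
                series, truth = generate_diameter_series(
                    config, micromet[year], meta["species"], year, drought, rng,
                    growth_scale=meta["growth_scale"],
                )
                dendro[(sid, year)] = series
                truth_dendro[f"{sid}_{year}"] = truth

    manifests, traces, truth_flux = {}, {}, {}
    temp_offsets = dict(zip(_PLOT_ORDER, config.plot_temp_offsets_c))
    for year, drought in config.seasons:
        met = micromet[year].set_index("timestamp")
        rows = []
        for date_str in config.campaign_dates[year]:
            date = pd.Timestamp(date_str)
            ta10 = float(met.loc[date + pd.Timedelta(hours=10), "ta_c"])
            in_window = (
                drought
                and f"{year}-{config.drought_window[0]}"
                <= date_str
                <= f"{year}-{config.drought_window[1]}"
            )
            f = config.suppression_f if in_window else 1.0
            truth_flux.setdefault(str(year), {})[date_str] = {"suppression_f": f}
            for plot in config.plots:
                tstem_base = max(ta10 + temp_offsets[plot], 14.0)
                for sid in sprout_ids:
                    meta = sprout_meta[sid]
                    if meta["plot_id"] != plot:
                        continue
                    sp = meta["species"]
                    tstem = tstem_base + rng.normal(0.0, 0.3)
                    base = config.flux_slope[sp] * tstem + config.flux_intercept[sp]
                    rs_true = max(
                        base
                        * f
                        * plot_factor[(plot, sp)]
                        * meta["flux_factor"]
                        * _lognormal_mean_one(rng, config.measurement_flux_sigma),
                        config.min_flux,
                    )
                    v2, _ = segment_geometry(
                        meta["d1_mm"] / 1000.0,
                        meta["d2_mm"] / 1000.0,
                        meta["length_mm"] / 1000.0,
                    )
                    tair_k = tstem + 273.15 + 1.0
                    trace_name = f"{sid}_{date_str}.csv"
                    traces[trace_name] = generate_chamber_trace(
                        rs_true, v2, config.system_volume_m3, config.pressure_pa,
                        tair_k, config.trace_noise_ppm, rng,
                        duration_s=config.trace_seconds, c0_ppm=config.trace_c0_ppm,
                    )
                    truth_flux[str(year)][date_str][sid] = {
                        "true_rs_volume": float(rs_true)
                    }
                    rows.append(
                        {
                            "sprout_id": sid,
                            "plot_id": plot,
                            "species": sp,
                            "date": date_str,
                            "d1_mm": meta["d1_mm"],
                            "d2_mm": meta["d2_mm"],
                            "length_mm": meta["length_mm"],
                            "v1_m3": config.system_volume_m3,
                            "pressure_pa": config.pressure_pa,
                            "tair_k": round(tair_k, 3),
                            "tstem_c": round(tstem, 3),
                            "trace_file": trace_name,
                        }
                    )
        manifests[year] = pd.DataFrame(rows)

    ground_truth = {
        "config_seed": config.seed,
        "suppression_f": config.suppression_f,
        "flux_model": {
            sp: {"slope": config.flux_slope[sp], "intercept": config.flux_intercept[sp]}
            for sp in config.species
        },
        "dendrometer": truth_dendro,
        "campaign_fluxes": truth_flux,
        "plot_factors": {f"{p}|{s}": v for (p, s), v in plot_factor.items()},
        "swc_calibration": {
            "slope": config.swc_calibration_slope,
            "intercept": config.swc_calibration_intercept,
        },
    }
    bundle = SyntheticBundle(
        config=config,
        micromet=micromet,
        dendro=dendro,
        manifests=manifests,
        traces=traces,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
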