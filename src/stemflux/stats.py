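"""Regression-based inference on campaign fluxes and growth.

The drought-effect analysis fits the efflux-temperature relationship in a
reference (wet) year on campaign/plot mean values, then expresses each
drought-year observation as a residual from, and a percentage of, the
reference prediction at the observed stem temperature.  A linear and a
log-linear (exponential) temperature response are compared on original-scale
R^2.  The coupling of temperature-normalized efflux (R15) to the stem
increment rate is compared between species with an OLS interaction model
(the classical ANCOVA), and campaign-level Pearson correlations probe
whether sprout size or recent growth explains spatial variability in R15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import DegenerateFitError, InsufficientDataError, ValidationError

__all__ = [
    "RegressionResult",
    "ExponentialFit",
    "DroughtEffect",
    "GrowthRespirationFit",
    "fit_linear",
    "fit_exponential",
    "predict_linear",
    "drought_effect",
    "compare_species_growth_fit",
    "pearson_correlation",
    "campaign_plot_means",
    "mixed_model_table",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary: y = intercept + slope * x."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n: int
    residual_se: float
    flag: str = "ok"  # ok | flat_response


@dataclass(frozen=True)
class ExponentialFit:
    """Log-linear fit y = scale * exp(rate * x).

    ``r_squared`` is computed on the original scale (1 - SSE/SST of y, not
    of log y) so it is directly comparable with a linear fit's R^2.
    """

    scale: float
    rate: float
    rate_se: float
    r_squared: float
    r_squared_log: float
    n: int


@dataclass(frozen=True)
class DroughtEffect:
    """Per date and species: departure of drought-year efflux from reference.

    ``residual_*`` are in efflux units (umol m-3 s-1), ``percent_*`` are
    100 * measured / predicted; means and SDs are taken across plots.
    """

    date: str
    species: str
    residual_mean: float
    residual_sd: float
    percent_mean: float
    percent_sd: float
    n_plots: int
    n_excluded: int = 0  # points with non-positive predicted efflux


def fit_linear(x, y) -> RegressionResult:
    """OLS fit of y on x with classical standard errors.

    Raises :class:`InsufficientDataError` for n < 2 and
    :class:`DegenerateFitError` for zero variance in x.  A flat response
    (zero variance in y) is legal: slope 0 with R^2 reported as 0 and the
    result flagged ``flat_response``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"linear fit needs >= 2 points, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("predictor has zero variance")
    res = sps.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = n - 2
    residual_se = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else np.nan
    if np.ptp(y) == 0.0:
        r2, flag = 0.0, "flat_response"
    else:
        r2, flag = float(res.rvalue**2), "ok"
    return RegressionResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r_squared=r2,
        n=int(n),
        residual_se=residual_se,
        flag=flag,
    )


def predict_linear(fit: RegressionResult, x):
    """Predicted response of a linear fit at ``x``."""
    return fit.intercept + fit.slope * np.asarray(x, dtype=float)


def fit_exponential(x, y) -> ExponentialFit:
    """Fit y = scale * exp(rate * x) by OLS on log y.

    All y must be strictly positive.  R^2 is reported on the original scale
    for comparability with :func:`fit_linear`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise InsufficientDataError(f"exponential fit needs >= 2 points, got {x.size}")
    if np.any(y <= 0):
        raise ValidationError("exponential fit requires strictly positive y")
    log_fit = fit_linear(x, np.log(y))
    pred = np.exp(log_fit.intercept + log_fit.slope * x)
    sst = np.sum((y - y.mean()) ** 2)
    sse = np.sum((y - pred) ** 2)
    r2 = float(1.0 - sse / sst) if sst > 0 else 0.0
    return ExponentialFit(
        scale=float(np.exp(log_fit.intercept)),
        rate=log_fit.slope,
        rate_se=log_fit.slope_se,
        r_squared=r2,
        r_squared_log=log_fit.r_squared,
        n=int(x.size),
    )


def drought_effect(
    reference_fit: RegressionResult, drought_points: pd.DataFrame
) -> list[DroughtEffect]:
    """Residuals and percent-of-expected for drought-year campaign points.

    ``drought_points`` carries one row per plot/date (and optionally
    species): columns ``date, plot_id, tstem_c, rs`` and optionally
    ``species``.  For each point the reference fit predicts the efflux at
    the observed stem temperature; residual = rs - predicted and percent =
    100 * rs / predicted.  Means and SDs (ddof=1) are taken across plots per
    date.  Points with non-positive predicted efflux are excluded from the
    percent summary with a warning.
    """
    req = {"date", "plot_id", "tstem_c", "rs"}
    if not req.issubset(drought_points.columns):
        raise ValidationError(f"drought_points needs columns {sorted(req)}")
    df = drought_points.copy()
    if "species" not in df.columns:
        df["species"] = "all"
    df["predicted"] = predict_linear(reference_fit, df["tstem_c"].to_numpy())
    df["residual"] = df["rs"] - df["predicted"]
    df["percent"] = np.where(
        df["predicted"] > 0, 100.0 * df["rs"] / df["predicted"], np.nan
    )
    n_bad = int((df["predicted"] <= 0).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} drought points had non-positive predicted efflux; "
            "percent-of-expected undefined for those",
            stacklevel=2,
        )
    out = []
    for (date, species), grp in df.groupby(["date", "species"], sort=True):
        pct = grp["percent"].dropna()
        out.append(
            DroughtEffect(
                date=str(date),
                species=str(species),
                residual_mean=float(grp["residual"].mean()),
                residual_sd=float(grp["residual"].std(ddof=1))
                if len(grp) > 1
                else np.nan,
                percent_mean=float(pct.mean()) if len(pct) else np.nan,
                percent_sd=float(pct.std(ddof=1)) if len(pct) > 1 else np.nan,
                n_plots=int(len(grp)),
                n_excluded=int(grp["percent"].isna().sum()),
            )
        )
    return out


@dataclass(frozen=True)
class GrowthRespirationFit:
    """Species comparison of the R15 ~ increment-rate relationship.

    Fitted as one OLS with a species indicator and its interaction with the
    increment rate; ``intercept_diff``/``slope_diff`` are the indicator and
    interaction coefficients (second species minus baseline) with t-test
    p-values.  ``species`` lists the labels in baseline-first order.
    """

    species: tuple
    intercepts: dict
    slopes: dict
    intercept_diff: float
    intercept_diff_se: float
    intercept_diff_p: float
    slope_diff: float
    slope_diff_se: float
    slope_diff_p: float
    r_squared: float
    n: int
    flag: str = "ok"  # ok | single_species

    def ratio_at_rate(self, species: str, rate: float) -> float:
        """Percent of the zero-increment (maintenance) R15 at a given rate.

        ratio_at_rate(0) is 100 % by construction; values above 100 %
        quantify the growth-respiration surcharge.
        """
        b0 = self.intercepts[species]
        b1 = self.slopes[species]
        return 100.0 * (b0 + b1 * rate) / b0


def compare_species_growth_fit(data: pd.DataFrame) -> GrowthRespirationFit:
    """ANCOVA-style comparison of R15 vs increment-rate lines between species.

    ``data`` has columns ``species, increment_rate, r15`` with >= 3 points
    per species.  A single OLS on [1, I(species=B), rate, I*rate] yields the
    per-species intercepts/slopes and t-tests of the intercept and slope
    differences.  With only one species present the fit falls back to that
    species alone (differences NaN, flag ``single_species``).
    """
    req = {"species", "increment_rate", "r15"}
    if not req.issubset(data.columns):
        raise ValidationError(f"growth-fit data needs columns {sorted(req)}")
    df = data.dropna(subset=["increment_rate", "r15"])
    labels = sorted(df["species"].unique())
    if len(labels) == 0:
        raise InsufficientDataError("no data for the species growth fit")
    if len(labels) == 1:
        warnings.warn(
            f"only one species ({labels[0]}) present; fitting single line",
            stacklevel=2,
        )
        lf = fit_linear(df["increment_rate"], df["r15"])
        return GrowthRespirationFit(
            species=(labels[0],),
            intercepts={labels[0]: lf.intercept},
            slopes={labels[0]: lf.slope},
            intercept_diff=np.nan, intercept_diff_se=np.nan, intercept_diff_p=np.nan,
            slope_diff=np.nan, slope_diff_se=np.nan, slope_diff_p=np.nan,
            r_squared=lf.r_squared, n=lf.n, flag="single_species",
        )
    if len(labels) > 2:
        raise ValidationError("species comparison supports exactly two species")
    counts = df["species"].value_counts()
    if counts.min() < 3:
        raise InsufficientDataError("need >= 3 points per species")
    a, b = labels
    rate = df["increment_rate"].to_numpy(dtype=float)
    ind = (df["species"] == b).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), ind, rate, ind * rate])
    model = sm.OLS(df["r15"].to_numpy(dtype=float), X).fit()
    beta, se, pvals = model.params, model.bse, model.pvalues
    return GrowthRespirationFit(
        species=(a, b),
        intercepts={a: float(beta[0]), b: float(beta[0] + beta[1])},
        slopes={a: float(beta[2]), b: float(beta[2] + beta[3])},
        intercept_diff=float(beta[1]),
        intercept_diff_se=float(se[1]),
        intercept_diff_p=float(pvals[1]),
        slope_diff=float(beta[3]),
        slope_diff_se=float(se[3]),
        slope_diff_p=float(pvals[3]),
        r_squared=float(model.rsquared),
        n=int(len(df)),
    )


def pearson_correlation(x, y):
    """Sample Pearson correlation with a two-sided p-value.

    The p-value comes from the t-transform with n-2 degrees of freedom.
    Zero variance in either variable leaves the correlation undefined:
    returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError(f"Pearson correlation needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("zero variance: Pearson correlation undefined", stacklevel=2)
        return np.nan, np.nan
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Aggregation helpers
# ---------------------------------------------------------------------------

def campaign_plot_means(
    fluxes: pd.DataFrame,
    value_cols=("rs_volume", "rs_surface", "r15", "tstem_c"),
    exclude_flags=("negative_slope",),
) -> pd.DataFrame:
    """Mean per species / plot / campaign date over sprouts.

    All downstream regressions consume these campaign/plot means rather than
    raw per-sprout values.  Measurements whose quality flag is listed in
    ``exclude_flags`` are dropped first.
    """
    df = fluxes
    if "quality_flag" in df.columns and exclude_flags:
        df = df[~df["quality_flag"].isin(exclude_flags)]
    cols = [c for c in value_cols if c in df.columns]
    out = (
        df.groupby(["species", "plot_id", "date"], sort=True)[cols]
        .mean()
        .reset_index()
    )
    return out


def mixed_model_table(
    fluxes: pd.DataFrame, daily_increments: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-format per-sprout table for external mixed-model fitting.

    Adds thinning / throughfall-reduction indicator columns decoded from the
    plot label (C-0, T-0, C-r, T-r) and, when daily increment statistics are
    supplied (columns ``sprout_id, date, increment_um_d_ma7``), merges the
    sprout's 7-day mean increment on the campaign date.  The model itself
    (random intercepts for tree and measurement day) is left to external
    tooling; this package only exports the table it would consume.
    """
    out = fluxes.copy()
    plot = out["plot_id"].astype(str)
    out["thinning"] = plot.str.startswith("T").astype(int)
    out["reduction"] = plot.str.endswith("r").astype(int)
    if daily_increments is not None:
        inc = daily_increments[["sprout_id", "date", "increment_um_d_ma7"]].copy()
        inc["date"] = inc["date"].astype(str)
        out["date"] = out["date"].astype(str)
        out = out.merge(inc, on=["sprout_id", "date"], how="left")
    return out
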