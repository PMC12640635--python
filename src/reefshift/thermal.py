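"""Thermal-stress climatology from a daily sea-surface-temperature series.

Implements the monthly climatology and its Maximum of Monthly Means (MMM),
bleaching/cooling thresholds, a modified degree-heating-week (DHW)
accumulation with a configurable trailing window, annual
threshold-exceedance counts, OLS trend fitting, and monthly aggregation of
in-situ logger records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ClimatologyError, FitError, ValidationError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

__all__ = [
    "ClimatologyConfig",
    "ThermalClimatology",
    "TrendFit",
    "as_daily_series",
    "compute_climatology",
    "compute_dhw",
    "annual_exceedance",
    "fit_trend",
    "dates_to_years",
    "slope_per_decade",
    "aggregate_logger",
]


@dataclass(frozen=True)
class ClimatologyConfig:
    """Baseline years and threshold offsets for the climatology.

    ``window_days`` is the trailing DHW accumulation window (84 days =
    12 weeks). ``accumulate`` selects what is summed on exceedance days:
    ``"magnitude"`` adds the hotspot SST − MMM (°C·days, reported /7 as
    °C-weeks), ``"count"`` adds 1 per day (reported /7 as weeks) — kept as
    a sensitivity switch.
    """

    baseline_years: frozenset = frozenset(range(1985, 1991)) | {1993}
    hotspot_offset: float = 0.5
    cool_offset: float = 0.5
    window_days: int = 84
    accumulate: str = "magnitude"

    def __post_init__(self):
        if not self.baseline_years:
            raise ValidationError("baseline_years must be nonempty")
        if self.hotspot_offset < 0 or self.cool_offset < 0:
            raise ValidationError("threshold offsets must be >= 0")
        if self.window_days < 7:
            raise ValidationError("window_days must be >= 7")
        if self.accumulate not in ("magnitude", "count"):
            raise ValidationError("accumulate must be 'magnitude' or 'count'")
        object.__setattr__(self, "baseline_years", frozenset(self.baseline_years))


@dataclass(frozen=True)
class ThermalClimatology:
    """Monthly climatological means with derived thresholds (°C)."""

    monthly_mean: np.ndarray  # 12 values, index 0 = January
    mmm: float
    bleaching_threshold: float
    cooling_threshold: np.ndarray  # 12 values
    hotspot_offset: float = 0.5
    cool_offset: float = 0.5

    def __post_init__(self):
        mm = np.asarray(self.monthly_mean, dtype=float)
        ct = np.asarray(self.cooling_threshold, dtype=float)
        if mm.shape != (12,) or ct.shape != (12,):
            raise ValidationError("monthly_mean and cooling_threshold must have 12 entries")
        object.__setattr__(self, "monthly_mean", mm)
        object.__setattr__(self, "cooling_threshold", ct)


def as_daily_series(values, dates=None) -> pd.Series:
    """Coerce input to a float series indexed by strictly increasing dates."""
    if isinstance(values, pd.Series):
        s = values.astype(float)
        s.index = pd.DatetimeIndex(s.index)
    else:
        if dates is None:
            raise ValidationError("dates required when values is not a Series")
        s = pd.Series(np.asarray(values, dtype=float), index=pd.DatetimeIndex(dates))
    if not s.index.is_monotonic_increasing or s.index.has_duplicates:
        raise ValidationError("dates must be strictly increasing")
    if not np.isfinite(s.to_numpy()).all():
        raise ValidationError("series values must be finite")
    return s


def compute_climatology(series: pd.Series, config: ClimatologyConfig = ClimatologyConfig()) -> ThermalClimatology:
    """Two-stage monthly climatology and MMM over the baseline years.

    Daily values are averaged within each year-month first, then the
    year-month means are averaged across baseline years, so months keep
    equal weight regardless of data density or month length.
    """
    s = as_daily_series(series)
    base = s[np.isin(s.index.year, sorted(config.baseline_years))]
    if base.empty:
        raise ClimatologyError("no data in any baseline year")
    ym = base.groupby([base.index.year, base.index.month]).mean()
    monthly = ym.groupby(level=1).mean()
    missing = sorted(set(range(1, 13)) - set(monthly.index))
    if missing:
        raise ClimatologyError(
            f"calendar month(s) {missing} absent from all baseline years"
        )
    monthly_mean = monthly.reindex(range(1, 13)).to_numpy()
    mmm = float(monthly_mean.max())
    return ThermalClimatology(
        monthly_mean=monthly_mean,
        mmm=mmm,
        bleaching_threshold=mmm + config.hotspot_offset,
        cooling_threshold=monthly_mean - config.cool_offset,
        hotspot_offset=config.hotspot_offset,
        cool_offset=config.cool_offset,
    )


def _hotspot(values: np.ndarray, clim: ThermalClimatology, accumulate: str) -> np.ndarray:
    exceed = values > clim.bleaching_threshold
    if accumulate == "count":
        return exceed.astype(float)
    return np.where(exceed, values - clim.mmm, 0.0)


def compute_dhw(
    series: pd.Series,
    clim: ThermalClimatology,
    config: ClimatologyConfig = ClimatologyConfig(),
) -> pd.Series:
    """Trailing-window degree heating weeks in °C-weeks.

    dhw(t) = sum over the ``window_days`` calendar days ending at t of the
    daily hotspot (SST − MMM on days with SST > MMM + offset, else 0),
    divided by 7. The first ``window_days − 1`` days carry NaN; calendar
    gaps contribute 0 (a warning is logged when a window is >10% gappy).
    """
    s = as_daily_series(series)
    if len(s) < config.window_days:
        warnings.warn("series shorter than the DHW window; returning empty result")
        return pd.Series(dtype=float, name="dhw")
    full = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    present = full.notna()
    hot = pd.Series(
        np.where(present, _hotspot(full.to_numpy(), clim, config.accumulate), 0.0),
        index=full.index,
    )
    w = config.window_days
    dhw = hot.rolling(w, min_periods=w).sum() / 7.0
    gap_frac = 1.0 - present.rolling(w, min_periods=w).mean()
    if (gap_frac > 0.10).any():
        logger.warning(
            "DHW windows with >10%% missing days: %d", int((gap_frac > 0.10).sum())
        )
    dhw.name = "dhw"
    return dhw


def annual_exceedance(series: pd.Series, clim: ThermalClimatology) -> pd.DataFrame:
    """Per-year counts of warm days (SST > MMM + offset) and cool days
    (SST < monthly climatological mean − offset). Missing days are simply
    absent from the counts."""
    s = as_daily_series(series)
    values = s.to_numpy()
    warm = values > clim.bleaching_threshold
    cool = values < clim.cooling_threshold[s.index.month.to_numpy() - 1]
    out = pd.DataFrame(
        {"warm_days": warm, "cool_days": cool}, index=s.index.year
    ).groupby(level=0).sum()
    out.index.name = "year"
    return out.astype(int)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit summary; slope is per unit of the supplied predictor."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple
    p_value: float
    stderr: float
    covariate_coefs: dict = field(default_factory=dict)


def dates_to_years(dates) -> np.ndarray:
    """Convert dates to fractional years since the first date (365.25 d/y)."""
    idx = pd.DatetimeIndex(dates)
    return (idx - idx[0]).days.to_numpy() / DAYS_PER_YEAR


def slope_per_decade(fit: TrendFit) -> float:
    """Slope of a per-year fit expressed per decade."""
    return fit.slope * 10.0


def fit_trend(x, y, covariates: pd.DataFrame | None = None) -> TrendFit:
    """Ordinary least squares of ``y`` on ``x`` (plus optional covariates).

    ``x`` may be datelike, in which case it is converted to fractional
    years so the slope is °C per year (see :func:`slope_per_decade`).
    """
    x = np.asarray(x)
    if np.issubdtype(x.dtype, np.datetime64) or isinstance(
        x.flat[0] if x.size else None, (pd.Timestamp,)
    ):
        x = dates_to_years(x)
    x = x.astype(float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise FitError("zero predictor variance")
    X = pd.DataFrame({"x": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    model = sm.OLS(y[keep], sm.add_constant(X[keep])).fit()
    cov_coefs = {
        name: float(model.params[name]) for name in X.columns if name != "x"
    }
    return TrendFit(
        slope=float(model.params["x"]),
        intercept=float(model.params["const"]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        p_value=float(model.f_pvalue),
        stderr=float(model.bse["x"]),
        covariate_coefs=cov_coefs,
    )


def aggregate_logger(records: pd.DataFrame) -> pd.DataFrame:
    """Monthly mean/max/min per site from sub-daily logger records.

    ``records`` columns: site, datetime, temp_c. Months with no data are
    simply absent from the output.
    """
    for col in ("site", "datetime", "temp_c"):
        if col not in records.columns:
            raise ValidationError(f"logger table missing column '{col}'", column=col)
    df = records.copy()
    df["datetime"] = pd.to_datetime(df["datetime"])
    grouped = df.groupby(
        ["site", df["datetime"].dt.year.rename("year"), df["datetime"].dt.month.rename("month")]
    )["temp_c"]
    out = grouped.agg(mean_c="mean", max_c="max", min_c="min").reset_index()
    return out
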