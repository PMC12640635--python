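"""CSV schema contracts for the pipeline's input and output tables.

Schemas (all dates ISO 8601):

* SST:     date, sst_c
* benthic: site, date, transect, category, proportion
* belt:    site, date, transect, taxon, health_state, count
* logger:  site, datetime, temp_c
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diversity import HEALTH_STATES
from .errors import ValidationError

#: per-transect proportion sums within 1 ± this tolerance are renormalized
SUM_TOLERANCE = 0.05

__all__ = ["read_sst", "read_benthic", "read_belt", "read_logger", "assign_periods"]


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}", column=missing[0])


def _parse_dates(df: pd.DataFrame, col: str, path):
    try:
        return pd.to_datetime(df[col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable date in column '{col}': {exc}", column=col)


def _clean_site(series: pd.Series) -> pd.Series:
    # free-string site names: trim; matching elsewhere is case-insensitive
    return series.astype(str).str.strip()


def read_sst(path) -> pd.Series:
    """Daily SST series from a (date, sst_c) CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "sst_c"], path)
    dates = _parse_dates(df, "date", path)
    s = pd.Series(df["sst_c"].to_numpy(dtype=float), index=pd.DatetimeIndex(dates), name="sst_c")
    s = s.dropna().sort_index()
    if s.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate dates", column="date")
    return s


def read_benthic(path, categories=None) -> pd.DataFrame:
    """Long-format benthic cover table; proportions validated and, when a
    transect's categories sum to 1 ± 0.05, renormalized to exactly 1."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "date", "transect", "category", "proportion"], path)
    df = df.copy()
    df["site"] = _clean_site(df["site"])
    df["date"] = _parse_dates(df, "date", path).dt.normalize()
    df["proportion"] = df["proportion"].astype(float)
    bad = df.index[(df["proportion"] < 0) | (df["proportion"] > 1)]
    if len(bad):
        raise ValidationError(
            f"{path}: proportion outside [0, 1]", row=int(bad[0]), column="proportion"
        )
    if categories is not None:
        unknown = set(df["category"]) - set(categories)
        if unknown:
            raise ValidationError(
                f"{path}: unknown benthic category(s) {sorted(unknown)}", column="category"
            )
    sums = df.groupby(["site", "date", "transect"])["proportion"].transform("sum")
    off = (sums - 1.0).abs()
    if (off > SUM_TOLERANCE).any():
        row = int(off.idxmax())
        raise ValidationError(
            f"{path}: transect proportions sum to {sums.iloc[row]:.3f} (tolerance {SUM_TOLERANCE})",
            row=row,
            column="proportion",
        )
    needs_renorm = (off > 1e-9) & (sums > 0)
    if needs_renorm.any():
        warnings.warn(
            f"{path}: renormalized {int(df.loc[needs_renorm].groupby(['site', 'date', 'transect']).ngroups)} "
            "transect(s) whose proportions did not sum to 1"
        )
        df.loc[needs_renorm, "proportion"] = (
            df.loc[needs_renorm, "proportion"] / sums[needs_renorm]
        )
    return df


def read_belt(path, taxa=None) -> pd.DataFrame:
    """Belt-transect colony counts by taxon and health state."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "date", "transect", "taxon", "health_state", "count"], path)
    df = df.copy()
    df["site"] = _clean_site(df["site"])
    df["date"] = _parse_dates(df, "date", path).dt.normalize()
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0])
        raise ValidationError(f"{path}: negative count", row=row, column="count")
    badstate = set(df["health_state"]) - set(HEALTH_STATES)
    if badstate:
        raise ValidationError(
            f"{path}: unknown health state(s) {sorted(badstate)}", column="health_state"
        )
    if taxa is not None:
        unknown = set(df["taxon"]) - set(taxa)
        if unknown:
            raise ValidationError(f"{path}: unknown taxon/taxa {sorted(unknown)}", column="taxon")
    return df


def read_logger(path) -> pd.DataFrame:
    """Sub-daily logger records (site, datetime, temp_c); timestamps keep time-of-day."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "datetime", "temp_c"], path)
    df = df.copy()
    df["site"] = _clean_site(df["site"])
    df["datetime"] = _parse_dates(df, "datetime", path)
    df["temp_c"] = df["temp_c"].astype(float)
    if not np.isfinite(df["temp_c"]).all():
        raise ValidationError(f"{path}: non-finite temperature", column="temp_c")
    return df


def assign_periods(benthic: pd.DataFrame, windows: dict) -> pd.DataFrame:
    """Pivot a long benthic table to a wide community matrix with a
    ``period`` label per sample.

    ``windows`` maps period name → (start, end) date. Samples outside all
    windows are dropped; overlapping windows are rejected.
    """
    items = sorted(windows.items())
    spans = []
    for name, (start, end) in items:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if end < start:
            raise ValidationError(f"window '{name}' ends before it starts")
        spans.append((name, start, end))
    for i, (na, sa, ea) in enumerate(spans):
        for nb, sb, eb in spans[i + 1:]:
            if sa <= eb and sb <= ea:
                raise ValidationError(f"windows '{na}' and '{nb}' overlap")

    df = benthic.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["period"] = None
    for name, start, end in spans:
        inside = (df["date"] >= start) & (df["date"] <= end)
        df.loc[inside, "period"] = name
    df = df[df["period"].notna()]
    wide = df.pivot_table(
        index=["site", "date", "transect", "period"],
        columns="category",
        values="proportion",
        aggfunc="mean",
    ).reset_index()
    wide.columns.name = None
    return wide
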