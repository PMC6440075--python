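"""Reading, validating and writing daily region series as CSV.

The on-disk dialect is comma-separated UTF-8 with ISO-8601 dates and header

    date,deaths,tmean,tmin,tmax,dow,holiday,pop

``dow`` (0 = Monday), ``holiday`` and the season label can be reconstructed
from the date and are filled in when absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import add_calendar_columns, season_of_month

__all__ = ["read_region_csv", "write_region_csv", "validate_region"]

CSV_COLUMNS = ["date", "deaths", "tmean", "tmin", "tmax", "dow", "holiday", "pop"]


class RegionDataError(ValueError):
    """Raised when a region series violates its structural invariants."""


def validate_region(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a daily region series.

    Checks: required columns, parseable strictly increasing daily dates
    without gaps, non-negative deaths, and tmin <= tmean <= tmax wherever
    all three are present.  Returns a copy with calendar columns filled.
    """
    missing = [c for c in ("date", "deaths", "tmean") if c not in frame.columns]
    if missing:
        raise RegionDataError(f"missing required columns: {missing}")
    frame = frame.copy()
    try:
        dates = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise RegionDataError(f"unparseable dates: {exc}") from exc
    if len(dates) > 1:
        deltas = dates.diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            raise RegionDataError("dates must be strictly increasing")
        gaps = deltas[deltas != pd.Timedelta(days=1)]
        if len(gaps):
            where = dates[gaps.index].dt.date.tolist()[:5]
            raise RegionDataError(f"date gaps before: {where}")
    frame["date"] = dates
    deaths = frame["deaths"].to_numpy(dtype=float)
    finite = deaths[~np.isnan(deaths)]
    if (finite < 0).any():
        raise RegionDataError("negative death counts present")
    if not np.allclose(finite, np.round(finite)):
        raise RegionDataError("death counts must be integers")
    if {"tmin", "tmax"} <= set(frame.columns):
        t = frame[["tmin", "tmean", "tmax"]].to_numpy(dtype=float)
        complete = ~np.isnan(t).any(axis=1)
        bad = complete & ((t[:, 0] > t[:, 1]) | (t[:, 1] > t[:, 2]))
        if bad.any():
            rows = frame.loc[bad, "date"].dt.date.tolist()[:5]
            raise RegionDataError(f"tmin <= tmean <= tmax violated on: {rows}")
    if "dow" not in frame.columns or "holiday" not in frame.columns:
        keep_hol = frame["holiday"] if "holiday" in frame.columns else None
        frame = add_calendar_columns(frame)
        if keep_hol is not None:
            frame["holiday"] = keep_hol.astype(int)
    else:
        frame["season"] = season_of_month(frame["date"].dt.month.to_numpy())
    if "pop" not in frame.columns:
        frame["pop"] = 1.0
    return frame


def read_region_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a region series CSV."""
    frame = pd.read_csv(path)
    return validate_region(frame)


def write_region_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a region series with the canonical column order and ISO dates."""
    out = frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in CSV_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)
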