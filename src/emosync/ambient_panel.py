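"""City × two-hour-period ambient emotion panels.

The unit of measurement is one tweet; the unit of analysis is a (city,
period) cell.  Each scored measure is first standardized *within user* so
that variation in who tweets when cannot drive spurious co-movement, then
averaged over all tweets by a city's residents in each two-hour bin.  Cells
with fewer than ``min_tweets`` tweets (default 50) are dropped from analysis
but kept in the table with their tweet counts.

Periods index the study month: ``t = (day_of_month - 1) * 12 +
floor(local_hour / 2)``, so a 30-day month has periods 0..359.  Binning uses
one configured local timezone for every city (the study region spans a
single zone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lexicon_scoring import MEASURES

__all__ = ["StudyWindow", "OutOfWindowError", "assign_period",
           "assign_periods", "user_standardize", "build_panel"]

logger = logging.getLogger(__name__)

PERIODS_PER_DAY = 12  # two-hour bins


class OutOfWindowError(ValueError):
    """Raised for a timestamp outside the configured study window."""


@dataclass(frozen=True)
class StudyWindow:
    """Calendar month and timezone that define the period grid."""

    year: int = 2021
    month: int = 9
    days: int = 30
    timezone: str = "America/New_York"

    @property
    def n_periods(self) -> int:
        return self.days * PERIODS_PER_DAY

    def localize(self, ts: pd.Series | pd.Timestamp):
        """Interpret naive timestamps as study-local; convert aware ones."""
        if isinstance(ts, pd.Timestamp):
            return ts.tz_localize(self.timezone) if ts.tz is None \
                else ts.tz_convert(self.timezone)
        if ts.dt.tz is None:
            return ts.dt.tz_localize(self.timezone)
        return ts.dt.tz_convert(self.timezone)


def assign_period(ts: pd.Timestamp, window: StudyWindow = StudyWindow()) -> int:
    """Two-hour-period index of one timestamp; raises if out of window."""
    loc = window.localize(pd.Timestamp(ts))
    if loc.year != window.year or loc.month != window.month \
            or not (1 <= loc.day <= window.days):
        raise OutOfWindowError(f"timestamp {ts} outside study window")
    return (loc.day - 1) * PERIODS_PER_DAY + loc.hour // 2


def assign_periods(ts: pd.Series, window: StudyWindow = StudyWindow()
                   ) -> pd.Series:
    """Vectorized period assignment; out-of-window rows get <NA> (counted)."""
    loc = window.localize(pd.to_datetime(ts))
    ok = (loc.dt.year == window.year) & (loc.dt.month == window.month) \
        & (loc.dt.day <= window.days)
    period = (loc.dt.day - 1) * PERIODS_PER_DAY + loc.dt.hour // 2
    out = period.astype("Int64").where(ok)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d timestamps outside the study window", n_bad)
    return out


def user_standardize(scored: pd.DataFrame,
                     measures: tuple[str, ...] = MEASURES,
                     user_col: str = "user_id") -> pd.DataFrame:
    """Replace each measure by its within-user z-score.

    z = (x - mean_u) / sd_u with the user's mean and sample sd (n-1
    denominator) over all of that user's tweets in the study window.  Users
    with fewer than two tweets, or with zero variance in a measure,
    contribute z = 0 for that measure so that cell means stay defined.
    """
    out = scored.copy()
    g = out.groupby(user_col, sort=False)[list(measures)]
    mu = g.transform("mean")
    sd = g.transform("std")  # ddof=1; NaN for single-tweet users
    x = out[list(measures)].astype(float)
    z = (x - mu) / sd
    z = z.where(sd > 0, 0.0).fillna(0.0)
    out[list(measures)] = z
    return out


def build_panel(scored: pd.DataFrame,
                window: StudyWindow = StudyWindow(),
                min_tweets: int = 50,
                measures: tuple[str, ...] = MEASURES,
                cities: tuple[str, ...] | None = None,
                period_col: str = "period") -> pd.DataFrame:
    """Average user-standardized scores to a city × period ambient panel.

    ``scored`` must carry ``city``, the measure columns (already
    user-standardized) and either a precomputed ``period`` column or a
    ``timestamp`` column to bin.  Returns the full (city × period) grid with
    columns ``n_tweets``, ``retained`` and one column per measure; measure
    values are NaN in cells that fail the ``min_tweets`` retention filter.
    """
    df = scored
    if period_col not in df.columns:
        df = df.copy()
        df[period_col] = assign_periods(df["timestamp"], window)
        df = df.dropna(subset=[period_col])
        df[period_col] = df[period_col].astype(int)
    if cities is None:
        cities = tuple(sorted(df["city"].unique()))
    if df.empty:
        logger.warning("building panel from an empty tweet table")

    grid = pd.MultiIndex.from_product(
        [cities, range(window.n_periods)], names=["city", "period"])
    grouped = df.groupby(["city", period_col], sort=True)
    means = grouped[list(measures)].mean().reindex(grid)
    n = grouped.size().reindex(grid, fill_value=0)

    panel = means
    panel["n_tweets"] = n.astype(int)
    panel["retained"] = panel["n_tweets"] >= min_tweets
    panel.loc[~panel["retained"], list(measures)] = np.nan
    logger.info("panel: %d cells, %d retained (min_tweets=%d)",
                len(panel), int(panel["retained"].sum()), min_tweets)
    return panel.reset_index()
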