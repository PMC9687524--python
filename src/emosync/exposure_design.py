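"""Assembly of the estimation tables for the contagion models.

For each measure the regression row for city i at period t carries:

* ``S`` — the city's ambient measure at t (dependent variable);
* ``S_lag`` — the same measure at t-1;
* ``MED_lag`` — the *mean degree-weighted* measure: the contact-weighted
  average of the six other cities' values at t-1, weights being the contact
  levels C_ij,t-1;
* ``CONT_lag`` — city i's total contact with all other cities at t-1,
  z-scored over the estimation sample;
* ``tweet_volume`` — log tweet count of the (i, t) cell, centered and scaled
  within city.

A row exists only when the (i, t) and (i, t-1) panel cells both pass the
retention filter and at least one partner city is retained at t-1.  The ten
emotions can be stacked long-form (one row per city × period × emotion) for
pooled estimation, in full or by grouping: positive = {joy, trust,
positive}, negative = {anger, disgust, sadness, negative}, tense =
{anticipation, fear, surprise}.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ambient_panel import PERIODS_PER_DAY
from .lexicon_scoring import EMOTIONS
from .mobility_contact import ContactSeries

__all__ = ["GROUPINGS", "mean_degree_weighted", "med_matrix",
           "standardize_covariates", "assemble_estimation_table",
           "build_long_form"]

logger = logging.getLogger(__name__)

#: Emotion groupings used for pooled estimation.
GROUPINGS: dict[str, tuple[str, ...]] = {
    "positive": ("joy", "trust", "positive"),
    "negative": ("anger", "disgust", "sadness", "negative"),
    "tense": ("anticipation", "fear", "surprise"),
    "all": EMOTIONS,
}


def _panel_matrices(panel: pd.DataFrame, measure: str, cities: tuple):
    """Pivot a panel to (n_cities, T) value / count matrices."""
    idx = panel.set_index(["city", "period"])
    T = int(panel["period"].max()) + 1
    grid = pd.MultiIndex.from_product([cities, range(T)])
    vals = idx[measure].reindex(grid).to_numpy().reshape(len(cities), T)
    n = idx["n_tweets"].reindex(grid, fill_value=0) \
        .to_numpy().reshape(len(cities), T)
    return vals, n


def med_matrix(values: np.ndarray, cs: ContactSeries) -> tuple[np.ndarray,
                                                               np.ndarray]:
    """Mean degree-weighted measure for every (city, period).

    ``values`` is the (n_cities, T) ambient matrix with NaN in non-retained
    cells.  Returns ``(med, fallback)`` where ``med[i, t]`` is the weighted
    average of the retained partner values at t with weights C_ijt, and
    ``fallback[i, t]`` marks cells where all weights were zero and the
    unweighted mean of retained partners was used instead.  Cells with no
    retained partner are NaN.
    """
    n, T = values.shape
    W = cs.values[:, :, :T]
    mask = ~np.isnan(values)  # (n, T)
    X = np.where(mask, values, 0.0)
    wm = W * mask[None, :, :]
    num = np.einsum("ijt,jt->it", wm, X)
    den = wm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        med = num / den
    # partners exclude the city itself even in the unweighted fallback
    pmask = mask[None, :, :].repeat(n, axis=0)
    ii = np.arange(n)
    pmask[ii, ii, :] = False
    n_partners = pmask.sum(axis=1)
    fallback = (den == 0) & (n_partners > 0)
    if fallback.any():
        unweighted = np.einsum("ijt,jt->it", pmask.astype(float), X)
        med = np.where(fallback, unweighted / np.maximum(n_partners, 1), med)
        logger.info("MED fallback to unweighted mean in %d cells",
                    int(fallback.sum()))
    med = np.where(n_partners == 0, np.nan, med)
    return med, fallback


def mean_degree_weighted(panel: pd.DataFrame, cs: ContactSeries, i, t: int,
                         measure: str) -> float:
    """Scalar MED for one city/period; NaN when no partner is retained."""
    values, _ = _panel_matrices(panel, measure, cs.cities)
    med, _ = med_matrix(values, cs)
    return float(med[cs.index(i), t])


def standardize_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Scale the regression covariates on the estimation sample.

    ``CONT_lag`` is z-scored with the global sample mean and sd;
    ``tweet_volume`` (log tweet count) is centered and scaled within city.
    Zero-variance columns become all zeros with a warning.
    """
    out = table.copy()
    c = out["CONT_lag"].to_numpy(dtype=float)
    sd = c.std(ddof=1) if len(c) > 1 else 0.0
    if sd > 0:
        out["CONT_lag"] = (c - c.mean()) / sd
    else:
        logger.warning("CONT_lag has zero variance; set to 0")
        out["CONT_lag"] = 0.0

    def _city_z(x: pd.Series) -> pd.Series:
        s = x.std(ddof=1)
        if not s > 0:
            return pd.Series(0.0, index=x.index)
        return (x - x.mean()) / s

    tv = out.groupby("city", sort=False)["tweet_volume"].transform(_city_z)
    if (out.groupby("city")["tweet_volume"].std(ddof=1).fillna(0) == 0).any():
        logger.warning("tweet_volume constant within some city; set to 0")
    out["tweet_volume"] = tv
    return out


def assemble_estimation_table(panel: pd.DataFrame, cs: ContactSeries,
                              measure: str,
                              standardize: bool = True) -> pd.DataFrame:
    """One-measure estimation table with DV at t and regressors at t-1.

    Rows cover every (city, t) with t >= 1 where both the t and t-1 cells
    are retained and MED at t-1 is defined.  Raises if no row survives.
    """
    cities = cs.cities
    values, counts = _panel_matrices(panel, measure, cities)
    T = values.shape[1]
    med, fb = med_matrix(values, cs)
    cont = cs.totals()[:, :T]

    rows = []
    for ci, city in enumerate(cities):
        ok = ~np.isnan(values[ci])
        for t in range(1, T):
            if not (ok[t] and ok[t - 1]) or np.isnan(med[ci, t - 1]):
                continue
            rows.append((city, t, measure, values[ci, t], values[ci, t - 1],
                         med[ci, t - 1], cont[ci, t - 1],
                         np.log(counts[ci, t]), bool(fb[ci, t - 1]),
                         t % PERIODS_PER_DAY))
    if not rows:
        raise ValueError(f"no estimable rows for measure {measure!r}: "
                         "panel and contact series share no usable periods")
    table = pd.DataFrame(rows, columns=[
        "city", "period", "emotion", "S", "S_lag", "MED_lag", "CONT_lag",
        "tweet_volume", "med_fallback", "hour_of_day"])
    return standardize_covariates(table) if standardize else table


def build_long_form(tables: dict, grouping: tuple[str, ...]) -> pd.DataFrame:
    """Stack per-emotion tables over a grouping's member emotions.

    All member tables must share the same (city, period) keys; the stacked
    table keeps the emotion label for fixed-effect construction, and has
    exactly (base rows) × (number of members) rows.
    """
    members = GROUPINGS.get(grouping, grouping) if isinstance(grouping, str) \
        else tuple(grouping)
    missing = [e for e in members if e not in tables]
    if missing:
        raise KeyError(f"no table for emotions {missing}")
    base_keys = None
    for e in members:
        keys = list(zip(tables[e]["city"], tables[e]["period"]))
        if base_keys is None:
            base_keys = keys
        elif keys != base_keys:
            raise ValueError(
                f"emotion {e!r} table keys differ from the base table; "
                "long-form stacking requires identical (city, period) keys")
    return pd.concat([tables[e] for e in members], ignore_index=True)
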