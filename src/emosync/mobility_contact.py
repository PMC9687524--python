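"""Inter-city contact estimated from POI visitation patterns.

Monthly POI records (in the style of aggregated mobility "patterns" data)
carry three marginals: the share of a POI's monthly visitors residing in
each city (``home_shares``), the POI's visitor totals by hour of day summed
over the month (``hourly_totals``, 24 values), and the share of the month's
visits falling on each day (``daily_shares``).  Hour-level contact between
residents of cities i and j at POI m on day l, hour k is the product

    C_ijklm = p_im * p_jm * V_km * P_lm

summed over POIs to a city-pair series, then aggregated to two-hour periods
by summing adjacent hours (matching the ambient panel's bin convention).
The formula is implemented literally as stated, with V in visitor units and
P as a day share; :func:`implied_monthly_volume` reports the implied volume
per POI as a validation aid.  Self-contact (i = j) is excluded throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["POIPatterns", "ContactSeries", "poi_hour_contact",
           "pair_contact_series", "to_two_hour", "total_contact",
           "implied_monthly_volume", "read_patterns", "write_patterns"]

HOURS_PER_DAY = 24


@dataclass
class POIPatterns:
    """Monthly visitation marginals for one point of interest."""

    poi_id: str
    poi_city: str
    home_shares: dict  # city -> proportion of monthly visitors residing there
    hourly_totals: np.ndarray  # 24 hour-of-day visitor totals over the month
    daily_shares: np.ndarray  # per-day visit proportions, summing to 1

    def __post_init__(self) -> None:
        self.hourly_totals = np.asarray(self.hourly_totals, dtype=float)
        self.daily_shares = np.asarray(self.daily_shares, dtype=float)
        if self.hourly_totals.shape != (HOURS_PER_DAY,):
            raise ValueError(f"POI {self.poi_id}: need 24 hourly totals")
        if (self.hourly_totals < 0).any():
            raise ValueError(f"POI {self.poi_id}: negative hourly totals")
        if sum(self.home_shares.values()) > 1 + 1e-9:
            raise ValueError(f"POI {self.poi_id}: home shares sum above 1")
        if abs(self.daily_shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"POI {self.poi_id}: daily shares must sum to 1")


@dataclass
class ContactSeries:
    """Symmetric city-pair contact at two-hour resolution.

    ``values[i, j, t]`` is the contact between cities ``cities[i]`` and
    ``cities[j]`` in period ``t``; the diagonal is zero by construction
    (self-contact is not part of the analysis).
    """

    cities: tuple
    values: np.ndarray = field(repr=False)  # (n_cities, n_cities, n_periods)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[0] != v.shape[1] \
                or v.shape[0] != len(self.cities):
            raise ValueError("contact array shape mismatch")
        if (v < 0).any():
            raise ValueError("contact values must be non-negative")
        if not np.allclose(v, v.transpose(1, 0, 2)):
            raise ValueError("contact must be symmetric in the city pair")

    @property
    def n_periods(self) -> int:
        return self.values.shape[2]

    def index(self, city) -> int:
        return self.cities.index(city)

    def get(self, i, j, t: int) -> float:
        return float(self.values[self.index(i), self.index(j), t])

    def totals(self) -> np.ndarray:
        """CONT_it = sum over partners j != i, as an (n_cities, T) array."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV-friendly form with one row per unordered pair/period."""
        n = len(self.cities)
        rows = []
        for a in range(n):
            for b in range(a + 1, n):
                for t in range(self.n_periods):
                    rows.append((self.cities[a], self.cities[b], t,
                                 self.values[a, b, t]))
        return pd.DataFrame(rows, columns=["city_i", "city_j", "period",
                                           "contact"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   cities: tuple | None = None) -> "ContactSeries":
        if cities is None:
            cities = tuple(sorted(set(df["city_i"]) | set(df["city_j"])))
        n_periods = int(df["period"].max()) + 1
        values = np.zeros((len(cities), len(cities), n_periods))
        idx = {c: k for k, c in enumerate(cities)}
        a = df["city_i"].map(idx).to_numpy()
        b = df["city_j"].map(idx).to_numpy()
        t = df["period"].to_numpy(dtype=int)
        values[a, b, t] = df["contact"].to_numpy(dtype=float)
        values[b, a, t] = df["contact"].to_numpy(dtype=float)
        return cls(tuple(cities), values)


def poi_hour_contact(poi: POIPatterns, i, j, day: int, hour: int) -> float:
    """Contact between residents of i and j at one POI, day and hour.

    ``day`` is a 0-based day-of-month index into ``daily_shares``; ``hour``
    is the 0-based hour of day.
    """
    if i == j:
        raise ValueError("self-contact (i == j) is not defined")
    p_i = poi.home_shares.get(i, 0.0)
    p_j = poi.home_shares.get(j, 0.0)
    return p_i * p_j * poi.hourly_totals[hour] * poi.daily_shares[day]


def pair_contact_series(pois, cities: tuple, days: int) -> np.ndarray:
    """Hour-level contact summed over POIs.

    Returns an array of shape (n_cities, n_cities, days, 24); entries for
    pairs with no shared POI visitors are 0, and the diagonal is 0.
    """
    n = len(cities)
    H = np.zeros((n, n, days, HOURS_PER_DAY))
    for poi in pois:
        if poi.daily_shares.shape != (days,):
            raise ValueError(
                f"POI {poi.poi_id}: daily shares cover "
                f"{poi.daily_shares.size} days, calendar has {days}")
        p = np.array([poi.home_shares.get(c, 0.0) for c in cities])
        pair = np.outer(p, p)
        time = np.outer(poi.daily_shares, poi.hourly_totals)
        H += pair[:, :, None, None] * time[None, None, :, :]
    ii = np.arange(n)
    H[ii, ii] = 0.0
    return H


def to_two_hour(hourly: np.ndarray, cities: tuple) -> ContactSeries:
    """Sum adjacent one-hour values into the 2-hour period grid."""
    n, n2, days, hours = hourly.shape
    if hours != HOURS_PER_DAY:
        raise ValueError("hour axis must have 24 entries")
    values = hourly.reshape(n, n2, days * HOURS_PER_DAY // 2, 2).sum(axis=3)
    return ContactSeries(tuple(cities), values)


def total_contact(cs: ContactSeries, i, t: int) -> float:
    """CONT_it: city i's summed contact with every other city at period t."""
    return float(cs.values[cs.index(i), :, t].sum())


def implied_monthly_volume(pois) -> pd.DataFrame:
    """Validation report: visitor volume each POI's marginals imply.

    The literal product formula spreads the month-total hourly profile over
    days via the day shares, so the implied monthly volume is
    sum_k V_km * sum_l P_lm = sum_k V_km; the report makes this visible so
    users can judge the units of their patterns files.
    """
    rows = [(p.poi_id, p.poi_city, float(p.hourly_totals.sum()),
             float(sum(p.home_shares.values()))) for p in pois]
    return pd.DataFrame(rows, columns=["poi_id", "poi_city",
                                       "implied_monthly_volume",
                                       "in_region_share"])


def write_patterns(pois, path) -> None:
    """Write POI patterns as CSV with JSON-encoded array fields."""
    rows = [{
        "poi_id": p.poi_id,
        "poi_city": p.poi_city,
        "home_shares": json.dumps(p.home_shares, sort_keys=True),
        "hourly_totals": json.dumps(list(p.hourly_totals)),
        "daily_shares": json.dumps(list(p.daily_shares)),
    } for p in pois]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_patterns(path) -> list:
    df = pd.read_csv(path, dtype={"poi_id": str, "poi_city": str})
    return [POIPatterns(
        poi_id=r.poi_id,
        poi_city=r.poi_city,
        home_shares=json.loads(r.home_shares),
        hourly_totals=np.array(json.loads(r.hourly_totals)),
        daily_shares=np.array(json.loads(r.daily_shares)),
    ) for r in df.itertuples()]
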