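"""Synthetic corpus generator with a planted contagion coefficient.

Real inputs of this kind (geocoded tweets, commercial POI mobility
patterns) are restricted, so the pipeline's test surface is a fully
synthetic data-generating process that mirrors the assumed structure of the
analysis end to end:

* **Mobility** — POIs with home-city visitor shares drawn from a Dirichlet
  whose concentration controls cross-city mixing, a diurnal 24-hour
  popularity profile, and day shares summing to one.
* **Latent ambient emotion** — for each of the 11 measures, a city-level
  panel generated by the forward recursion

      S_it = b1 S_i,t-1 + b2 MED_i,t-1 + b3 CONT_i,t-1
             + b4 MED_i,t-1 CONT_i,t-1 + D_t + e_it

  with MED computed from the generated contact weights, CONT the z-scored
  total contact, D_t a common period shock, and a burn-in discarded so
  initial conditions do not leak into recovery experiments.  b4 is the
  planted contagion coefficient the pipeline should recover.
* **Tweets** — users nested in cities with heterogeneous Poisson tweeting
  rates (diurnal profile) and heterogeneous baseline word usage, which the
  pipeline's user standardization must remove.  Each tweet is a small bag
  of lexicon words: one graded valence word tracking the city-period latent
  sentiment plus per-user offset and noise, emotion words included with
  probability clamp(p0 + gamma * latent, 0.01, 0.99), filler words, and
  occasional mentions/URLs to exercise tokenization.

Everything is reproducible: a fixed seed yields a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ambient_panel import (PERIODS_PER_DAY, StudyWindow, build_panel,
                            user_standardize)
from .exposure_design import assemble_estimation_table
from .fe_estimation import FitResult, ModelSpec, ols_with_absorption
from .lexicon_scoring import (EMOTIONS, MEASURES, EmotionLexicon,
                              ValenceLexicon, score_tweets)
from .mobility_contact import (ContactSeries, POIPatterns,
                               pair_contact_series, to_two_hour)

__all__ = ["SynthConfig", "LatentPanel", "HAMPTON_ROADS",
           "generate_mobility", "generate_contact", "generate_latent_panel",
           "generate_tweets", "synthetic_lexicons", "single_pipeline_run",
           "recovery_experiment"]

#: The seven adjacent cities of the study region, used as default labels.
HAMPTON_ROADS: tuple[str, ...] = (
    "chesapeake", "hampton", "newport_news", "norfolk", "portsmouth",
    "suffolk", "virginia_beach")

_FILLERS = np.array(["lorem", "ipsum", "dolor", "amet", "tempor", "aliqua"])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the data-generating process.

    The defaults describe the reference study conditions: 7 cities over a
    30-day month (360 two-hour periods), 150 users per city, and a planted
    interaction coefficient ``beta4`` of 0.5 with lag ``beta1`` 0.3.
    """

    n_cities: int = 7
    users_per_city: int = 150
    days: int = 30
    year: int = 2021
    month: int = 9
    timezone: str = "America/New_York"
    city_labels: tuple[str, ...] | None = None
    # tweeting process
    tweet_rate: float = 0.6       # mean tweets per user per two-hour period
    diurnal_amplitude: float = 0.3
    activity_sd: float = 0.5      # lognormal sd of per-user rate multiplier
    # latent recursion coefficients
    beta1: float = 0.3
    beta2: float = 0.1
    beta3: float = 0.0
    beta4: float = 0.5
    period_sd: float = 0.05       # sd of the common period shock D_t
    noise_sd: float = 0.8         # sd of the idiosyncratic innovation e_it
    # word-emission model
    p0: float = 0.2               # baseline emotion-word inclusion probability
    gamma: float = 0.3            # emission slope on the latent value
    p0_user_sd: float = 0.05      # per-user baseline offset (heterogeneity)
    valence_user_sd: float = 0.3
    valence_noise_sd: float = 0.5
    valence_step: float = 0.25    # grading of the synthetic valence lexicon
    valence_max: float = 4.0
    # POI mobility process
    n_pois: int = 60
    mixing: float = 5.0           # Dirichlet concentration on the home city
    out_of_region: float = 0.1    # visitor share from outside the region
    poi_diurnal: float = 0.6
    poi_volume_sigma: float = 1.0
    day_concentration: float = 50.0
    # simulation plumbing
    burn_in: int = 24             # discarded leading periods
    min_tweets: int = 50          # retention filter handed to the pipeline
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.beta1) >= 1:
            raise ValueError("latent recursion requires |beta1| < 1")
        if self.city_labels is not None \
                and len(self.city_labels) != self.n_cities:
            raise ValueError("city_labels length must equal n_cities")

    @property
    def cities(self) -> tuple[str, ...]:
        if self.city_labels is not None:
            return self.city_labels
        if self.n_cities == 7:
            return HAMPTON_ROADS
        return tuple(f"city{i:02d}" for i in range(self.n_cities))

    @property
    def n_periods(self) -> int:
        return self.days * PERIODS_PER_DAY

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.year, self.month, self.days, self.timezone)


@dataclass(frozen=True)
class LatentPanel:
    """City-period latent values per measure, plus the contact inputs used."""

    measures: tuple[str, ...]
    cities: tuple[str, ...]
    values: np.ndarray  # (n_measures, n_cities, n_periods), burn-in removed
    cont_z: np.ndarray  # (n_cities, n_periods)


def _rng(cfg: SynthConfig, rng: np.random.Generator | None
         ) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def generate_mobility(cfg: SynthConfig,
                      rng: np.random.Generator | None = None
                      ) -> list[POIPatterns]:
    """Draw a POI collection with configurable cross-city mixing.

    Each POI's home-share vector is Dirichlet with concentration
    ``cfg.mixing`` on the POI's own city and 1 elsewhere, scaled down by the
    out-of-region visitor share; hourly totals follow a day-peaked profile
    scaled by a lognormal monthly volume; day shares are a near-uniform
    Dirichlet summing to one.
    """
    rng = _rng(cfg, rng)
    n = cfg.n_cities
    hours = np.arange(24)
    profile = 1.0 + cfg.poi_diurnal * np.cos(2 * np.pi * (hours - 15) / 24)
    profile = np.clip(profile, 0.0, None)
    profile /= profile.sum()
    pois = []
    for m in range(cfg.n_pois):
        home_city = int(rng.integers(n))
        alpha = np.ones(n)
        alpha[home_city] = cfg.mixing
        shares = rng.dirichlet(alpha) * (1.0 - cfg.out_of_region)
        volume = float(rng.lognormal(np.log(2000.0), cfg.poi_volume_sigma))
        pois.append(POIPatterns(
            poi_id=f"poi{m:04d}",
            poi_city=cfg.cities[home_city],
            home_shares={c: float(s) for c, s in zip(cfg.cities, shares)},
            hourly_totals=volume * profile,
            daily_shares=rng.dirichlet(
                np.full(cfg.days, cfg.day_concentration)),
        ))
    return pois


def generate_contact(cfg: SynthConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[list[POIPatterns], ContactSeries]:
    """Convenience: mobility patterns plus their two-hour contact series."""
    rng = _rng(cfg, rng)
    pois = generate_mobility(cfg, rng)
    hourly = pair_contact_series(pois, cfg.cities, cfg.days)
    return pois, to_two_hour(hourly, cfg.cities)


def generate_latent_panel(cfg: SynthConfig, contact: ContactSeries,
                          rng: np.random.Generator | None = None,
                          init: np.ndarray | None = None) -> LatentPanel:
    """Run the planted-coefficient recursion forward over the month.

    Contact weights for MED are the period's pair contacts normalized per
    city (uniform over partners where a city has zero contact); CONT is the
    z-scored total contact over the study window.  The first ``burn_in``
    periods reuse the opening periods' contact and are discarded.
    """
    rng = _rng(cfg, rng)
    n, T = cfg.n_cities, cfg.n_periods
    if contact.values.shape != (n, n, T):
        raise ValueError("contact series does not match the configured grid")
    b = cfg.burn_in

    totals = contact.totals()  # (n, T)
    sd = totals.std(ddof=1)
    cont_z = (totals - totals.mean()) / sd if sd > 0 else np.zeros_like(totals)

    C_ext = np.concatenate([contact.values[:, :, :b], contact.values], axis=2)
    cz_ext = np.concatenate([cont_z[:, :b], cont_z], axis=1)
    row = C_ext.sum(axis=1, keepdims=True)
    W = np.divide(C_ext, row, out=np.zeros_like(C_ext), where=row > 0)
    uniform = (np.ones((n, n)) - np.eye(n)) / (n - 1)
    zero_rows = (row[:, 0, :] == 0)
    if zero_rows.any():
        for t in range(W.shape[2]):
            W[zero_rows[:, t], :, t] = uniform[zero_rows[:, t]]

    n_meas = len(MEASURES)
    total_T = b + T
    delta = rng.normal(0.0, cfg.period_sd, size=(n_meas, total_T))
    eps = rng.normal(0.0, cfg.noise_sd, size=(n_meas, n, total_T))
    S = np.zeros((n_meas, n, total_T))
    if init is not None:
        S[:, :, 0] = np.broadcast_to(init, (n_meas, n))
    for t in range(1, total_T):
        prev = S[:, :, t - 1]
        med = prev @ W[:, :, t - 1].T
        cz = cz_ext[:, t - 1]
        S[:, :, t] = (cfg.beta1 * prev
                      + (cfg.beta2 + cfg.beta4 * cz)[None, :] * med
                      + cfg.beta3 * cz[None, :]
                      + delta[:, t][:, None] + eps[:, :, t])
        if np.abs(S[:, :, t]).max() > 1e6:
            raise ValueError("latent recursion diverged; the configured "
                             "coefficients are not stable for this contact "
                             "series")
    return LatentPanel(MEASURES, cfg.cities, S[:, :, b:], cont_z)


def synthetic_lexicons(cfg: SynthConfig
                       ) -> tuple[ValenceLexicon, EmotionLexicon]:
    """The lexicons the generator emits words from.

    Valence words form a grade ladder ``val00 .. valNN`` spanning
    [-valence_max, +valence_max] in steps of ``valence_step``; each emotion
    has a single signature word ``<emotion>word``.
    """
    grades = _valence_grades(cfg)
    vlex = ValenceLexicon({f"val{i:02d}": float(g)
                           for i, g in enumerate(grades)})
    elex = EmotionLexicon({f"{e}word": frozenset({e}) for e in EMOTIONS})
    return vlex, elex


def _valence_grades(cfg: SynthConfig) -> np.ndarray:
    k = int(round(cfg.valence_max / cfg.valence_step))
    return np.arange(-k, k + 1) * cfg.valence_step


def generate_tweets(cfg: SynthConfig, latent: LatentPanel,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit the tweet corpus implied by a latent panel.

    Returns a DataFrame with columns ``user_id``, ``city``, ``timestamp``
    (timezone-aware) and ``text``.
    """
    rng = _rng(cfg, rng)
    n, T = cfg.n_cities, cfg.n_periods
    n_users = n * cfg.users_per_city
    user_city = np.repeat(np.arange(n), cfg.users_per_city)
    activity = rng.lognormal(-cfg.activity_sd ** 2 / 2, cfg.activity_sd,
                             size=n_users)
    val_offset = rng.normal(0.0, cfg.valence_user_sd, size=n_users)
    p0_offset = rng.normal(0.0, cfg.p0_user_sd, size=n_users)

    bins = np.arange(PERIODS_PER_DAY)
    diurnal = 1.0 + cfg.diurnal_amplitude * np.cos(
        2 * np.pi * (bins - 7.5) / PERIODS_PER_DAY)
    rate = (cfg.tweet_rate * activity[:, None]
            * diurnal[None, np.arange(T) % PERIODS_PER_DAY])
    counts = rng.poisson(rate)  # (n_users, T)

    flat = counts.ravel()
    cell = np.repeat(np.arange(n_users * T), flat)
    u = cell // T
    t = cell % T
    city = user_city[u]
    M = len(u)

    # one graded valence word per tweet, tracking latent sentiment
    s_lat = latent.values[0, city, t]
    val = s_lat + val_offset[u] + rng.normal(0.0, cfg.valence_noise_sd, M)
    grades = _valence_grades(cfg)
    gi = np.clip(np.rint((val + cfg.valence_max) / cfg.valence_step),
                 0, len(grades) - 1).astype(int)
    val_words = np.array([f"val{i:02d}" for i in range(len(grades))],
                         dtype=object)

    # emotion words: Bernoulli with clamped linear probability, encoded as a
    # 10-bit mask and rendered through a precomputed suffix table
    bits = np.zeros(M, dtype=np.int64)
    for mi, e in enumerate(EMOTIONS):
        lat = latent.values[1 + mi, city, t]
        p = np.clip(cfg.p0 + p0_offset[u] + cfg.gamma * lat, 0.01, 0.99)
        bits |= (rng.random(M) < p).astype(np.int64) << mi
    lut = np.empty(1 << len(EMOTIONS), dtype=object)
    for code in range(len(lut)):
        lut[code] = "".join(f" {e}word" for mi, e in enumerate(EMOTIONS)
                            if code >> mi & 1)

    # occasional noise tokens so tokenization is exercised on real clutter
    clutter = np.array(["", " @friend", " http://t.co/xyz",
                        " @friend http://t.co/xyz"], dtype=object)
    ci = ((rng.random(M) < 0.05).astype(np.int64)
          | ((rng.random(M) < 0.03).astype(np.int64) << 1))

    text = (_FILLERS[rng.integers(len(_FILLERS), size=M)].astype(object)
            + " " + val_words[gi] + lut[bits] + clutter[ci])

    start = pd.Timestamp(year=cfg.year, month=cfg.month, day=1,
                         tz=cfg.timezone)
    seconds = t * 7200 + rng.random(M) * 7200
    ts = start + pd.to_timedelta(seconds, unit="s")

    uids = np.array([f"u{k:05d}" for k in range(n_users)], dtype=object)
    return pd.DataFrame({
        "user_id": uids[u],
        "city": np.asarray(cfg.cities, dtype=object)[city],
        "timestamp": ts,
        "text": text,
    })


def single_pipeline_run(cfg: SynthConfig, seed: int,
                        measure: str = "sentiment") -> FitResult:
    """Generate a corpus and run the full pipeline up to the model-3 fit.

    One end-to-end realization: mobility -> contact -> latent panel ->
    tweets -> lexicon scoring -> user standardization -> ambient panel ->
    estimation table -> OLS with period fixed effects.  Returns the fit
    whose ``MED_x_CONT`` coefficient estimates the planted ``beta4``.
    """
    rng = np.random.default_rng(seed)
    run_cfg = replace(cfg, seed=seed)
    pois, contact = generate_contact(run_cfg, rng)
    latent = generate_latent_panel(run_cfg, contact, rng)
    tweets = generate_tweets(run_cfg, latent, rng)
    vlex, elex = synthetic_lexicons(run_cfg)
    emotions = () if measure == "sentiment" else (measure,)
    scored = score_tweets(tweets, vlex, elex, emotions=emotions)
    std = user_standardize(scored, measures=(measure,))
    panel = build_panel(std, window=run_cfg.window,
                        min_tweets=run_cfg.min_tweets, measures=(measure,),
                        cities=run_cfg.cities)
    table = assemble_estimation_table(panel, contact, measure)
    spec = ModelSpec(dv="S", regressors=("S_lag", "MED_lag", "CONT_lag",
                                         "MED_x_CONT"), fe=(("period",),))
    return ols_with_absorption(table, spec)


def recovery_experiment(planted: tuple[float, ...], n_reps: int,
                        cfg: SynthConfig | None = None, seed: int = 0,
                        alpha: float = 0.05,
                        measure: str = "sentiment") -> pd.DataFrame:
    """Monte-Carlo recovery of the planted interaction coefficient.

    For each planted ``beta4`` value, runs ``n_reps`` end-to-end pipeline
    realizations and reports the mean estimate, its Monte-Carlo standard
    error, the mean reported SE, and the two-sided rejection rate at
    ``alpha``.
    """
    cfg = cfg if cfg is not None else SynthConfig()
    master = np.random.default_rng(seed)
    rows = []
    for b4 in planted:
        cfg_b = replace(cfg, beta4=float(b4))
        est, rej, ses = [], [], []
        for _ in range(n_reps):
            rep_seed = int(master.integers(2 ** 31))
            fit = single_pipeline_run(cfg_b, rep_seed, measure=measure)
            est.append(fit.params["MED_x_CONT"])
            ses.append(fit.se["MED_x_CONT"])
            rej.append(fit.pvalues["MED_x_CONT"] < alpha)
        est = np.asarray(est)
        rows.append({
            "planted_beta4": float(b4),
            "n_reps": n_reps,
            "mean_estimate": est.mean(),
            "sd_estimate": est.std(ddof=1),
            "mc_se": est.std(ddof=1) / np.sqrt(n_reps),
            "mean_reported_se": float(np.mean(ses)),
            "reject_rate": float(np.mean(rej)),
        })
    return pd.DataFrame(rows)
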