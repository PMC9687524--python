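"""End-to-end orchestration: file formats, configuration, and the full run.

``run_pipeline`` executes score -> panel -> contact -> assemble -> fit for
general sentiment, the pooled 10-emotion long form, and the three emotion
groupings (positive, negative, tense), writing every intermediate table and
a JSON manifest of row counts, so each stage can be re-run from saved
artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ambient_panel import StudyWindow, build_panel, user_standardize
from .exposure_design import (GROUPINGS, assemble_estimation_table,
                              build_long_form)
from .fe_estimation import FitResult, fit_battery
from .lexicon_scoring import (EMOTIONS, MEASURES, EmotionLexicon,
                              ValenceLexicon, score_tweets)
from .mobility_contact import (ContactSeries, implied_monthly_volume,
                               pair_contact_series, read_patterns,
                               to_two_hour)

__all__ = ["PipelineConfig", "ConfigError", "read_tweets", "write_tweets",
           "read_panel", "write_panel", "write_fit_results", "run_pipeline"]

logger = logging.getLogger(__name__)

TWEET_COLUMNS = ["user_id", "city", "timestamp", "text"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad paths or values)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and options of one full pipeline run."""

    tweets: str
    valence_lexicon: str
    emotion_lexicon: str
    patterns: str
    output_dir: str
    cities: tuple[str, ...]
    year: int = 2021
    month: int = 9
    days: int = 30
    timezone: str = "America/New_York"
    min_tweets: int = 50
    se_type: str = "classical"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cities"] = tuple(raw["cities"])
        return cls(**raw)

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.year, self.month, self.days, self.timezone)

    def validate(self) -> None:
        if not self.cities:
            raise ConfigError("city list is empty")
        for name in ("tweets", "valence_lexicon", "emotion_lexicon",
                     "patterns"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def read_tweets(path) -> pd.DataFrame:
    """Read a tweet table (JSONL or CSV by extension) with parsed timestamps."""
    path = Path(path)
    if path.suffix in {".jsonl", ".json"}:
        df = pd.read_json(path, lines=True, dtype={"user_id": str},
                          convert_dates=False)
    else:
        df = pd.read_csv(path, dtype={"user_id": str})
    missing = [c for c in TWEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tweet file {path} lacks columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["text"] = df["text"].fillna("")
    return df[TWEET_COLUMNS]


def write_tweets(df: pd.DataFrame, path) -> None:
    """Write tweets as JSONL or CSV; ISO-8601 timestamps (round-trip stable)."""
    path = Path(path)
    out = df[TWEET_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda x: pd.Timestamp(x).isoformat())
    if path.suffix in {".jsonl", ".json"}:
        with open(path, "w") as fh:
            for rec in out.to_dict(orient="records"):
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        out.to_csv(path, index=False)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["retained"] = df["retained"].astype(bool)
    return df


def write_fit_results(results: list[FitResult], prefix: Path) -> None:
    """Write one battery: tidy coefficient CSV plus JSON fit summaries."""
    rows, summaries = [], []
    for m, res in enumerate(results, start=1):
        for term in res.params.index:
            rows.append({
                "model": m, "term": term,
                "estimate": res.params[term], "se": res.se[term],
                "p": res.pvalues[term],
                "stars": res.summary_frame().loc[term, "stars"],
            })
        summaries.append({
            "model": m, "n": res.n_obs, "k": res.k_params,
            "n_fe_levels": res.n_fe_levels, "loglik": res.loglik,
            "aic": res.aic, "bic": res.bic, "pseudo_r2": res.pseudo_r2,
            "se_type": res.spec.se_type,
            "fe": ["x".join(f) for f in res.spec.fe],
            "pseudo_r2_definition": "squared correlation of fitted "
                                    "(fixed effects included) with observed",
        })
    pd.DataFrame(rows).to_csv(f"{prefix}_coefficients.csv", index=False)
    with open(f"{prefix}_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)


def _filter_cities(tweets: pd.DataFrame, cities: tuple[str, ...]
                   ) -> tuple[pd.DataFrame, int]:
    ok = tweets["city"].isin(cities)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d tweets with unknown city", n_bad)
    return tweets[ok].reset_index(drop=True), n_bad


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``output_dir``.

    Produces the ambient panel, the contact series, per-measure estimation
    tables, the four long forms, and five fit-result sets (sentiment, all
    emotions pooled, positive, negative, tense groupings), plus a manifest
    of row counts.  Outputs are pure functions of (inputs, config).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    vlex = ValenceLexicon.from_tsv(cfg.valence_lexicon)
    elex = EmotionLexicon.from_tsv(cfg.emotion_lexicon)
    tweets = read_tweets(cfg.tweets)
    counts["tweets_read"] = len(tweets)
    tweets, counts["tweets_rejected_city"] = _filter_cities(tweets, cfg.cities)
    logger.info("scoring %d tweets", len(tweets))

    scored = score_tweets(tweets, vlex, elex)
    std = user_standardize(scored)
    panel = build_panel(std, window=cfg.window, min_tweets=cfg.min_tweets,
                        cities=cfg.cities)
    counts["panel_cells"] = len(panel)
    counts["panel_retained"] = int(panel["retained"].sum())
    write_panel(panel, out / "panel.csv")

    pois = read_patterns(cfg.patterns)
    if not pois:
        raise ValueError("patterns file contains no POIs; contact series "
                         "would be empty")
    hourly = pair_contact_series(pois, cfg.cities, cfg.days)
    contact = to_two_hour(hourly, cfg.cities)
    contact.to_frame().to_csv(out / "contact.csv", index=False)
    implied_monthly_volume(pois).to_csv(out / "poi_volume_report.csv",
                                        index=False)

    tables = {}
    for measure in MEASURES:
        tables[measure] = assemble_estimation_table(panel, contact, measure)
        tables[measure].to_csv(out / f"estimation_{measure}.csv", index=False)
        counts[f"rows_{measure}"] = len(tables[measure])
    emotion_tables = {e: tables[e] for e in EMOTIONS}

    fits: dict[str, list[FitResult]] = {}
    fits["sentiment"] = fit_battery(
        tables["sentiment"], base_fe=(("period",),),
        extra_fe=("city", "hour_of_day"), se_type=cfg.se_type)
    for name in ("all", "positive", "negative", "tense"):
        long_form = build_long_form(emotion_tables, GROUPINGS[name])
        long_form.to_csv(out / f"long_form_{name}.csv", index=False)
        counts[f"rows_long_{name}"] = len(long_form)
        fits[name] = fit_battery(
            long_form, base_fe=(("emotion", "period"),),
            extra_fe=("emotion", "city", "hour_of_day"), se_type=cfg.se_type)
    for name, results in fits.items():
        write_fit_results(results, out / f"fits_{name}")

    manifest = {"config": asdict(cfg), "version": __version__,
                "row_counts": counts,
                "numpy": np.__version__, "pandas": pd.__version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"panel": panel, "contact": contact, "tables": tables,
            "fits": fits, "manifest": manifest}
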