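"""Lexicon-based sentiment and emotion scoring of short texts.

Each text is scored two ways:

* a continuous *sentiment* score — the sum of signed valence weights of the
  tokens matched in a valence lexicon (each occurrence counted);
* ten *emotion* word counts against an emotion lexicon whose labels form the
  fixed NRC-style universe (anger, anticipation, disgust, fear, joy, sadness,
  surprise, trust, negative, positive), dichotomized to presence flags.

Lexicons are pluggable TSV files because widely used emotion lexicons cannot
be redistributed; a tiny built-in toy lexicon ships for tests and examples.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EMOTIONS",
    "MEASURES",
    "ValenceLexicon",
    "EmotionLexicon",
    "TweetScores",
    "tokenize",
    "tokenize_series",
    "score_valence",
    "count_emotions",
    "dichotomize",
    "score_tweet",
    "score_tweets",
    "toy_valence_lexicon",
    "toy_emotion_lexicon",
]

#: The ten emotion/sentiment categories, in canonical order.
EMOTIONS: tuple[str, ...] = (
    "anger",
    "anticipation",
    "disgust",
    "fear",
    "joy",
    "sadness",
    "surprise",
    "trust",
    "negative",
    "positive",
)

#: The eleven per-tweet measures carried through the pipeline.
MEASURES: tuple[str, ...] = ("sentiment",) + EMOTIONS

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Split a raw text into lowercase word tokens.

    URLs and @-mentions are removed entirely; a leading ``#`` is stripped but
    the hashtag word itself is kept; the remainder is lowercased and split on
    any run of non-alphanumeric characters.  No stemming and no negation
    handling are applied.
    """
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    return _TOKEN_RE.findall(text.lower())


def tokenize_series(texts: pd.Series) -> pd.Series:
    """Vectorized :func:`tokenize` over a Series of texts.

    Produces exactly the same token lists as calling :func:`tokenize` on each
    element (a property the test suite checks), but much faster on large
    corpora.
    """
    s = texts.fillna("").astype(object)
    # URL/mention stripping only touches texts that can contain them
    needs = s.str.contains(r"@|https?://|www\.", case=False, regex=True)
    if needs.any():
        sub = s[needs]
        sub = sub.str.replace(_URL_RE, " ", regex=True)
        sub = sub.str.replace(_MENTION_RE, " ", regex=True)
        s = s.copy()
        s[needs] = sub
    return s.str.lower().str.findall(_TOKEN_RE)


def _check_terms(terms: Iterable[str]) -> None:
    for t in terms:
        if t != t.lower():
            raise ValueError(f"lexicon term {t!r} is not lowercase")


@dataclass(frozen=True)
class ValenceLexicon:
    """Map from term to signed real valence weight."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_terms(self.entries)
        for t, w in self.entries.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight for term {t!r}")

    @classmethod
    def from_tsv(cls, path) -> "ValenceLexicon":
        """Read a ``term<TAB>weight`` TSV (UTF-8, no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "weight"],
                         dtype={"term": str}, comment=None)
        if df["term"].duplicated().any():
            dup = df.loc[df["term"].duplicated(), "term"].iloc[0]
            raise ValueError(f"duplicate lexicon term {dup!r} in {path}")
        return cls(dict(zip(df["term"], df["weight"].astype(float))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.entries.items())).to_csv(
            path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class EmotionLexicon:
    """Map from term to the subset of the ten emotion labels it evokes."""

    entries: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        _check_terms(self.entries)
        universe = set(EMOTIONS)
        for t, labels in self.entries.items():
            bad = set(labels) - universe
            if bad:
                raise ValueError(f"term {t!r} has unknown labels {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path) -> "EmotionLexicon":
        """Read a ``term<TAB>label`` TSV with one association per row."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "label"],
                         dtype=str)
        entries: dict[str, set] = {}
        for term, label in zip(df["term"], df["label"]):
            entries.setdefault(term, set()).add(label)
        return cls({t: frozenset(v) for t, v in entries.items()})

    def to_tsv(self, path) -> None:
        rows = [(t, lab) for t, labs in sorted(self.entries.items())
                for lab in sorted(labs)]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def term_sets(self) -> dict[str, frozenset]:
        """Inverse view: emotion label -> set of terms evoking it."""
        out: dict[str, set] = {e: set() for e in EMOTIONS}
        for t, labs in self.entries.items():
            for lab in labs:
                out[lab].add(t)
        return {e: frozenset(s) for e, s in out.items()}


@dataclass(frozen=True)
class TweetScores:
    """Scores for one text: continuous sentiment plus 10 emotion indicators."""

    sentiment: float
    emotion_counts: np.ndarray = field(repr=False)
    emotion_flags: np.ndarray = field(repr=False)


def score_valence(tokens: Iterable[str], lex: ValenceLexicon,
                  stat: str = "sum") -> float:
    """Sentiment of a token list: sum of matched valence weights.

    ``stat="mean"`` averages over matched tokens instead (0 when nothing
    matches); the sum is the default and is what the rest of the pipeline
    uses.
    """
    hits = [lex.entries[t] for t in tokens if t in lex.entries]
    if not hits:
        return 0.0
    if stat == "sum":
        return float(sum(hits))
    if stat == "mean":
        return float(sum(hits) / len(hits))
    raise ValueError(f"unknown sentiment stat {stat!r}")


def count_emotions(tokens: Iterable[str], lex: EmotionLexicon) -> np.ndarray:
    """Per-emotion word counts; one token may increment several emotions."""
    counts = np.zeros(len(EMOTIONS), dtype=np.int64)
    idx = {e: i for i, e in enumerate(EMOTIONS)}
    for t in tokens:
        labs = lex.entries.get(t)
        if labs:
            for lab in labs:
                counts[idx[lab]] += 1
    return counts


def dichotomize(counts: np.ndarray) -> np.ndarray:
    """0/1 presence flags: 1 iff the count is at least one word."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("emotion counts must be non-negative")
    return (counts >= 1).astype(np.int64)


def score_tweet(text: str, vlex: ValenceLexicon, elex: EmotionLexicon,
                sentiment_stat: str = "sum") -> TweetScores:
    tokens = tokenize(text)
    counts = count_emotions(tokens, elex)
    return TweetScores(
        sentiment=score_valence(tokens, vlex, stat=sentiment_stat),
        emotion_counts=counts,
        emotion_flags=dichotomize(counts),
    )


def score_tweets(tweets: pd.DataFrame, vlex: ValenceLexicon,
                 elex: EmotionLexicon, *, text_col: str = "text",
                 sentiment_stat: str = "sum",
                 emotions: tuple[str, ...] = EMOTIONS) -> pd.DataFrame:
    """Score a tweet table, returning it with ``sentiment`` and flag columns.

    Vectorized batch equivalent of :func:`score_tweet`; the flag column for
    emotion ``e`` is named ``e`` and holds the dichotomized presence
    indicator.  ``emotions`` may be restricted to a subset when only some
    measures are needed (the sentiment column is always produced).
    """
    out = tweets.copy()
    tokens = tokenize_series(out[text_col])
    tokens.index = pd.RangeIndex(len(tokens))
    ex = tokens.explode().dropna()

    weights = ex.map(vlex.entries).dropna()
    sent = weights.groupby(level=0).agg(["sum", "count"])
    sent = sent.reindex(pd.RangeIndex(len(out)))
    if sentiment_stat == "sum":
        sentiment = sent["sum"].fillna(0.0)
    elif sentiment_stat == "mean":
        sentiment = (sent["sum"] / sent["count"]).fillna(0.0)
    else:
        raise ValueError(f"unknown sentiment stat {sentiment_stat!r}")
    out["sentiment"] = sentiment.to_numpy(dtype=float)

    by_emotion = elex.term_sets()
    rng_index = pd.RangeIndex(len(out))
    for e in emotions:
        terms = by_emotion[e]
        if terms:
            hit = ex[ex.isin(terms)]
            flag = pd.Series(1, index=hit.index.unique())
        else:
            flag = pd.Series(dtype=np.int64)
        out[e] = flag.reindex(rng_index).fillna(0).to_numpy(dtype=np.int64)
    return out


def toy_valence_lexicon() -> ValenceLexicon:
    """Small built-in valence lexicon for examples and tests."""
    return ValenceLexicon({
        "good": 0.8, "great": 1.0, "happy": 0.7, "love": 0.9, "calm": 0.4,
        "bad": -0.5, "awful": -1.0, "sad": -0.6, "hate": -0.9, "angry": -0.7,
    })


def toy_emotion_lexicon() -> EmotionLexicon:
    """Small built-in emotion lexicon; some terms carry several labels."""
    f = frozenset
    return EmotionLexicon({
        "happy": f({"joy", "positive"}),
        "love": f({"joy", "trust", "positive"}),
        "great": f({"positive"}),
        "angry": f({"anger", "negative"}),
        "fear": f({"fear", "negative"}),
        "awful": f({"disgust", "negative"}),
        "sad": f({"sadness", "negative"}),
        "shock": f({"surprise"}),
        "soon": f({"anticipation"}),
        "trust": f({"trust", "positive"}),
    })
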