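import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emosync import (StudyWindow, SynthConfig, toy_emotion_lexicon,
                     toy_valence_lexicon)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vlex():
    return toy_valence_lexicon()


@pytest.fixture(scope="session")
def elex():
    return toy_emotion_lexicon()


@pytest.fixture(scope="session")
def window():
    return StudyWindow(2021, 9, 30, "America/New_York")


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small but structurally complete synthetic configuration."""
    return SynthConfig(n_cities=3, users_per_city=40, days=4,
                       min_tweets=5, n_pois=12, seed=11)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_cfg):
    """One deterministic tiny corpus: (pois, contact, latent, tweets)."""
    from emosync import generate_contact, generate_latent_panel, generate_tweets
    rng = np.random.default_rng(tiny_cfg.seed)
    pois, cs = generate_contact(tiny_cfg, rng)
    latent = generate_latent_panel(tiny_cfg, cs, rng)
    tweets = generate_tweets(tiny_cfg, latent, rng)
    return pois, cs, latent, tweets


def random_panel(rng, n_rows, fe_cols):
    """Random regression table with the pipeline's column layout."""
    df = pd.DataFrame({
        "S": rng.normal(size=n_rows),
        "S_lag": rng.normal(size=n_rows),
        "MED_lag": rng.normal(size=n_rows),
        "CONT_lag": rng.normal(size=n_rows),
        "tweet_volume": rng.normal(size=n_rows),
    })
    for col, n_levels in fe_cols.items():
        df[col] = rng.integers(n_levels, size=n_rows)
    return df
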