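import numpy as np
import pandas as pd
import pytest

from conftest import random_panel
from emosync.fe_estimation import (BATTERY_REGRESSORS, ModelSpec,
                                   absorb_fixed_effects, fit_battery,
                                   fit_stats, ols_with_absorption,
                                   significance_stars)

SCHEMES = {
    "single": (("f1",),),
    "combined": (("f1", "f2"),),
    "crossed": (("f1",), ("f2",)),
    "crossed_combined": (("f1",), ("f2", "f3")),
}


def dummy_ols(df, spec):
    """Oracle: explicit dummy-variable OLS via statsmodels."""
    import statsmodels.api as sm

    from emosync.fe_estimation import TERM_DEFS
    X = {}
    for term in spec.regressors:
        parts = TERM_DEFS[term]
        x = df[parts[0]].to_numpy(dtype=float)
        for prt in parts[1:]:
            x = x * df[prt].to_numpy(dtype=float)
        X[term] = x
    X = pd.DataFrame(X)
    for fi, factor in enumerate(spec.fe):
        key = df[list(factor)].astype(str).agg("|".join, axis=1)
        dums = pd.get_dummies(key, prefix=f"fe{fi}", drop_first=(fi > 0))
        X = pd.concat([X, dums.astype(float)], axis=1)
    fit = sm.OLS(df[spec.dv].to_numpy(dtype=float), X).fit()
    return fit


def test_single_group_demeaning():
    df = pd.DataFrame({"y": [1.0, 3.0], "g": [0, 0]})
    out, rank, n_iter = absorb_fixed_effects(df, (("g",),), ["y"])
    np.testing.assert_allclose(out[:, 0], [-1.0, 1.0])
    assert rank == 1 and n_iter == 1


def test_purely_additive_two_way_data_demeans_to_zero():
    rng = np.random.default_rng(0)
    a = rng.normal(size=6)
    b = rng.normal(size=4)
    rows = [(a[i] + b[j], i, j) for i in range(6) for j in range(4)]
    df = pd.DataFrame(rows, columns=["y", "f1", "f2"])
    out, _, _ = absorb_fixed_effects(df, (("f1",), ("f2",)), ["y"])
    assert np.abs(out).max() < 1e-9


@pytest.mark.parametrize("scheme", list(SCHEMES))
def test_absorption_matches_dummy_ols(scheme):
    rng = np.random.default_rng(42)
    for rep in range(5):
        n = int(rng.integers(50, 200))
        df = random_panel(rng, n, {"f1": 6, "f2": 4, "f3": 3})
        df["S"] = (0.5 * df["S_lag"] - 0.2 * df["MED_lag"]
                   + rng.normal(size=n))
        spec = ModelSpec(regressors=("S_lag", "MED_lag", "CONT_lag",
                                     "MED_x_CONT"), fe=SCHEMES[scheme])
        mine = ols_with_absorption(df, spec)
        oracle = dummy_ols(df, spec)
        for term in spec.regressors:
            assert mine.params[term] == pytest.approx(oracle.params[term],
                                                      abs=1e-8)
            assert mine.se[term] == pytest.approx(oracle.bse[term], abs=1e-8)
        assert mine.dof_resid == int(oracle.df_resid)


def test_exact_fit_zero_se():
    df = pd.DataFrame({"S": np.arange(10, dtype=float) * 2,
                       "S_lag": np.arange(10, dtype=float),
                       "g": 0})
    spec = ModelSpec(regressors=("S_lag",), fe=(("g",),))
    fit = ols_with_absorption(df, spec)
    assert fit.params["S_lag"] == pytest.approx(2.0)
    assert fit.se["S_lag"] == pytest.approx(0.0, abs=1e-12)


def test_perfect_collinearity_names_regressor():
    rng = np.random.default_rng(3)
    df = random_panel(rng, 80, {"f1": 5})
    df["CONT_lag"] = df["MED_lag"]  # duplicate regressor
    spec = ModelSpec(regressors=("S_lag", "MED_lag", "CONT_lag"),
                     fe=(("f1",),))
    with pytest.raises(ValueError, match="collinear"):
        ols_with_absorption(df, spec)


def test_planted_coefficients_recovered_on_latent_panel():
    """Direct fit on a large noiseless-measurement panel hits (b1, b4)."""
    from emosync.exposure_design import assemble_estimation_table
    from emosync.synthetic_data import (SynthConfig, generate_contact,
                                        generate_latent_panel)
    cfg = SynthConfig(days=30, beta1=0.3, beta4=0.5, seed=5)
    rng = np.random.default_rng(5)
    _, cs = generate_contact(cfg, rng)
    latent = generate_latent_panel(cfg, cs, rng)
    panel = pd.DataFrame({
        "city": np.repeat(cfg.cities, cfg.n_periods),
        "period": np.tile(np.arange(cfg.n_periods), cfg.n_cities),
        "sentiment": latent.values[0].ravel(),
        "n_tweets": 100, "retained": True})
    tbl = assemble_estimation_table(panel, cs, "sentiment")
    fit = ols_with_absorption(tbl, ModelSpec(fe=(("period",),)))
    assert abs(fit.params["S_lag"] - 0.3) < 3 * fit.se["S_lag"]
    assert abs(fit.params["MED_x_CONT"] - 0.5) < 3 * fit.se["MED_x_CONT"]


def test_fit_stats_identities():
    rng = np.random.default_rng(7)
    y = rng.normal(size=100)
    fitted = y + rng.normal(scale=0.5, size=100)
    k = 13
    loglik, aic, bic, r2 = fit_stats(y, fitted, k)
    assert bic - aic == pytest.approx(k * (np.log(100) - 2))
    assert aic == pytest.approx(2 * k - 2 * loglik)
    assert 0.0 <= r2 <= 1.0


def test_battery_structure():
    rng = np.random.default_rng(9)
    n = 600
    df = random_panel(rng, n, {})
    df["period"] = np.tile(np.arange(60), 10)
    df["city"] = np.repeat(np.arange(5), 120)
    df["hour_of_day"] = df["period"] % 12
    results = fit_battery(df, base_fe=(("period",),),
                          extra_fe=("city", "hour_of_day"))
    assert len(results) == 5
    assert [len(r.params) for r in results] == [2, 2, 4, 4, 6]
    assert all(r.n_obs == n for r in results)
    assert results[0].n_fe_levels == 60
    # model 4 absorbs the crossed city-hour factor on top of the periods
    assert results[3].n_fe_levels > results[2].n_fe_levels
    assert list(results[2].params.index) == ["S_lag", "MED_lag", "CONT_lag",
                                             "MED_x_CONT"]
    assert results[2].k_params == 4 + 60 + 1
    assert results[2].bic - results[2].aic == pytest.approx(
        results[2].k_params * (np.log(n) - 2))


def test_cluster_se_differs_from_classical():
    rng = np.random.default_rng(11)
    df = random_panel(rng, 300, {"f1": 10})
    df["city"] = np.repeat(np.arange(6), 50)
    base = ModelSpec(regressors=("S_lag", "MED_lag"), fe=(("f1",),))
    classical = ols_with_absorption(df, base)
    clustered = ols_with_absorption(
        df, ModelSpec(regressors=("S_lag", "MED_lag"), fe=(("f1",),),
                      se_type="cluster_city"))
    np.testing.assert_allclose(classical.params, clustered.params, rtol=1e-12)
    assert not np.allclose(classical.se, clustered.se)


def test_significance_stars():
    assert significance_stars(0.0004) == "***"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.4) == ""


def test_null_rejection_rate_on_direct_panels():
    """With no true interaction, the b4 test rejects at ~ the nominal rate."""
    rng = np.random.default_rng(13)
    rejections = []
    for rep in range(200):
        n = 240
        df = random_panel(rng, n, {})
        df["period"] = np.tile(np.arange(40), 6)
        spec = ModelSpec(regressors=("S_lag", "MED_lag", "CONT_lag",
                                     "MED_x_CONT"), fe=(("period",),))
        df["S"] = 0.3 * df["S_lag"] + rng.normal(size=n)
        fit = ols_with_absorption(df, spec)
        rejections.append(fit.pvalues["MED_x_CONT"] < 0.05)
    rate = np.mean(rejections)
    assert 0.01 < rate < 0.10
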