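import numpy as np
import pandas as pd
import pytest

from emosync.exposure_design import (GROUPINGS, assemble_estimation_table,
                                     build_long_form, med_matrix,
                                     standardize_covariates)
from emosync.mobility_contact import ContactSeries

CITIES = ("A", "B", "C")


def make_cs(weight_fn, T=6, cities=CITIES):
    n = len(cities)
    values = np.zeros((n, n, T))
    for a in range(n):
        for b in range(n):
            if a != b:
                values[a, b, :] = weight_fn(min(a, b), max(a, b))
    return ContactSeries(cities, values)


def test_med_weighted_mean_example():
    # city A's partners B, C valued 1 and 3 with weights 1 and 3 -> 2.5
    values = np.array([[np.nan], [1.0], [3.0]])
    cs = make_cs(lambda a, b: 0.0, T=1)
    cs.values[0, 1, 0] = cs.values[1, 0, 0] = 1.0
    cs.values[0, 2, 0] = cs.values[2, 0, 0] = 3.0
    med, fb = med_matrix(values, cs)
    assert med[0, 0] == pytest.approx(2.5)
    assert not fb[0, 0]


def test_med_equal_weights_is_simple_mean_and_zero_weight_fallback():
    values = np.array([[np.nan], [2.0], [4.0]])
    cs_eq = make_cs(lambda a, b: 7.0, T=1)
    med, _ = med_matrix(values, cs_eq)
    assert med[0, 0] == pytest.approx(3.0)
    cs0 = make_cs(lambda a, b: 0.0, T=1)
    med0, fb0 = med_matrix(values, cs0)
    assert med0[0, 0] == pytest.approx(3.0)
    assert fb0[0, 0]


def test_med_missing_when_no_partner_retained():
    values = np.array([[1.0], [np.nan], [np.nan]])
    cs = make_cs(lambda a, b: 1.0, T=1)
    med, _ = med_matrix(values, cs)
    assert np.isnan(med[0, 0])


def test_med_scale_and_weight_equivariance():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(3, 6))
    cs = make_cs(lambda a, b: float(a + b + 1), T=6)
    med, _ = med_matrix(values, cs)
    med_scaled, _ = med_matrix(3.0 * values, cs)
    np.testing.assert_allclose(med_scaled, 3.0 * med, rtol=1e-12)
    cs2 = ContactSeries(CITIES, cs.values * 11.0)
    med_w, _ = med_matrix(values, cs2)
    np.testing.assert_allclose(med_w, med, rtol=1e-12)
    # MED lies within the partner value range
    for i in range(3):
        others = np.delete(values, i, axis=0)
        assert (med[i] >= others.min(axis=0) - 1e-12).all()
        assert (med[i] <= others.max(axis=0) + 1e-12).all()


def test_standardize_covariates_moments():
    df = pd.DataFrame({
        "city": ["A", "A", "A", "B", "B", "B"],
        "CONT_lag": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        "tweet_volume": [np.log(50), np.log(60), np.log(70)] + [np.log(55)] * 3,
    })
    out = standardize_covariates(df)
    assert out["CONT_lag"].mean() == pytest.approx(0.0, abs=1e-9)
    assert out["CONT_lag"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    sub = out[out["city"] == "A"]["CONT_lag"].to_numpy()
    # z-scoring is affine: equal raw spacing stays equal
    assert sub[1] - sub[0] == pytest.approx(sub[2] - sub[1])
    # constant log tweet volume within city B becomes zeros
    assert (out[out["city"] == "B"]["tweet_volume"] == 0).all()
    tv_a = out[out["city"] == "A"]["tweet_volume"]
    assert tv_a.mean() == pytest.approx(0.0, abs=1e-12)
    assert tv_a.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_standardize_cont_unit_variance_simple_case():
    df = pd.DataFrame({"city": ["A"] * 3, "CONT_lag": [1.0, 2.0, 3.0],
                       "tweet_volume": [1.0, 2.0, 3.0]})
    out = standardize_covariates(df)
    np.testing.assert_allclose(out["CONT_lag"], [-1.0, 0.0, 1.0], atol=1e-12)


def _full_panel(T=8, cities=CITIES, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for c in cities:
        for t in range(T):
            rows.append((c, t, rng.normal(), 60, True))
    return pd.DataFrame(rows, columns=["city", "period", "sentiment",
                                       "n_tweets", "retained"])


def test_assemble_row_count_and_lag_alignment():
    T = 8
    panel = _full_panel(T)
    cs = make_cs(lambda a, b: float(a + b + 1), T=T)
    tbl = assemble_estimation_table(panel, cs, "sentiment",
                                    standardize=False)
    assert len(tbl) == len(CITIES) * (T - 1)
    # the row for (A, t) uses S at t, lag and MED from t-1
    piv = panel.pivot(index="city", columns="period", values="sentiment")
    row = tbl[(tbl["city"] == "A") & (tbl["period"] == 3)].iloc[0]
    assert row["S"] == pytest.approx(piv.loc["A", 3])
    assert row["S_lag"] == pytest.approx(piv.loc["A", 2])
    med, _ = med_matrix(piv.loc[list(CITIES)].to_numpy(), cs)
    assert row["MED_lag"] == pytest.approx(med[0, 2])
    assert row["CONT_lag"] == pytest.approx(cs.totals()[0, 2])
    assert row["hour_of_day"] == 3


def test_assemble_gap_removes_two_rows():
    T = 8
    panel = _full_panel(T)
    mask = (panel["city"] == "A") & (panel["period"] == 4)
    panel.loc[mask, "retained"] = False
    panel.loc[mask, "n_tweets"] = 3
    panel.loc[mask, "sentiment"] = np.nan
    cs = make_cs(lambda a, b: 1.0, T=T)
    tbl = assemble_estimation_table(panel, cs, "sentiment",
                                    standardize=False)
    gone = {(c, t) for c, t in zip(tbl["city"], tbl["period"])}
    assert ("A", 4) not in gone and ("A", 5) not in gone
    assert len(tbl) == len(CITIES) * (T - 1) - 2


def test_assemble_empty_intersection_raises():
    panel = _full_panel(4)
    panel["retained"] = False
    panel["sentiment"] = np.nan
    cs = make_cs(lambda a, b: 1.0, T=4)
    with pytest.raises(ValueError):
        assemble_estimation_table(panel, cs, "sentiment")


def test_long_form_row_counts_and_key_check():
    base = pd.DataFrame({
        "city": ["A", "B"] * 3, "period": [1, 1, 2, 2, 3, 3],
        "S": 0.0, "S_lag": 0.0, "MED_lag": 0.0, "CONT_lag": 0.0,
        "tweet_volume": 0.0,
    })
    tables = {}
    for e in GROUPINGS["all"]:
        t = base.copy()
        t["emotion"] = e
        tables[e] = t
    for name, members in [("all", 10), ("positive", 3), ("negative", 4),
                          ("tense", 3)]:
        long = build_long_form(tables, GROUPINGS[name])
        assert len(long) == len(base) * members
        assert set(long["emotion"]) == set(GROUPINGS[name])
    bad = dict(tables)
    bad["joy"] = tables["joy"].iloc[:-1]
    with pytest.raises(ValueError):
        build_long_form(bad, GROUPINGS["positive"])
    with pytest.raises(KeyError):
        build_long_form({"joy": tables["joy"]}, GROUPINGS["positive"])


def test_grouping_membership():
    assert GROUPINGS["positive"] == ("joy", "trust", "positive")
    assert GROUPINGS["negative"] == ("anger", "disgust", "sadness", "negative")
    assert GROUPINGS["tense"] == ("anticipation", "fear", "surprise")
    assert set(GROUPINGS["all"]) == set(GROUPINGS["positive"]) \
        | set(GROUPINGS["negative"]) | set(GROUPINGS["tense"])
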