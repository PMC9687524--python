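"""OLS with absorbed (high-dimensional) fixed effects.

The contagion model for a measure S is

    S_it = b1 * S_i,t-1 + b2 * MED_i,t-1 + b3 * CONT_i,t-1
           + b4 * MED_i,t-1 * CONT_i,t-1 + D_t + e_it

where D_t are period fixed effects (one level per two-hour period of the
sample; emotion × period levels in the pooled long form) and b4 — the
contact × mean-degree-emotion interaction — is the focal quantity: a
positive b4 means inter-city synchrony strengthens with contact.

Fixed effects are absorbed by group demeaning (alternating projections for
crossed schemes), which reproduces the slope estimates of the explicit
dummy-variable regression exactly; classical standard errors use residual
degrees of freedom adjusted for the absorbed levels, so they too match the
dummy regression.  Cluster-robust (by city) errors are available.

A model *battery* mirrors the five-column table layout used throughout the
analysis: (1) lag + MED; (2) lag + interaction; (3) lag + MED + CONT +
interaction; (4) model 3 with an additional city × hour-of-day (× emotion)
fixed-effect factor; (5) model 3 plus tweet-volume controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ModelSpec", "FitResult", "TERM_DEFS", "absorb_fixed_effects",
           "ols_with_absorption", "fit_battery", "fit_stats", "fe_rank",
           "significance_stars", "BATTERY_REGRESSORS"]

logger = logging.getLogger(__name__)

#: Regressor term -> the data columns whose product forms it.
TERM_DEFS: dict[str, tuple[str, ...]] = {
    "S_lag": ("S_lag",),
    "MED_lag": ("MED_lag",),
    "CONT_lag": ("CONT_lag",),
    "MED_x_CONT": ("MED_lag", "CONT_lag"),
    "tweet_volume": ("tweet_volume",),
    "TV_x_MED": ("tweet_volume", "MED_lag"),
}

#: Regressor sets of the five battery models.
BATTERY_REGRESSORS: tuple[tuple[str, ...], ...] = (
    ("S_lag", "MED_lag"),
    ("S_lag", "MED_x_CONT"),
    ("S_lag", "MED_lag", "CONT_lag", "MED_x_CONT"),
    ("S_lag", "MED_lag", "CONT_lag", "MED_x_CONT"),
    ("S_lag", "MED_lag", "CONT_lag", "MED_x_CONT",
     "tweet_volume", "TV_x_MED"),
)


@dataclass(frozen=True)
class ModelSpec:
    """One estimation specification.

    ``fe`` is a tuple of fixed-effect factors; each factor is a tuple of
    column names whose combinations define its levels (e.g. ``(("period",),)``
    for period effects, ``(("emotion", "period"),)`` for emotion-period
    effects, or two factors for a crossed scheme).
    """

    dv: str = "S"
    regressors: tuple[str, ...] = ("S_lag", "MED_lag", "CONT_lag",
                                   "MED_x_CONT")
    fe: tuple[tuple[str, ...], ...] = (("period",),)
    se_type: str = "classical"  # or "cluster_city"

    def __post_init__(self) -> None:
        if not self.fe:
            raise ValueError("at least one fixed-effect factor is required")
        unknown = [r for r in self.regressors if r not in TERM_DEFS]
        if unknown:
            raise ValueError(f"unknown regressors {unknown}")


@dataclass(frozen=True)
class FitResult:
    """Estimates and fit statistics for one specification."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n_obs: int
    n_fe_levels: int
    dof_resid: int
    k_params: int
    loglik: float
    aic: float
    bic: float
    pseudo_r2: float
    n_demean_iter: int = 0
    cov: np.ndarray = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.se, "t": self.tvalues,
            "p": self.pvalues,
            "stars": [significance_stars(p) for p in self.pvalues],
        })


def significance_stars(p: float) -> str:
    """Render the conventional significance stars for a p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _factor_codes(df: pd.DataFrame, factor: tuple[str, ...]) -> tuple[np.ndarray, int]:
    if len(factor) == 1:
        codes, levels = pd.factorize(df[factor[0]], sort=True)
    else:
        codes, levels = pd.factorize(
            pd.MultiIndex.from_frame(df[list(factor)]), sort=True)
    return codes.astype(np.int64), len(levels)


def _demean_once(arr: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    out = arr.copy()
    for c in range(arr.shape[1]):
        sums = np.bincount(codes, weights=arr[:, c], minlength=n_levels)
        out[:, c] -= (sums / counts)[codes]
    return out


def fe_rank(codes_list: list[np.ndarray], n_levels_list: list[int]) -> int:
    """Number of estimable parameters the absorbed dummies represent.

    For one factor this is its level count (the intercept is part of it).
    For two factors it is L1 + L2 minus the number of connected components
    of the bipartite level graph (the exact rank of the two-factor dummy
    design).  Further factors are folded in with the same pairwise rule
    against the first factor, which is exact whenever the extra factors'
    graphs are connected through the first.
    """
    rank = n_levels_list[0]
    base = codes_list[0]
    n_base = n_levels_list[0]
    for codes, n_lev in zip(codes_list[1:], n_levels_list[1:]):
        parent = np.arange(n_base + n_lev)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in set(zip(base.tolist(), (codes + n_base).tolist())):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        n_comp = len({find(x) for x in range(n_base + n_lev)})
        rank += n_lev - n_comp
    return rank


def absorb_fixed_effects(df: pd.DataFrame, fe: tuple[tuple[str, ...], ...],
                         columns: list[str], tol: float = 1e-10,
                         max_iter: int = 10_000
                         ) -> tuple[np.ndarray, int, int]:
    """Residualize ``columns`` on the fixed-effect dummies.

    Returns (demeaned array, absorbed-parameter count, iterations).  A single
    factor needs one exact pass; crossed schemes alternate group demeaning
    until the largest change falls below ``tol``.  Observations alone in
    every one of their cells are absorbed completely (their residuals are
    zero) — they carry no information about the slopes.
    """
    arr = df[columns].to_numpy(dtype=float).copy()
    codes_list, levels_list = [], []
    for factor in fe:
        codes, n_levels = _factor_codes(df, factor)
        codes_list.append(codes)
        levels_list.append(n_levels)
    rank = fe_rank(codes_list, levels_list)

    if len(codes_list) == 1:
        arr = _demean_once(arr, codes_list[0], levels_list[0])
        return arr, rank, 1

    for it in range(1, max_iter + 1):
        prev = arr.copy()
        for codes, n_levels in zip(codes_list, levels_list):
            arr = _demean_once(arr, codes, n_levels)
        if np.max(np.abs(arr - prev)) < tol:
            return arr, rank, it
    raise RuntimeError(
        f"fixed-effect demeaning did not converge in {max_iter} iterations")


def _design(df: pd.DataFrame, regressors: tuple[str, ...]) -> np.ndarray:
    cols = []
    for term in regressors:
        parts = TERM_DEFS[term]
        x = df[parts[0]].to_numpy(dtype=float)
        for p in parts[1:]:
            x = x * df[p].to_numpy(dtype=float)
        cols.append(x)
    return np.column_stack(cols)


def fit_stats(y: np.ndarray, fitted: np.ndarray, k: int
              ) -> tuple[float, float, float, float]:
    """Gaussian log-likelihood, AIC, BIC and pseudo-R² of a fit.

    ``k`` counts slope parameters, absorbed fixed-effect levels and the
    error variance.  Pseudo-R² is the squared correlation between fitted
    (fixed effects included) and observed values.
    """
    n = len(y)
    rss = float(((y - fitted) ** 2).sum())
    sigma2 = max(rss / n, np.finfo(float).tiny)  # exact fits stay finite
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    aic = 2 * k - 2 * loglik
    bic = k * np.log(n) - 2 * loglik
    if np.std(fitted) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    return loglik, aic, bic, r2


def ols_with_absorption(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one specification by demeaned OLS.

    Slopes are identical to the explicit dummy-variable regression; classical
    SEs use dof = n − slopes − absorbed levels.  Perfect collinearity among
    the demeaned regressors raises with the offending term named.
    """
    df = df.reset_index(drop=True)
    y = df[spec.dv].to_numpy(dtype=float)
    X = _design(df, spec.regressors)
    names = list(spec.regressors)

    work = np.column_stack([y, X])
    tmp = pd.DataFrame(work, columns=["__y__"] + names)
    for col in {c for f in spec.fe for c in f}:
        tmp[col] = df[col].to_numpy()
    demeaned, rank, n_iter = absorb_fixed_effects(
        tmp, spec.fe, ["__y__"] + names)
    yd = demeaned[:, 0]
    Xd = demeaned[:, 1:]

    n, p = Xd.shape
    xtx = Xd.T @ Xd
    if np.linalg.matrix_rank(xtx, tol=1e-8 * max(np.max(np.abs(xtx)), 1e-300)) < p \
            or (np.diag(xtx) <= 1e-12 * n).any():
        # identify a term whose removal restores full rank
        for drop in range(p):
            keep = [c for c in range(p) if c != drop]
            sub = xtx[np.ix_(keep, keep)]
            if np.linalg.matrix_rank(
                    sub, tol=1e-8 * max(np.max(np.abs(sub)), 1e-300)) == p - 1:
                raise ValueError(
                    f"regressor {names[drop]!r} is perfectly collinear "
                    "after fixed-effect absorption")
        raise ValueError("perfect collinearity after fixed-effect absorption")

    beta = np.linalg.solve(xtx, Xd.T @ yd)
    resid = yd - Xd @ beta
    dof = n - p - rank
    if dof <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, "
                         f"slopes={p}, absorbed={rank})")
    xtx_inv = np.linalg.inv(xtx)

    if spec.se_type == "classical":
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * xtx_inv
        t_dof = dof
    elif spec.se_type == "cluster_city":
        clusters, n_g = _factor_codes(df, ("city",))
        meat = np.zeros((p, p))
        for g in range(n_g):
            m = clusters == g
            s = Xd[m].T @ resid[m]
            meat += np.outer(s, s)
        adj = (n_g / (n_g - 1)) * ((n - 1) / dof)
        cov = adj * xtx_inv @ meat @ xtx_inv
        t_dof = n_g - 1
    else:
        raise ValueError(f"unknown se_type {spec.se_type!r}")

    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), t_dof)
    pvals = np.where(se > 0, pvals, 0.0)

    fitted = y - resid  # includes the absorbed fixed-effect contribution
    k = p + rank + 1
    loglik, aic, bic, pseudo_r2 = fit_stats(y, fitted, k)

    idx = pd.Index(names, name="term")
    return FitResult(
        spec=spec,
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        n_obs=n, n_fe_levels=rank, dof_resid=dof, k_params=k,
        loglik=loglik, aic=aic, bic=bic, pseudo_r2=pseudo_r2,
        n_demean_iter=n_iter, cov=cov,
    )


def fit_battery(data: pd.DataFrame,
                base_fe: tuple[tuple[str, ...], ...] = (("period",),),
                extra_fe: tuple[str, ...] = ("city", "hour_of_day"),
                se_type: str = "classical") -> list[FitResult]:
    """Fit the five-model battery on one estimation table.

    ``base_fe`` applies to every model (period effects for a single measure,
    emotion × period for a long form); model 4 adds ``extra_fe`` — city ×
    hour-of-day, or emotion × city × hour-of-day in the long form — on top
    of the base scheme.
    """
    results = []
    for m, regressors in enumerate(BATTERY_REGRESSORS, start=1):
        fe = base_fe + ((tuple(extra_fe),) if m == 4 else ())
        spec = ModelSpec(dv="S", regressors=regressors, fe=fe,
                         se_type=se_type)
        res = ols_with_absorption(data, spec)
        logger.info("model %d: n=%d, k=%d, b4=%s", m, res.n_obs, res.k_params,
                    res.params.get("MED_x_CONT"))
        results.append(res)
    return results
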