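"""Inference on growth features and day-specific growth rates.

Two mixed-model layouts are supported, matching the rearing design and
nothing more:

* feature layout — one observation per larva; fixed effects sex and
  host plant; a random brood intercept;
* repeated layout — day-specific rates as repeated measurements; fixed
  effects sex, day (continuous, centred), host plant, sex:day and
  sex:plant; random brood and individual-within-brood intercepts.

Variance components are estimated by profiled restricted maximum
likelihood (REML) over the variance ratios, with the zero boundary
admissible, so that designs with no group-level variance collapse
exactly to ordinary least squares.  Fixed effects use sum-to-zero
codings and Type III Wald F-tests.  Denominator degrees of freedom
follow a containment-style rule based on the number of larvae rather
than the number of measurements, to avoid pseudoreplication: for
between-larva factors ddf = (number of larvae) − (rank of the
between-larva fixed design); for within-larva factors
ddf = (number of observations) − (number of larvae) − (number of
within-larva fixed parameters).

Factor-specific R² is reported as the factor's Type III sum of squares
as a share of the total sum of squares, computed from the corresponding
fixed-effects fit; this is a transparent approximation, not a
mixed-model R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
import statsmodels.api as sm


@dataclass
class RegressionFit:
    """OLS fit of a day-specific growth rate on prior body mass."""

    sex: str
    measure: str
    day: int
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int


@dataclass
class AnovaResult:
    """One factor's row from a mixed-ANOVA table."""

    factor: str
    F: float
    ndf: int
    ddf: int
    p: float
    r2: float
    method: str = "reml"  # "reml" or "moments" fallback


# ---------------------------------------------------------------------------
# REML engine


class _MixedFit:
    def __init__(self, beta, cov_beta, sigma2, lambdas, method):
        self.beta = beta
        self.cov_beta = cov_beta
        self.sigma2 = sigma2
        self.lambdas = lambdas
        self.method = method


def _block_solve(lams, blocks, X, y):
    """Accumulate GLS quantities over independent brood blocks.

    Each entry of ``blocks`` is (row_indices, individual_labels or None).
    V within a block is I + lam_b*J + lam_i*blockdiag(J_ind).
    Returns (XtVX, XtVy, ytVy, logdetV).
    """
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for rows, ind in blocks:
        nb = len(rows)
        V = np.eye(nb) + lams[0] * np.ones((nb, nb))
        if ind is not None and len(lams) > 1:
            for lab in np.unique(ind):
                sel = np.where(ind == lab)[0]
                V[np.ix_(sel, sel)] += lams[1]
        c, low = linalg.cho_factor(V, lower=True)
        logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
        Xb, yb = X[rows], y[rows]
        Vx = linalg.cho_solve((c, low), Xb)
        Vy = linalg.cho_solve((c, low), yb)
        XtVX += Xb.T @ Vx
        XtVy += Xb.T @ Vy
        ytVy += float(yb @ Vy)
    return XtVX, XtVy, ytVy, logdet


def _reml_neg_loglik(lams, blocks, X, y):
    n, p = X.shape
    XtVX, XtVy, ytVy, logdetV = _block_solve(lams, blocks, X, y)
    sign, logdetX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / (n - p)
    return 0.5 * ((n - p) * math.log(sigma2) + logdetV + logdetX)


def _fit_mixed(y, X, brood, indiv=None) -> _MixedFit:
    """Profiled-REML fit of the random-intercept model(s)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    brood = np.asarray(brood)
    n, p = X.shape
    blocks = []
    for lab in np.unique(brood):
        rows = np.where(brood == lab)[0]
        ind = None if indiv is None else np.asarray(indiv)[rows]
        blocks.append((rows, ind))
    k = 1 if indiv is None else 2

    method = "reml"
    res = optimize.minimize(
        _reml_neg_loglik, x0=np.full(k, 0.1), args=(blocks, X, y),
        method="L-BFGS-B", bounds=[(0.0, 1e4)] * k)
    lams = res.x
    # also test the zero-boundary corner explicitly: L-BFGS-B can stall
    # just off it, and the boundary is statistically meaningful
    corners = [np.zeros(k)]
    if k == 2:
        corners += [np.array([res.x[0], 0.0]), np.array([0.0, res.x[1]])]
    best = _reml_neg_loglik(lams, blocks, X, y)
    for c in corners:
        v = _reml_neg_loglik(c, blocks, X, y)
        if v < best - 1e-10:
            best, lams = v, c
    if not res.success and not np.isfinite(best):
        method = "moments"
        lams = _moments_lambdas(y, X, brood, indiv, k)

    XtVX, XtVy, ytVy, _ = _block_solve(lams, blocks, X, y)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    return _MixedFit(beta, cov_beta, sigma2, lams, method)


def _moments_lambdas(y, X, brood, indiv, k):
    """Method-of-moments fallback from OLS residual group means."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(np.var(resid, ddof=X.shape[1]))
    out = []
    for labels in ([brood] if k == 1 else [brood, indiv]):
        labels = np.asarray(labels)
        means = np.array([resid[labels == g].mean() for g in np.unique(labels)])
        sizes = np.array([(labels == g).sum() for g in np.unique(labels)])
        v_between = max(float(np.var(means, ddof=1)) - s2 / float(sizes.mean()), 0.0)
        out.append(v_between / s2 if s2 > 0 else 0.0)
    return np.array(out)


# ---------------------------------------------------------------------------
# design construction


def _sum_to_zero(series: pd.Series, positive: str) -> np.ndarray:
    return np.where(series.to_numpy() == positive, 1.0, -1.0)


def _check_two_levels(series: pd.Series, name: str) -> None:
    levels = set(series.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has a single level "
                         f"({sorted(levels)}); design is singular for {name!r}")


def _type3_r2(y, X, term_cols: dict[str, list[int]]) -> dict[str, float]:
    """Type III SS share of total SS from the fixed-effects fit."""
    y = np.asarray(y, dtype=float)

    def _rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    rss_full = _rss(X)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    out = {}
    for term, cols in term_cols.items():
        keep = [j for j in range(X.shape[1]) if j not in cols]
        out[term] = (max(_rss(X[:, keep]) - rss_full, 0.0) / ss_total
                     if ss_total > 0 else 0.0)
    return out


def _wald_f(fit: _MixedFit, cols: list[int]) -> float:
    b = fit.beta[cols]
    C = fit.cov_beta[np.ix_(cols, cols)]
    return float(b @ np.linalg.solve(C, b)) / len(cols)


# ---------------------------------------------------------------------------
# public operations


def feature_anova(features: pd.DataFrame, response: str) -> list[AnovaResult]:
    """Mixed ANOVA of one growth descriptor: sex + host, random brood.

    Returns Type III F-tests for sex and host plant with containment
    denominator df and Type-III-SS-share R².
    """
    if response not in features.columns:
        raise ValueError(f"unknown response {response!r}")
    data = features.dropna(subset=[response, "sex", "host", "brood_id"])
    if data["brood_id"].nunique() < 2:
        raise ValueError("need at least 2 broods")
    _check_two_levels(data["sex"], "sex")
    _check_two_levels(data["host"], "plant")

    y = data[response].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([
        np.ones(n),
        _sum_to_zero(data["sex"], "F"),
        _sum_to_zero(data["host"], "host1"),
    ])
    term_cols = {"sex": [1], "plant": [2]}
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design: sex and plant aliased")

    brood = data["brood_id"].to_numpy()
    fit = _fit_mixed(y, X, brood)
    broods = pd.get_dummies(pd.Series(brood)).to_numpy(dtype=float)
    ddf = n - np.linalg.matrix_rank(np.column_stack([X, broods]))
    r2 = _type3_r2(y, X, term_cols)
    out = []
    for term, cols in term_cols.items():
        F = _wald_f(fit, cols)
        out.append(AnovaResult(term, F, len(cols), int(ddf),
                               float(stats.f.sf(F, len(cols), ddf)),
                               r2[term], fit.method))
    return out


_REPEATED_ORDER = ["sex", "day", "plant", "sex:day", "sex:plant"]


def repeated_anova(records: pd.DataFrame, measure: str | None = None) -> list[AnovaResult]:
    """Repeated-measures mixed ANOVA of day-specific growth rates.

    Fixed effects sex, day (continuous, centred), plant, sex:day and
    sex:plant; random brood and individual-within-brood intercepts.
    Denominator df for between-larva factors are derived from the number
    of larvae, not measurements.
    """
    data = records
    if measure is not None:
        data = data[data["measure"] == measure]
    elif "measure" in data.columns and data["measure"].nunique() > 1:
        raise ValueError("records mix several measures; pass measure=...")
    data = data.dropna(subset=["value", "sex", "host", "brood_id",
                               "individual_id", "day"])
    if data.empty:
        raise ValueError("no rate records")
    days_per_ind = data.groupby("individual_id")["day"].nunique()
    if days_per_ind.max() < 2:
        raise ValueError("need >= 2 days per individual for a repeated design")
    if data["brood_id"].nunique() < 2:
        raise ValueError("need at least 2 broods")
    _check_two_levels(data["sex"], "sex")
    _check_two_levels(data["host"], "plant")

    y = data["value"].to_numpy(dtype=float)
    n_obs = len(y)
    sex = _sum_to_zero(data["sex"], "F")
    plant = _sum_to_zero(data["host"], "host1")
    day_c = data["day"].to_numpy(dtype=float)
    day_c = day_c - day_c.mean()
    X = np.column_stack([np.ones(n_obs), sex, day_c, plant,
                         sex * day_c, sex * plant])
    term_cols = {"sex": [1], "day": [2], "plant": [3],
                 "sex:day": [4], "sex:plant": [5]}
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design among "
                         "sex/day/plant interactions")

    brood = data["brood_id"].to_numpy()
    indiv = data["individual_id"].to_numpy()
    fit = _fit_mixed(y, X, brood, indiv)

    n_larvae = data["individual_id"].nunique()
    between = (data.groupby("individual_id")
               .agg(sex=("sex", "first"), host=("host", "first")))
    Xb = np.column_stack([
        np.ones(n_larvae),
        _sum_to_zero(between["sex"], "F"),
        _sum_to_zero(between["host"], "host1"),
        _sum_to_zero(between["sex"], "F") * _sum_to_zero(between["host"], "host1"),
    ])
    rank_between = int(np.linalg.matrix_rank(Xb))
    ddf_between = n_larvae - rank_between
    ddf_within = n_obs - n_larvae - 2  # day and sex:day parameters

    r2 = _type3_r2(y, X, term_cols)
    out = []
    for term in _REPEATED_ORDER:
        cols = term_cols[term]
        ddf = ddf_within if "day" in term else ddf_between
        F = _wald_f(fit, cols)
        out.append(AnovaResult(term, F, len(cols), int(ddf),
                               float(stats.f.sf(F, len(cols), ddf)),
                               r2[term], fit.method))
    return out


def size_dependence(records: pd.DataFrame,
                    days=(2, 3),
                    measures=("relative", "allometric")) -> list[RegressionFit]:
    """Per-(sex, measure, day) OLS of rate on prior body mass.

    The covariate is the mass recorded one day before the 24 h period,
    so the regression shares no measurement with the rate.  Returns
    slope, its SE and the two-sided p-value of slope = 0.
    """
    out = []
    for meas in measures:
        for day in days:
            sub_md = records[(records["measure"] == meas)
                             & (records["day"] == day)]
            for sex in ("F", "M"):
                sub = sub_md[sub_md["sex"] == sex].dropna(
                    subset=["value", "covariate_mass"])
                if len(sub) < 3:
                    raise ValueError(
                        f"fewer than 3 points for sex={sex}, measure={meas}, "
                        f"day={day}")
                Xd = sm.add_constant(sub["covariate_mass"].to_numpy(dtype=float))
                ols = sm.OLS(sub["value"].to_numpy(dtype=float), Xd).fit()
                out.append(RegressionFit(
                    sex=sex, measure=meas, day=day,
                    slope=float(ols.params[1]), intercept=float(ols.params[0]),
                    slope_se=float(ols.bse[1]), p_value=float(ols.pvalues[1]),
                    n=int(ols.nobs)))
    return out


def anova_frame(results: list[AnovaResult]) -> pd.DataFrame:
    """Tabular view of ANOVA results (factor, F, ndf, ddf, p, R²)."""
    return pd.DataFrame([r.__dict__ for r in results])


def regression_frame(results: list[RegressionFit]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
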