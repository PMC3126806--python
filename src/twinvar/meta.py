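"""Random-effects meta-regression of per-stratum standard deviations.

Each stratum contributes an estimate y_i (the additive genetic or unique
environmental SD of BMI) with within-stratum variance v_i = se_i^2.  The
random-effects model adds a between-stratum heterogeneity variance tau^2,

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, v_i),

estimated by the DerSimonian–Laird method of moments extended to moderators:
a fixed-effect WLS fit with weights 1/v_i gives the residual heterogeneity
statistic Q, and

    tau^2 = max(0, (Q - (k - p)) / (tr(W) - tr((X'WX)^{-1} X'W^2 X))),

with W = diag(1/v_i).  Coefficients are then weighted least squares with
weights 1/(v_i + tau^2); standard errors come from (X'WX)^{-1} and p-values
from the two-sided standard-normal reference (the classic Stata ``metareg``
behaviour), with a Knapp–Hartung t-adjustment available as an option.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DataError
from .types import FEMALE, MetaDataset, MetaRegressionResult

PROXIES = ("obesity_pct", "overweight_pct", "mean_bmi")
OUTCOMES = ("A", "E")

#: Default moderator layout of the published model: proxy effect controlled
#: for sex, age and survey wave, plus a sex x proxy interaction.
DEFAULT_TERMS = ("intercept", "proxy", "sex", "age", "sex_x_proxy", "survey")


def build_meta_dataset(
    stratum_table: pd.DataFrame,
    proxy: str,
    outcome: str = "A",
    include_age_x_proxy: bool = False,
) -> Tuple[MetaDataset, pd.DataFrame]:
    """Assemble the meta-regression design from a per-stratum table.

    One row per stratum with a valid, unflagged fit; flagged strata are
    returned in the second element as a log.  ``sex`` is coded 0 = male,
    1 = female; ``survey`` 0 for the first wave, 1 for the second; ``age`` is
    survey year minus birth year.
    """
    if proxy not in PROXIES:
        raise ConfigError(f"unknown proxy {proxy!r}; choose from {PROXIES}")
    if outcome not in OUTCOMES:
        raise ConfigError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")

    ycol, secol = ("agsd", "agsd_se") if outcome == "A" else ("esd", "esd_se")
    usable = (
        np.isfinite(stratum_table[ycol].to_numpy(dtype=float))
        & np.isfinite(stratum_table[secol].to_numpy(dtype=float))
        & (stratum_table[secol].to_numpy(dtype=float) > 0)
    )
    if "fit_valid" in stratum_table.columns:
        usable &= stratum_table["fit_valid"].to_numpy(dtype=bool)
    dropped = stratum_table[~usable]
    rows = stratum_table[usable]

    surveys = np.sort(stratum_table["survey_year"].unique())
    y = rows[ycol].to_numpy(dtype=float)
    v = rows[secol].to_numpy(dtype=float) ** 2
    px = rows[proxy].to_numpy(dtype=float)
    sex = (rows["sex"].to_numpy() == FEMALE).astype(float)
    age = (rows["survey_year"] - rows["birth_year"]).to_numpy(dtype=float)
    survey = (rows["survey_year"].to_numpy() == surveys[-1]).astype(float) \
        if len(surveys) > 1 else np.zeros(len(rows))

    cols = {"intercept": np.ones(len(rows)), "proxy": px, "sex": sex,
            "age": age, "sex_x_proxy": sex * px, "survey": survey}
    names = list(DEFAULT_TERMS)
    if include_age_x_proxy:
        cols["age_x_proxy"] = age * px
        names.append("age_x_proxy")
    # constant moderators (e.g. survey in a one-wave cohort) carry no
    # information and would be collinear with the intercept; drop them
    names = [c for c in names
             if c in ("intercept", "proxy") or np.ptp(cols[c]) > 0]
    X = np.column_stack([cols[c] for c in names])

    if len(y) <= X.shape[1]:
        raise DataError(
            f"only {len(y)} usable strata for a {X.shape[1]}-column design"
        )
    ds = MetaDataset(y=y, v=v, X=X, columns=names, proxy=proxy, outcome=outcome)
    return ds, dropped


def _check_collinear(X: np.ndarray, columns: Sequence[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape[0] * np.finfo(float).eps * diag.max(), 1e-10 * diag.max())
    if np.any(diag < tol):
        bad = [columns[i] for i in np.where(diag < tol)[0]]
        raise DataError(f"collinear design matrix; offending column(s): {', '.join(bad)}")


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ y)
    cov = np.linalg.inv(xtwx)
    resid = y - X @ beta
    q = float(np.sum(w * resid**2))
    return beta, cov, q


def dl_tau_squared(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """DerSimonian–Laird moment estimate of tau^2 for a meta-regression.

    Truncated at zero; a degenerate denominator yields 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if np.any(v <= 0):
        raise DataError("all within-stratum variances must be positive")
    k, p = X.shape
    w = 1.0 / v
    _, _, q = _wls(y, X, w)
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    trace_term = float(np.trace(xtwx_inv @ (X.T @ (X * (w**2)[:, None]))))
    denom = float(np.sum(w)) - trace_term
    if denom <= 0:
        warnings.warn("degenerate DL denominator; tau^2 set to 0", stacklevel=2)
        return 0.0
    return max(0.0, (q - (k - p)) / denom)


def _reml_tau_squared(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Restricted maximum-likelihood tau^2 (config alternative to DL)."""

    def neg_restricted_ll(log_tau2: float) -> float:
        t2 = math.exp(log_tau2)
        w = 1.0 / (v + t2)
        beta, cov, q = _wls(y, X, w)
        sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        return 0.5 * (np.sum(np.log(v + t2)) + logdet + q)

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-12.0, 6.0), method="bounded")
    t2 = math.exp(res.x)
    return 0.0 if t2 < 1e-10 else t2


def fit_remr(
    dataset: MetaDataset,
    tau2_method: str = "DL",
    knapp_hartung: bool = False,
) -> MetaRegressionResult:
    """Fit the random-effects meta-regression for one proxy and one outcome."""
    y, v, X = np.asarray(dataset.y, float), np.asarray(dataset.v, float), np.asarray(dataset.X, float)
    _check_collinear(X, dataset.columns)
    if tau2_method == "DL":
        tau2 = dl_tau_squared(y, v, X)
    elif tau2_method == "REML":
        tau2 = _reml_tau_squared(y, v, X)
    else:
        raise ConfigError(f"unknown tau2 method {tau2_method!r}")

    w = 1.0 / (v + tau2)
    beta, cov, q_res = _wls(y, X, w)
    k, p = X.shape
    if knapp_hartung:
        s2 = max(q_res / (k - p), 1.0)  # metareg-style truncation at 1
        se = np.sqrt(np.diag(cov) * s2)
        z = beta / se
        pval = 2.0 * stats.t.sf(np.abs(z), df=k - p)
    else:
        se = np.sqrt(np.diag(cov))
        z = beta / se
        pval = 2.0 * stats.norm.sf(np.abs(z))
    return MetaRegressionResult(
        columns=list(dataset.columns), beta=beta, se_beta=se, z=z,
        p_value=pval, tau2=float(tau2), q_residual=float(q_res), weights=w,
        proxy=dataset.proxy, outcome=dataset.outcome,
        method=("KH-" if knapp_hartung else "") + tau2_method,
    )


def report_relative_increase(result: MetaRegressionResult, mean_agsd: float) -> dict:
    """Proxy effect as a percentage of the population-average AGSD.

    Returns the percent change in the additive genetic SD per one proxy unit
    (100 * beta_proxy / mean AGSD) and its 10-unit extrapolation.
    """
    if not mean_agsd > 0:
        raise ConfigError("mean AGSD must be positive")
    beta = result.coef("proxy")
    per_unit = 100.0 * beta / mean_agsd
    return {
        "beta_proxy": beta,
        "mean_agsd": mean_agsd,
        "pct_per_unit": per_unit,
        "pct_per_10_units": 10.0 * per_unit,
    }


def meta_table(results: dict) -> pd.DataFrame:
    """Arrange fitted models into the published two-outcome layout.

    ``results`` maps (proxy, outcome) -> MetaRegressionResult; the output has
    one row per moderator within each proxy model and estimate / p-value
    columns for the A-SD and E-SD regressions.
    """
    rows = []
    for proxy in PROXIES:
        if (proxy, "A") not in results and (proxy, "E") not in results:
            continue
        ra = results.get((proxy, "A"))
        re_ = results.get((proxy, "E"))
        terms = (ra or re_).columns
        for term in terms:
            if term == "intercept":
                continue
            rows.append(
                {
                    "proxy_model": proxy,
                    "term": term,
                    "a_estimate": ra.coef(term) if ra else math.nan,
                    "a_p_value": ra.pval(term) if ra else math.nan,
                    "e_estimate": re_.coef(term) if re_ else math.nan,
                    "e_p_value": re_.pval(term) if re_ else math.nan,
                }
            )
    return pd.DataFrame(rows)
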