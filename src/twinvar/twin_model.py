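"""Maximum-likelihood variance decomposition of BMI for one stratum.

The classical twin design: monozygotic (MZ) co-twins share all segregating
genes, dizygotic (DZ) co-twins half on average, so the pattern of within-pair
covariance across the two zygosity groups identifies additive genetic (A),
shared environmental (C) or dominance (D), and unique environmental (E)
variance components.  For a pair with phenotypes (x1, x2) the model is a
bivariate normal with common mean (mu, mu) and covariance

    [[V, Czyg], [Czyg, V]],   V = var_A + var_C + var_D + var_E,
    C_MZ = var_A + var_C + var_D,   C_DZ = var_A/2 + var_C + var_D/4.

Estimation is full-information maximum likelihood on raw data: complete pairs
contribute the bivariate density, twins without a responding co-twin the
univariate N(mu, V) density.  Components are parameterized as squared path
coefficients so non-negativity is structural; the additive path coefficient's
magnitude equals the additive genetic standard deviation (AGSD), and its
curvature-based standard error is the AGSD standard error carried into the
meta-regression.

For speed the log-likelihood is evaluated in closed form from per-zygosity
sufficient statistics; this is algebraically identical to summing per-pair
densities (tested against an independent per-pair oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, DataError
from .types import VarianceFit

MODELS = ("ACE", "ADE", "AE", "E")

_LOG2PI = math.log(2.0 * math.pi)

#: Coefficient of additive genetic sharing for DZ twins (full siblings).
DZ_ADDITIVE_SHARE = 0.5
#: Coefficient of dominance sharing for DZ twins (full siblings).
DZ_DOMINANCE_SHARE = 0.25


@dataclass
class ZygosityData:
    """Sufficient statistics for one zygosity group within a stratum."""

    n_pairs: int = 0
    sum_pair: float = 0.0    # sum over pairs of (x1 + x2)
    sum_sq: float = 0.0      # sum over pairs of (x1^2 + x2^2)
    sum_cross: float = 0.0   # sum over pairs of x1 * x2
    n_singles: int = 0
    sum_single: float = 0.0
    sum_single_sq: float = 0.0

    @classmethod
    def from_arrays(
        cls,
        x1: Sequence[float],
        x2: Sequence[float],
        singles: Optional[Sequence[float]] = None,
    ) -> "ZygosityData":
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if x1.shape != x2.shape:
            raise DataError("co-twin arrays differ in length")
        s = np.asarray(singles, dtype=float) if singles is not None else np.empty(0)
        return cls(
            n_pairs=int(x1.size),
            sum_pair=float(np.sum(x1) + np.sum(x2)),
            sum_sq=float(np.sum(x1 * x1) + np.sum(x2 * x2)),
            sum_cross=float(np.sum(x1 * x2)),
            n_singles=int(s.size),
            sum_single=float(np.sum(s)),
            sum_single_sq=float(np.sum(s * s)),
        )

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_pairs + self.n_singles

    def pair_covariance_moments(self) -> Tuple[float, float, float]:
        """(mean, variance, within-pair covariance) treating pairs as unordered."""
        if self.n_pairs == 0:
            return math.nan, math.nan, math.nan
        m = self.sum_pair / (2 * self.n_pairs)
        var = self.sum_sq / (2 * self.n_pairs) - m * m
        cov = self.sum_cross / self.n_pairs - m * m
        return m, var, cov


def pair_covariance(model: str, zygosity: str, params: Dict[str, float]) -> np.ndarray:
    """2x2 covariance structure implied by a model for one zygosity.

    ``params`` holds the *variance* components active in the model
    (``var_a``, ``var_c``, ``var_d``, ``var_e``).
    """
    if model not in MODELS:
        raise ConfigError(f"unknown model {model!r}")
    va = params.get("var_a", 0.0)
    vc = params.get("var_c", 0.0)
    vd = params.get("var_d", 0.0)
    ve = params.get("var_e", 0.0)
    if model == "AE":
        vc = vd = 0.0
    elif model == "ACE":
        vd = 0.0
    elif model == "ADE":
        vc = 0.0
    elif model == "E":
        va = vc = vd = 0.0
    total = va + vc + vd + ve
    if zygosity == "MZ":
        off = va + vc + vd
    elif zygosity in ("DZ", "DZ_same_sex"):
        off = DZ_ADDITIVE_SHARE * va + vc + DZ_DOMINANCE_SHARE * vd
    else:
        raise ConfigError(f"unknown zygosity {zygosity!r} for twin covariance")
    return np.array([[total, off], [off, total]])


def _group_loglik(mu: float, total: float, off: float, z: ZygosityData) -> float:
    """Closed-form normal log-likelihood for one zygosity group."""
    ll = 0.0
    if z.n_pairs:
        det = total * total - off * off
        if det <= 0.0 or total <= 0.0:
            return -math.inf
        n = z.n_pairs
        q_diag = z.sum_sq - 2.0 * mu * z.sum_pair + 2.0 * n * mu * mu
        q_cross = z.sum_cross - mu * z.sum_pair + n * mu * mu
        ll += -n * _LOG2PI - 0.5 * n * math.log(det) \
              - 0.5 * (total * q_diag - 2.0 * off * q_cross) / det
    if z.n_singles:
        if total <= 0.0:
            return -math.inf
        m = z.n_singles
        q = z.sum_single_sq - 2.0 * mu * z.sum_single + m * mu * mu
        ll += -0.5 * m * (_LOG2PI + math.log(total)) - 0.5 * q / total
    return ll


def loglik_stratum(
    mz: ZygosityData,
    dz: ZygosityData,
    model: str,
    mu: float,
    params: Dict[str, float],
    mu_dz: Optional[float] = None,
) -> float:
    """Raw-data log-likelihood of one stratum under a variance-component model.

    Complete pairs contribute bivariate-normal densities, singletons the
    univariate N(mu, total variance) density.  ``mu_dz`` enables the optional
    zygosity-specific-means sensitivity parameterization.
    """
    if mz.n_pairs + dz.n_pairs + mz.n_singles + dz.n_singles == 0:
        raise DataError("empty stratum")
    cov_mz = pair_covariance(model, "MZ", params)
    cov_dz = pair_covariance(model, "DZ", params)
    return _group_loglik(mu, cov_mz[0, 0], cov_mz[0, 1], mz) + _group_loglik(
        mu if mu_dz is None else mu_dz, cov_dz[0, 0], cov_dz[0, 1], dz
    )


# ---------------------------------------------------------------------------
# fitting


_MODEL_PATHS = {"E": ("e",), "AE": ("a", "e"), "ACE": ("a", "c", "e"), "ADE": ("a", "d", "e")}

#: off-diagonal loading of each path's variance for (MZ, DZ) pairs
_PATH_SHARES = {
    "a": (1.0, DZ_ADDITIVE_SHARE),
    "c": (1.0, 1.0),
    "d": (1.0, DZ_DOMINANCE_SHARE),
    "e": (0.0, 0.0),
}


def _group_ll_and_derivs(mu: float, V: float, C: float, z: ZygosityData):
    """(loglik, d/dmu, d/dV, d/dC) for one zygosity group, in closed form."""
    ll = dmu = dV = dC = 0.0
    if z.n_pairs:
        det = V * V - C * C
        if det <= 0.0 or V <= 0.0:
            return None
        n = z.n_pairs
        qd = z.sum_sq - 2.0 * mu * z.sum_pair + 2.0 * n * mu * mu
        qc = z.sum_cross - mu * z.sum_pair + n * mu * mu
        num = V * qd - 2.0 * C * qc
        ll += -n * _LOG2PI - 0.5 * n * math.log(det) - 0.5 * num / det
        qd_mu = -2.0 * z.sum_pair + 4.0 * n * mu
        qc_mu = -z.sum_pair + 2.0 * n * mu
        dmu += -0.5 * (V * qd_mu - 2.0 * C * qc_mu) / det
        dV += -n * V / det - 0.5 * qd / det + num * V / (det * det)
        dC += n * C / det + qc / det - num * C / (det * det)
    if z.n_singles:
        if V <= 0.0:
            return None
        m = z.n_singles
        q = z.sum_single_sq - 2.0 * mu * z.sum_single + m * mu * mu
        ll += -0.5 * m * (_LOG2PI + math.log(V)) - 0.5 * q / V
        dmu += (z.sum_single - m * mu) / V
        dV += -0.5 * m / V + 0.5 * q / (V * V)
    return ll, dmu, dV, dC


def _variances_from_paths(model: str, paths: Sequence[float]) -> Dict[str, float]:
    names = _MODEL_PATHS[model]
    out = {"var_a": 0.0, "var_c": 0.0, "var_d": 0.0, "var_e": 0.0}
    for name, val in zip(names, paths):
        out["var_" + name] = val * val
    return out


def _neg_loglik_factory(mz: ZygosityData, dz: ZygosityData, model: str,
                        zygosity_specific_means: bool):
    """Fast scalar negative log-likelihood and its analytic gradient.

    Parameter vector: (mu[, mu_dz], path coefficients); the gradient chains
    the closed-form (V, C) derivatives through var = path^2.
    """
    n_mu = 2 if zygosity_specific_means else 1
    shares = [_PATH_SHARES[p] for p in _MODEL_PATHS[model]]
    big = 1e12

    def neg_ll(theta: np.ndarray) -> float:
        paths = theta[n_mu:]
        V = float(np.dot(paths, paths))
        c_mz = sum(s[0] * x * x for s, x in zip(shares, paths))
        c_dz = sum(s[1] * x * x for s, x in zip(shares, paths))
        g_mz = _group_ll_and_derivs(theta[0], V, c_mz, mz)
        g_dz = _group_ll_and_derivs(theta[n_mu - 1], V, c_dz, dz)
        if g_mz is None or g_dz is None:
            return big
        return -(g_mz[0] + g_dz[0])

    def neg_ll_grad(theta: np.ndarray) -> np.ndarray:
        paths = theta[n_mu:]
        V = float(np.dot(paths, paths))
        c_mz = sum(s[0] * x * x for s, x in zip(shares, paths))
        c_dz = sum(s[1] * x * x for s, x in zip(shares, paths))
        g_mz = _group_ll_and_derivs(theta[0], V, c_mz, mz)
        g_dz = _group_ll_and_derivs(theta[n_mu - 1], V, c_dz, dz)
        grad = np.zeros_like(theta)
        if g_mz is None or g_dz is None:
            return grad
        if n_mu == 1:
            grad[0] = -(g_mz[1] + g_dz[1])
        else:
            grad[0] = -g_mz[1]
            grad[1] = -g_dz[1]
        for i, (s, x) in enumerate(zip(shares, paths)):
            d = (g_mz[2] + g_dz[2]) + s[0] * g_mz[3] + s[1] * g_dz[3]
            grad[n_mu + i] = -2.0 * x * d
        return grad

    return neg_ll, neg_ll_grad, n_mu


def _moment_starts(mz: ZygosityData, dz: ZygosityData, model: str) -> list:
    """Deterministic starting points from moment estimators plus perturbations."""
    n_ind = mz.n_individuals + dz.n_individuals
    grand = (mz.sum_pair + mz.sum_single + dz.sum_pair + dz.sum_single) / max(n_ind, 1)
    _, var_mz, cov_mz = mz.pair_covariance_moments()
    _, var_dz, cov_dz = dz.pair_covariance_moments()
    var_tot = np.nanmean([var_mz, var_dz])
    if not math.isfinite(var_tot) or var_tot <= 0:
        var_tot = 1.0
    cov_mz = cov_mz if math.isfinite(cov_mz) else 0.5 * var_tot
    cov_dz = cov_dz if math.isfinite(cov_dz) else 0.25 * var_tot

    floor = 1e-3 * var_tot
    va = max(2.0 * (cov_mz - cov_dz), floor)
    ve = max(var_tot - cov_mz, floor)
    if model == "E":
        base = [math.sqrt(var_tot)]
    elif model == "AE":
        base = [math.sqrt(min(va, var_tot)), math.sqrt(ve)]
    elif model == "ACE":
        vc = max(2.0 * cov_dz - cov_mz, floor)
        base = [math.sqrt(min(va, var_tot)), math.sqrt(vc), math.sqrt(ve)]
    else:  # ADE
        va_ade = max(4.0 * cov_dz - cov_mz, floor)
        vd = max(2.0 * cov_mz - 4.0 * cov_dz, floor)
        base = [math.sqrt(min(va_ade, var_tot)), math.sqrt(vd), math.sqrt(ve)]

    starts = [[grand] + base]
    # two fixed perturbed starts guard against a bad moment estimate
    for f in (0.5, 1.5):
        starts.append([grand] + [f * b if i == 0 else b for i, b in enumerate(base)])
    return starts


def fit_variance_model(
    mz: ZygosityData,
    dz: ZygosityData,
    model: str = "AE",
    zygosity_specific_means: bool = False,
    compute_se: bool = True,
) -> VarianceFit:
    """Fit one variance-component model to a stratum by maximum likelihood.

    Deterministic multi-start: moment-based starting values (mu = grand mean,
    var_A = 2(cov_MZ - cov_DZ) clipped to >= 0, var_E = remainder) plus two
    fixed perturbations; Nelder-Mead followed by a BFGS polish, best
    log-likelihood kept.  Standard errors from the observed information
    (central-difference Hessian) in the path-coefficient parameterization.
    """
    if model not in MODELS:
        raise ConfigError(f"unknown model {model!r}")
    if model != "E" and (mz.n_pairs < 2 or dz.n_pairs < 2):
        return _invalid_fit(model, mz, dz, "too few complete pairs to identify the model")

    neg_ll, neg_ll_grad, n_mu = _neg_loglik_factory(mz, dz, model, zygosity_specific_means)
    starts = _moment_starts(mz, dz, model)
    if zygosity_specific_means:
        starts = [[s[0]] + s for s in starts]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 500},
        )
        polish = optimize.minimize(neg_ll, res.x, jac=neg_ll_grad, method="BFGS",
                                   options={"gtol": 1e-8, "maxiter": 200})
        cand = polish if polish.fun <= res.fun else res
        if best is None or cand.fun < best.fun - 0.0:
            best = cand
    if best is None or not math.isfinite(best.fun):
        return _invalid_fit(model, mz, dz, "optimizer failed to converge")

    theta = best.x
    params = _variances_from_paths(model, theta[n_mu:])
    loglik = -best.fun
    agsd = abs(theta[n_mu]) if model != "E" else 0.0
    e_idx = n_mu + len(_MODEL_PATHS[model]) - 1
    esd = abs(theta[e_idx])

    agsd_se = esd_se = math.nan
    se_valid = False
    boundary = bool(params["var_a"] < 1e-6 * max(params["var_e"], 1e-12)) and model != "E"
    if compute_se:
        cov = _observed_information_cov(neg_ll, theta)
        if cov is not None:
            a_idx = n_mu if model != "E" else None
            if a_idx is not None and cov[a_idx, a_idx] > 0:
                agsd_se = math.sqrt(cov[a_idx, a_idx])
                se_valid = True
            if cov[e_idx, e_idx] > 0:
                esd_se = math.sqrt(cov[e_idx, e_idx])
            if model == "E":
                se_valid = cov[e_idx, e_idx] > 0
        if boundary:
            se_valid = False  # curvature SE of sqrt(var_A) unreliable at the boundary

    return VarianceFit(
        model=model,
        mu=float(theta[0]),
        var_a=params["var_a"],
        var_c=params["var_c"],
        var_d=params["var_d"],
        var_e=params["var_e"],
        agsd=float(agsd),
        agsd_se=float(agsd_se),
        esd=float(esd),
        esd_se=float(esd_se),
        loglik=float(loglik),
        n_pairs_mz=mz.n_pairs,
        n_pairs_dz=dz.n_pairs,
        converged=True,
        se_valid=se_valid,
        boundary=boundary,
    )


def _invalid_fit(model: str, mz: ZygosityData, dz: ZygosityData, reason: str) -> VarianceFit:
    nan = math.nan
    return VarianceFit(
        model=model, mu=nan, var_a=nan, var_c=nan, var_d=nan, var_e=nan,
        agsd=nan, agsd_se=nan, esd=nan, esd_se=nan, loglik=nan,
        n_pairs_mz=mz.n_pairs, n_pairs_dz=dz.n_pairs,
        converged=False, se_valid=False, notes=reason,
    )


def _observed_information_cov(neg_ll, theta: np.ndarray, rel_step: float = 1e-4):
    """Inverse of the central-difference Hessian of the negative log-likelihood."""
    k = len(theta)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = neg_ll(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (neg_ll(theta + ei) - 2.0 * f0 + neg_ll(theta - ei)) / (h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                neg_ll(theta + ei + ej) - neg_ll(theta + ei - ej)
                - neg_ll(theta - ei + ej) + neg_ll(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def agsd_standard_error(fit: VarianceFit) -> float:
    """Standard error of the additive genetic SD from a converged fit.

    Raises :class:`DataError` when the information matrix was singular or the
    fit sits on the var_A = 0 boundary (the stratum then carries no defined
    meta-regression weight and is excluded upstream).
    """
    if not fit.converged:
        raise DataError("fit did not converge")
    if not fit.se_valid or not math.isfinite(fit.agsd_se):
        raise DataError("AGSD standard error unavailable (singular Hessian or boundary fit)")
    return fit.agsd_se


# ---------------------------------------------------------------------------
# model comparison


def fit_all_models(mz: ZygosityData, dz: ZygosityData, **kw) -> Dict[str, VarianceFit]:
    return {m: fit_variance_model(mz, dz, m, **kw) for m in MODELS}


def select_model(
    fits: Dict[str, VarianceFit],
    alpha: float = 0.05,
    boundary_mixture: bool = False,
    force: Optional[str] = None,
) -> str:
    """Pick the most parsimonious adequately fitting model.

    ACE and ADE (same parameter count) are compared by log-likelihood; the
    shared component of the winner is then tested by a likelihood-ratio test
    against chi^2(1), and if dropping it is not rejected the same test is
    applied to A (AE vs E).  ``boundary_mixture`` applies the 50:50
    chi^2(0):chi^2(1) boundary correction to the LRT p-values; the default is
    the plain chi^2 reference, matching classic Mx practice.  ``force``
    returns a fixed label regardless (the AE-everywhere policy).
    """
    if force is not None:
        if force not in MODELS:
            raise ConfigError(f"cannot force unknown model {force!r}")
        return force
    for m in MODELS:
        if m not in fits:
            raise ConfigError(f"missing fit for model {m}")

    def lrt_p(full: VarianceFit, reduced: VarianceFit) -> float:
        stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
        p = float(stats.chi2.sf(stat, df=1))
        return 0.5 * p if boundary_mixture else p

    full = "ACE" if fits["ACE"].loglik >= fits["ADE"].loglik else "ADE"
    if lrt_p(fits[full], fits["AE"]) < alpha:
        return full
    if lrt_p(fits["AE"], fits["E"]) < alpha:
        return "AE"
    return "E"


def heritability(fit: VarianceFit) -> float:
    """Proportion of phenotypic variance that is additive genetic: A / (A+C+D+E)."""
    return fit.heritability
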