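"""Maximum-likelihood mixed models via Gauss–Hermite quadrature.

Two generalised linear mixed models are fitted by direct maximisation of the
marginal likelihood, with the random intercepts integrated out by
Gauss–Hermite quadrature (a deterministic, arbitrarily accurate alternative to
the Laplace approximation at this problem size):

* negative-binomial (NB2, log link) with a colony random intercept, for total
  revisits;
* binomial (logit link) with bee-nested-in-colony random intercepts, for the
  per-choice success indicators.

The Gaussian model on log time-per-visit delegates to statsmodels ``MixedLM``
fitted by ML (not REML) so that AICs are comparable across fixed-effect
structures. Fixed-effect standard errors are conditional on the variance
parameters at their ML estimates, the usual mixed-model convention.

AIC parameter counts: fixed effects + one per random-effect variance + one
dispersion (NB) or residual variance (Gaussian).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import gammaln, logsumexp

from ..errors import RamForageError
from .models import FitResult, ModelSpec, build_design

__all__ = ["fit_nb_glmm", "fit_binomial_glmm", "fit_lmm_log_time"]

logger = logging.getLogger(__name__)

_GH_POINTS = 15
#: |coefficient| at/above which a logistic fit is flagged as separated
SEPARATION_CLAMP = 12.0
_BETA_BOUND = 15.0


def _gh_nodes(n: int = _GH_POINTS) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = hermgauss(n)
    return nodes, np.log(weights) - 0.5 * np.log(np.pi)


def _group_slices(codes: np.ndarray) -> np.ndarray:
    """reduceat boundaries for contiguous group codes."""
    return np.flatnonzero(np.r_[True, np.diff(codes) != 0])


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = x.size
    h = np.zeros((p, p))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def _beta_ses(nll_beta, beta_hat: np.ndarray) -> np.ndarray:
    hess = _numeric_hessian(nll_beta, beta_hat)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
        if np.any(~np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.abs(np.diag(cov)))
    return se


def _nb2_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 log-pmf, Var = mu + alpha * mu^2."""
    r = 1.0 / alpha
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def fit_nb_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    response_col: str = "total_revisits",
    group_col: str = "colony",
    gh_points: int = _GH_POINTS,
) -> FitResult:
    """NB2 mixed model with log link and a colony random intercept (ML).

    Parameters are the fixed effects, the NB dispersion alpha and the colony
    intercept SD, all estimated jointly by quadrature-integrated ML.
    """
    df = data.sort_values(group_col, kind="stable").reset_index(drop=True)
    y = df[response_col].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise RamForageError("NB response must be non-negative integers")
    X, names = build_design(df, spec.fixed)
    codes = pd.factorize(df[group_col])[0]
    starts = _group_slices(codes)
    nodes, logw = _gh_nodes(gh_points)
    p = X.shape[1]

    def nll(theta: np.ndarray) -> float:
        beta, log_alpha, log_sigma = theta[:p], theta[p], theta[p + 1]
        alpha = np.exp(log_alpha)
        sigma = np.exp(log_sigma)
        eta0 = X @ beta
        u = np.sqrt(2.0) * sigma * nodes
        mu = np.exp(np.clip(eta0[:, None] + u[None, :], -30.0, 30.0))
        lp = _nb2_logpmf(y[:, None], mu, alpha)
        per_group = np.add.reduceat(lp, starts, axis=0)  # (G, K)
        return -float(np.sum(logsumexp(per_group + logw[None, :], axis=1)))

    x0 = np.zeros(p + 2)
    if "intercept" in names:
        x0[names.index("intercept")] = np.log(y.mean() + 0.1)
    x0[p] = np.log(0.5)
    x0[p + 1] = np.log(0.2)
    bounds = [(-_BETA_BOUND, _BETA_BOUND)] * p + [(-10.0, 5.0), (-8.0, 3.0)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    beta_hat = res.x[:p]
    se = _beta_ses(lambda b: nll(np.r_[b, res.x[p:]]), beta_hat)
    converged = bool(res.success) and np.all(np.abs(beta_hat) < SEPARATION_CLAMP)
    if not res.success:
        logger.warning("NB GLMM %s did not converge: %s", spec.name, res.message)
    return FitResult(
        spec=spec,
        loglik=-float(res.fun),
        k=p + 2,
        params=pd.Series(beta_hat, index=names),
        bse=pd.Series(se, index=names),
        converged=converged,
        n_obs=len(df),
        extra={"alpha": float(np.exp(res.x[p])), "colony_sd": float(np.exp(res.x[p + 1]))},
    )


def fit_binomial_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    response_col: str = "success",
    colony_col: str = "colony",
    bee_col: str = "bee_id",
    gh_points: int = 12,
) -> FitResult:
    """Binomial mixed model, logit link, bee nested within colony (ML).

    ``data`` is long format: one row per choice with a 0/1 response and
    bee-level covariates repeated. Complete separation (e.g. all successes) is
    flagged via ``converged=False`` with the coefficient held at the bound.
    """
    df = data.sort_values([colony_col, bee_col], kind="stable").reset_index(drop=True)
    y = df[response_col].to_numpy(dtype=float)
    X, names = build_design(df, spec.fixed)
    bee_codes = pd.factorize(df[colony_col].astype(str) + "/" + df[bee_col].astype(str))[0]
    bee_starts = _group_slices(bee_codes)
    colony_of_bee = pd.factorize(df[colony_col])[0][bee_starts]
    col_starts = _group_slices(colony_of_bee)
    nodes, logw = _gh_nodes(gh_points)
    sign = 2.0 * y - 1.0
    p = X.shape[1]

    def nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        sig_c, sig_b = np.exp(theta[p]), np.exp(theta[p + 1])
        eta0 = X @ beta
        u = np.sqrt(2.0) * sig_c * nodes
        v = np.sqrt(2.0) * sig_b * nodes
        per_colony = np.empty((col_starts.size, nodes.size))
        for ki in range(nodes.size):
            eta = eta0[:, None] + u[ki] + v[None, :]
            lp = -np.logaddexp(0.0, -sign[:, None] * eta)  # (n_obs, K_inner)
            per_bee = np.add.reduceat(lp, bee_starts, axis=0)
            bee_ll = logsumexp(per_bee + logw[None, :], axis=1)  # (n_bees,)
            per_colony[:, ki] = np.add.reduceat(bee_ll, col_starts)
        return -float(np.sum(logsumexp(per_colony + logw[None, :], axis=1)))

    x0 = np.zeros(p + 2)
    if "intercept" in names:
        pbar = min(max(y.mean(), 1e-3), 1 - 1e-3)
        x0[names.index("intercept")] = np.log(pbar / (1 - pbar))
    x0[p:] = np.log(0.3)
    bounds = [(-_BETA_BOUND, _BETA_BOUND)] * p + [(-8.0, 3.0)] * 2
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    beta_hat = res.x[:p]
    se = _beta_ses(lambda b: nll(np.r_[b, res.x[p:]]), beta_hat)
    separated = np.any(np.abs(beta_hat) >= SEPARATION_CLAMP)
    if separated:
        logger.warning("binomial GLMM %s: separation detected, estimate at bound", spec.name)
    return FitResult(
        spec=spec,
        loglik=-float(res.fun),
        k=p + 2,
        params=pd.Series(beta_hat, index=names),
        bse=pd.Series(se, index=names),
        converged=bool(res.success) and not separated,
        n_obs=len(df),
        extra={
            "colony_sd": float(np.exp(res.x[p])),
            "bee_sd": float(np.exp(res.x[p + 1])),
            "separated": bool(separated),
        },
    )


def fit_lmm_log_time(
    data: pd.DataFrame,
    spec: ModelSpec,
    response_col: str = "time_per_visit_s",
    group_col: str = "colony",
    log_response: bool = True,
) -> FitResult:
    """Gaussian mixed model on log time-per-visit, colony intercept, ML fit.

    The marginal likelihood of a random-intercept Gaussian model is available
    in closed form (compound-symmetry covariance per colony); it is maximised
    directly over the fixed effects and the two variance components, by ML
    rather than REML so AICs are comparable across fixed-effect structures.
    """
    df = data.dropna(subset=[response_col]).reset_index(drop=True)
    yraw = df[response_col].to_numpy(dtype=float)
    if log_response:
        if np.any(yraw <= 0):
            raise RamForageError("time per visit must be positive for the log transform")
        y = np.log(yraw)
    else:
        y = yraw
    X, names = build_design(df, spec.fixed)
    codes = pd.factorize(df.sort_values(group_col, kind="stable")[group_col])[0]
    order = df.sort_values(group_col, kind="stable").index.to_numpy()
    y_s, X_s = y[order], X[order]
    starts = _group_slices(codes)
    group_sizes = np.diff(np.r_[starts, codes.size])
    p = X.shape[1]

    def nll(theta: np.ndarray) -> float:
        beta, log_tau, log_sig = theta[:p], theta[p], theta[p + 1]
        tau2, sig2 = np.exp(2 * log_tau), np.exp(2 * log_sig)
        resid = y_s - X_s @ beta
        ll = 0.0
        for start, m in zip(starts, group_sizes):
            r = resid[start : start + m]
            # Woodbury/determinant identities for sig2*I + tau2*J
            s = r.sum()
            quad = (r @ r) / sig2 - tau2 * s * s / (sig2 * (sig2 + m * tau2))
            logdet = (m - 1) * np.log(sig2) + np.log(sig2 + m * tau2)
            ll += -0.5 * (m * np.log(2 * np.pi) + logdet + quad)
        return -ll

    beta0 = np.linalg.lstsq(X_s, y_s, rcond=None)[0]
    resid0 = y_s - X_s @ beta0
    s0 = max(resid0.std(), 1e-3)
    x0 = np.r_[beta0, np.log(s0 / 2), np.log(s0)]
    bounds = [(None, None)] * p + [(-10.0, 5.0), (-10.0, 5.0)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    beta_hat = res.x[:p]
    se = _beta_ses(lambda b: nll(np.r_[b, res.x[p:]]), beta_hat)
    if not res.success:
        logger.warning("LMM %s did not converge: %s", spec.name, res.message)
    return FitResult(
        spec=spec,
        loglik=-float(res.fun),
        k=p + 2,  # + colony variance + residual variance
        params=pd.Series(beta_hat, index=names),
        bse=pd.Series(se, index=names),
        converged=bool(res.success),
        n_obs=len(df),
        extra={
            "colony_var": float(np.exp(2 * res.x[p])),
            "resid_var": float(np.exp(2 * res.x[p + 1])),
        },
    )
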