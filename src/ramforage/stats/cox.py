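"""Cox proportional hazards on the choice index of the first revisit.

Event times are small integers (choice 2..8) and heavily tied, so the partial
likelihood uses the Efron tie correction. The fitter maximises the partial
likelihood directly with scipy, which keeps offsets and strata under our
control; lifelines serves as an independent cross-check in the test suite and
provides the Kaplan–Meier product-limit curves.

The "basic" candidate model has no covariates: its log partial likelihood is
evaluated at the empty coefficient vector and it contributes k = 0 parameters
to AIC.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from ..errors import NoEventsError
from .glmm import _beta_ses
from .models import FitResult, ModelSpec, build_design

__all__ = ["efron_log_partial_likelihood", "fit_coxph", "kaplan_meier"]

logger = logging.getLogger(__name__)

_MONOTONE_BOUND = 10.0


def _efron_ll_and_grad(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    offset: Optional[np.ndarray] = None,
    strata: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Efron-tied log partial likelihood and its gradient."""
    beta = np.asarray(beta, dtype=float)
    p = X.shape[1] if X.ndim == 2 else 0
    eta = (X @ beta if p else np.zeros(len(time))) + (
        offset if offset is not None else 0.0
    )
    if strata is None:
        strata = np.zeros(len(time), dtype=int)
    ll = 0.0
    grad = np.zeros(p)
    for s in np.unique(strata):
        in_s = strata == s
        t_s, e_s, eta_s = time[in_s], event[in_s].astype(bool), eta[in_s]
        X_s = X[in_s] if p else np.zeros((in_s.sum(), 0))
        c = eta_s.max() if eta_s.size else 0.0
        w = np.exp(eta_s - c)
        for t in np.unique(t_s[e_s]):
            dead = e_s & (t_s == t)
            at_risk = t_s >= t
            d = int(dead.sum())
            s_risk = w[at_risk].sum()
            s_dead = w[dead].sum()
            ll += float(eta_s[dead].sum())
            if p:
                v_risk = w[at_risk] @ X_s[at_risk]
                v_dead = w[dead] @ X_s[dead]
                grad += X_s[dead].sum(axis=0)
            for l in range(d):
                frac = l / d
                denom = s_risk - frac * s_dead
                ll -= float(np.log(denom) + c)
                if p:
                    grad -= (v_risk - frac * v_dead) / denom
    return ll, grad


def efron_log_partial_likelihood(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    offset: Optional[np.ndarray] = None,
    strata: Optional[np.ndarray] = None,
) -> float:
    """Log partial likelihood with Efron's correction for tied event times."""
    return _efron_ll_and_grad(beta, X, time, event, offset, strata)[0]


def fit_coxph(
    data: pd.DataFrame,
    spec: ModelSpec,
    time_col: str = "time",
    event_col: str = "event",
    colony: str = "none",
    colony_col: str = "colony",
) -> FitResult:
    """Cox PH fit by direct Efron partial-likelihood maximisation.

    ``colony`` ∈ {"none", "strata"}: how the colony grouping enters (the
    package default is no colony term; stratification is the alternative).
    Returns hazard ratios ``exp(b)`` in ``extra["hazard_ratios"]``.
    """
    df = data.reset_index(drop=True)
    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=bool)
    if event.sum() == 0:
        raise NoEventsError("Cox fit requires at least one observed event")
    if colony == "strata":
        strata = pd.factorize(df[colony_col])[0]
    elif colony == "none":
        strata = None
    else:
        raise ValueError(f"colony must be 'none' or 'strata', got {colony!r}")
    X, names = build_design(df, spec.fixed, intercept=False)
    p = X.shape[1]

    def nll_grad(beta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _efron_ll_and_grad(beta, X, time, event, strata=strata)
        return -ll, -g

    def nll(beta: np.ndarray) -> float:
        return nll_grad(beta)[0]

    if p == 0:
        loglik = -nll(np.zeros(0))
        return FitResult(
            spec=spec, loglik=loglik, k=0,
            params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            converged=True, n_obs=len(df), extra={"hazard_ratios": pd.Series(dtype=float)},
        )
    res = optimize.minimize(nll_grad, np.zeros(p), jac=True, method="BFGS", options={"gtol": 1e-7})
    beta_hat = res.x
    se = _beta_ses(nll, beta_hat)
    grad_ok = bool(np.max(np.abs(nll_grad(beta_hat)[1])) < 1e-4 * max(1.0, abs(res.fun)))
    monotone = bool(np.any(np.abs(beta_hat) > _MONOTONE_BOUND))
    if monotone:
        logger.warning("Cox fit %s: monotone likelihood suspected (|b| > %.0f)", spec.name, _MONOTONE_BOUND)
    return FitResult(
        spec=spec,
        loglik=-float(res.fun),
        k=p,
        params=pd.Series(beta_hat, index=names),
        bse=pd.Series(se, index=names),
        converged=(bool(res.success) or grad_ok) and not monotone,
        n_obs=len(df),
        extra={"hazard_ratios": pd.Series(np.exp(beta_hat), index=names), "colony": colony},
    )


def kaplan_meier(
    data: pd.DataFrame,
    group_col: str = "treatment",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Product-limit survival curves per group with Greenwood standard errors.

    Returns a tidy step-function table: group, time, n_at_risk, n_events,
    survival, se.
    """
    from lifelines import KaplanMeierFitter

    frames = []
    for group, grp in data.groupby(group_col, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(grp[time_col], event_observed=grp[event_col].astype(bool))
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
        d = table["observed"].to_numpy(dtype=float)
        n = table["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
        se = surv.to_numpy() * np.sqrt(np.cumsum(inc))
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "time": table.index.to_numpy(),
                    "n_at_risk": n.astype(int),
                    "n_events": d.astype(int),
                    "survival": surv.to_numpy(),
                    "se": se,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
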