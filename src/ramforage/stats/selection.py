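"""AIC model selection, Akaike weights, model averaging and the size split.

Models within two AIC units of the best model form the "best set". When the
best set holds more than one model, coefficients are model-averaged with
Akaike weights renormalised within the set. Averaging is *conditional* by
default — each coefficient is averaged only over best-set models that contain
it — with full averaging (absent coefficients counted as zero) available by
flag; results carry a label saying which was used. The unconditional standard
error is Burnham & Anderson's

    SE = sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..errors import RamForageError
from .models import FitResult, ModelSpec, build_candidate_set

__all__ = [
    "SelectionTable",
    "akaike_weights",
    "wald_ci",
    "hazard_ratio",
    "select_and_average",
    "size_split_analysis",
]

logger = logging.getLogger(__name__)

#: models within this many AIC units of the best form the averaging set
BEST_SET_DELTA = 2.0


@dataclass
class SelectionTable:
    """Per-model AIC, ΔAIC and Akaike weight, sorted from the best model."""

    table: pd.DataFrame  # columns: model, aic, delta_aic, weight, in_best_set

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    @property
    def best_set(self) -> list[str]:
        return self.table.loc[self.table["in_best_set"], "model"].tolist()


def akaike_weights(aics: Sequence[float], names: Optional[Sequence[str]] = None) -> SelectionTable:
    """ΔAIC and Akaike weights ``w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2)``.

    Non-finite AICs are dropped with a warning. The best-set flag marks models
    strictly within :data:`BEST_SET_DELTA` units of the minimum.
    """
    aics = np.asarray(aics, dtype=float)
    if names is None:
        names = [f"model{i + 1}" for i in range(aics.size)]
    names = list(names)
    finite = np.isfinite(aics)
    if not finite.any():
        raise RamForageError("no finite AIC values")
    if not finite.all():
        dropped = [n for n, ok in zip(names, finite) if not ok]
        logger.warning("dropping models with non-finite AIC: %s", dropped)
    aics_f = aics[finite]
    names_f = [n for n, ok in zip(names, finite) if ok]
    delta = aics_f - aics_f.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    df = pd.DataFrame(
        {
            "model": names_f,
            "aic": aics_f,
            "delta_aic": delta,
            "weight": w,
            "in_best_set": delta < BEST_SET_DELTA,
        }
    ).sort_values(["delta_aic", "model"], kind="stable", ignore_index=True)
    return SelectionTable(table=df)


def wald_ci(b: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Two-sided normal-quantile interval ``b ± z·se``."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return b - z * se, b + z * se


def hazard_ratio(b: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Hazard ratio ``e^b`` with its Wald interval on the ratio scale."""
    lo, hi = wald_ci(b, se, level)
    return math.exp(b), math.exp(lo), math.exp(hi)


def select_and_average(
    fits: Sequence[FitResult],
    mode: str = "conditional",
    level: float = 0.95,
) -> tuple[SelectionTable, pd.DataFrame]:
    """Build the selection table and (if needed) model-average the best set.

    Non-converged fits are excluded from selection. If a single model is
    within two AIC units of the best, its estimates pass through unchanged.
    Returns the selection table and a coefficient table with columns
    estimate, se, ci_low, ci_high (and hazard-ratio columns for Cox fits),
    plus the averaging mode used.
    """
    if mode not in ("conditional", "full"):
        raise ValueError(f"mode must be 'conditional' or 'full', got {mode!r}")
    usable = [f for f in fits if f.converged]
    dropped = [f.name for f in fits if not f.converged]
    if dropped:
        logger.warning("excluding non-converged fits from selection: %s", dropped)
    if not usable:
        raise RamForageError("no converged fits to select among")
    table = akaike_weights([f.aic for f in usable], [f.name for f in usable])
    by_name = {f.name: f for f in usable}
    best_fits = [by_name[n] for n in table.best_set]
    is_cox = usable[0].spec.family == "coxph"

    w_raw = table.table.loc[table.table["in_best_set"], "weight"].to_numpy()
    w_set = w_raw / w_raw.sum()

    coef_names: list[str] = []
    for f in best_fits:
        for c in f.params.index:
            if c not in coef_names:
                coef_names.append(c)

    rows = []
    for coef in coef_names:
        bs, ses, ws = [], [], []
        for f, w in zip(best_fits, w_set):
            if coef in f.params.index:
                bs.append(float(f.params[coef]))
                ses.append(float(f.bse[coef]))
                ws.append(w)
            elif mode == "full":
                bs.append(0.0)
                ses.append(0.0)
                ws.append(w)
        bs, ses, ws = np.array(bs), np.array(ses), np.array(ws)
        ws = ws / ws.sum()
        b_bar = float(np.sum(ws * bs))
        se_bar = float(np.sum(ws * np.sqrt(ses**2 + (bs - b_bar) ** 2)))
        lo, hi = wald_ci(b_bar, se_bar, level)
        row = {
            "coefficient": coef,
            "estimate": b_bar,
            "se": se_bar,
            "ci_low": lo,
            "ci_high": hi,
            "n_models": int(np.sum(ws > 0)),
            "averaging": mode if len(best_fits) > 1 else "single-best",
        }
        if is_cox:
            hr, hr_lo, hr_hi = hazard_ratio(b_bar, se_bar, level)
            row.update({"hazard_ratio": hr, "hr_ci_low": hr_lo, "hr_ci_high": hr_hi})
        rows.append(row)
    averaged = pd.DataFrame(rows)
    return table, averaged


def size_split_analysis(
    data: pd.DataFrame,
    fit_fn: Callable[[pd.DataFrame, ModelSpec], FitResult],
    threshold_mm: float = 5.46,
    size_col: str = "size",
    response: str = "total_revisits",
    family: str = "nb",
    level: float = 0.95,
) -> pd.DataFrame:
    """Re-fit treatment vs basic within small (≤ threshold) and large strata.

    Reports per-stratum ``delta_aic = AIC(basic) − AIC(treatment)`` (positive
    means the treatment model is better supported) and the treatment
    coefficients with Wald intervals. An empty stratum is skipped with a
    warning.
    """
    specs = {s.name: s for s in build_candidate_set(response, family)}
    rows = []
    for label, mask in (
        ("small", data[size_col] <= threshold_mm),
        ("large", data[size_col] > threshold_mm),
    ):
        sub = data.loc[mask]
        if sub.empty:
            logger.warning("size stratum %r is empty at threshold %.2f mm", label, threshold_mm)
            continue
        fit_basic = fit_fn(sub, specs["basic"])
        fit_treat = fit_fn(sub, specs["treatment"])
        delta = fit_basic.aic - fit_treat.aic
        for coef in fit_treat.params.index:
            if not coef.startswith("treatment["):
                continue
            b, se = float(fit_treat.params[coef]), float(fit_treat.bse[coef])
            lo, hi = wald_ci(b, se, level)
            rows.append(
                {
                    "stratum": label,
                    "n_bees": int(len(sub)),
                    "delta_aic_treatment_vs_basic": delta,
                    "coefficient": coef,
                    "estimate": b,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    if not rows:
        raise RamForageError("both size strata empty")
    return pd.DataFrame(rows)
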