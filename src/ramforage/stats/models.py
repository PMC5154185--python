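"""Model specifications, design matrices and the common fit-result container.

The candidate set is the all-subsets family over two fixed effects, bee size
(continuous thorax width, mm) and pesticide treatment (categorical, control as
reference), plus their interaction, always keeping main effects under an
interaction. Random-effect structure is fixed per family: a colony intercept
for the count and Gaussian models, bee-nested-in-colony intercepts for the
per-choice binomial model, and (by this package's choice) no colony term for
the Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "FitResult", "build_candidate_set", "build_design", "TREATMENT_ORDER"]

TREATMENT_ORDER = ["control", "ld091", "ld377", "high"]

_CANDIDATE_TERMS = [
    ("basic", ()),
    ("size", ("size",)),
    ("treatment", ("treatment",)),
    ("treatment+size", ("treatment", "size")),
    ("treatment*size", ("treatment", "size", "treatment:size")),
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family and fixed-effect terms."""

    response: str
    family: str  # "nb", "binomial", "gaussian_log", "coxph"
    fixed: tuple
    name: str

    def __post_init__(self):
        if "treatment:size" in self.fixed and not {"treatment", "size"} <= set(self.fixed):
            raise ValueError("interaction requires both main effects")


@dataclass
class FitResult:
    """A fitted candidate model: likelihood, AIC and named coefficients."""

    spec: ModelSpec
    loglik: float
    k: int
    params: "pd.Series"
    bse: "pd.Series"
    converged: bool = True
    n_obs: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def name(self) -> str:
        return self.spec.name


def build_candidate_set(response: str, family: str) -> list[ModelSpec]:
    """The five all-subsets candidate models for one response."""
    return [
        ModelSpec(response=response, family=family, fixed=fixed, name=name)
        for name, fixed in _CANDIDATE_TERMS
    ]


def _treatment_levels(values: pd.Series) -> list[str]:
    present = list(pd.unique(values))
    ordered = [t for t in TREATMENT_ORDER if t in present]
    ordered += sorted(set(present) - set(ordered))
    return ordered


def build_design(
    df: pd.DataFrame,
    fixed: Sequence[str],
    intercept: bool = True,
    size_col: str = "size",
    treatment_col: str = "treatment",
    center_size: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the given fixed-effect terms.

    Treatment is dummy-coded against the first level present in
    ``TREATMENT_ORDER`` (control when available); the interaction multiplies
    size into each treatment dummy. Size is centred at its sample mean by
    default — a pure reparameterisation (identical likelihood and AIC) that
    removes the near-collinearity between a treatment dummy and its
    size-by-treatment column; treatment coefficients are then effects at the
    mean size. Slopes and interaction terms are unaffected.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    dummies = None
    dummy_names: list[str] = []
    size = None
    if "size" in fixed or "treatment:size" in fixed:
        size = df[size_col].to_numpy(dtype=float)
        if center_size:
            size = size - size.mean()
    if "treatment" in fixed:
        levels = _treatment_levels(df[treatment_col])
        dummies = []
        for lev in levels[1:]:
            dummies.append((df[treatment_col] == lev).to_numpy(dtype=float))
            dummy_names.append(f"treatment[{lev}]")
        cols.extend(dummies)
        names.extend(dummy_names)
    if "size" in fixed:
        cols.append(size)
        names.append("size")
    if "treatment:size" in fixed:
        for dummy, dname in zip(dummies, dummy_names):
            cols.append(dummy * size)
            names.append(f"size:{dname}")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names
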