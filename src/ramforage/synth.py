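"""Synthetic radial-arm-maze experiments with the design the analysis assumes.

The generator emulates the study design end to end: 61 bees from 7 colonies,
four acute-dose groups (0 / 0.091 / 0.377 / 2.5 ng per bee; n = 16/14/16/15),
thorax widths from a truncated normal, ten training bouts whose working-memory
strength rises to an asymptote, and one post-exposure test bout whose memory
strength is degraded as a function of dose and body size. Colony-level
heterogeneity enters as a random intercept on the logit-memory scale, and bout
durations come from a size-dependent log-normal per-visit time.

The dose–response shape is synthetic machinery: the exposure acts on the logit
of memory strength through ``log1p(dose)``, with a size interaction, so dose 0
leaves memory untouched and the marginal effect of dose saturates between the
two highest doses. Defaults are calibrated so high-dose bees make roughly 3–5
times the revisits of controls, with larger bees more strongly impaired.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import RamForageError
from .maze import VisitSequence
from .simulate import TransitionMatrix, memory_policy, simulate_bout

__all__ = [
    "ExperimentConfig",
    "ExperimentDataset",
    "TREATMENT_DOSES",
    "generate_bees",
    "post_exposure_memory",
    "generate_experiment",
]

#: treatment labels and their acute doses (ng of active ingredient per bee)
TREATMENT_DOSES = {"control": 0.0, "ld091": 0.091, "ld377": 0.377, "high": 2.5}

_LOGIT_CLAMP = 1e-9


@dataclass
class ExperimentConfig:
    """Design constants and synthetic effect parameters.

    Sizes and doses follow the study design; effect-shape parameters are the
    generator's own calibration (see the methods note).
    """

    n_colonies: int = 7
    group_sizes: dict = field(
        default_factory=lambda: {"control": 16, "ld091": 14, "ld377": 16, "high": 15}
    )
    # thorax width (mm): truncated normal
    size_mean_mm: float = 5.45
    size_sd_mm: float = 0.35
    size_bounds_mm: tuple = (4.4, 6.2)
    # training trajectory: m(bout) = m_max * (1 - exp(-bout / tau))
    m_max: float = 0.85
    tau: float = 3.0
    n_training_bouts: int = 10
    colony_sd_logit: float = 0.3
    # exposure effect: logit(m_test) = logit(m_train)
    #                  - gamma * log1p(dose) * (1 + delta * (size - size_mean))
    gamma: float = 1.4
    delta: float = 0.5
    # per-visit time: log seconds ~ N(mu0 + beta_size * (size - size_mean), sigma)
    time_mu0_log_s: float = 2.996  # ~log(20 s)
    time_beta_size: float = -0.335
    time_sigma: float = 0.3
    # optional per-visit probability of abandoning a bout early
    quit_hazard: float = 0.0
    max_visits: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.m_max <= 1.0:
            raise RamForageError(f"m_max must be in (0, 1], got {self.m_max}")
        for name in ("size_sd_mm", "colony_sd_logit", "time_sigma"):
            if getattr(self, name) < 0:
                raise RamForageError(f"{name} must be non-negative")
        unknown = set(self.group_sizes) - set(TREATMENT_DOSES)
        if unknown:
            raise RamForageError(f"unknown treatment labels {unknown}")

    @property
    def n_bees(self) -> int:
        return sum(self.group_sizes.values())

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ExperimentDataset:
    """The three tables of one synthetic experiment plus its provenance."""

    bees: pd.DataFrame
    visits: pd.DataFrame
    bouts: pd.DataFrame
    provenance: dict


def _logit(p: float) -> float:
    p = min(max(p, _LOGIT_CLAMP), 1.0 - _LOGIT_CLAMP)
    return float(np.log(p / (1.0 - p)))


def _ilogit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def training_memory(bout: int, config: ExperimentConfig) -> float:
    """Expected working-memory strength at a given training bout (1-based)."""
    if config.tau <= 0:
        return config.m_max
    return config.m_max * (1.0 - np.exp(-bout / config.tau))


def post_exposure_memory(
    m_train: float, dose_ng: float, size_mm: float, config: ExperimentConfig
) -> float:
    """Memory strength after an acute dose, degraded on the logit scale.

    ``logit(m_test) = logit(m_train) − γ·log1p(dose)·(1 + δ·(size − mean size))``,
    clamped to (0, 1). Dose 0 returns ``m_train`` exactly.
    """
    if dose_ng == 0.0:
        return m_train
    drop = config.gamma * np.log1p(dose_ng) * (1.0 + config.delta * (size_mm - config.size_mean_mm))
    return _ilogit(_logit(m_train) - drop)


def generate_bees(config: ExperimentConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Bee table: ids, round-robin colonies, random treatments, thorax widths."""
    n = config.n_bees
    labels = [t for t, size in sorted(config.group_sizes.items()) for _ in range(size)]
    order = rng.permutation(n)
    treatment = [labels[i] for i in order]
    lo, hi = config.size_bounds_mm
    if config.size_sd_mm == 0:
        sizes = np.full(n, config.size_mean_mm)
    else:
        a = (lo - config.size_mean_mm) / config.size_sd_mm
        b = (hi - config.size_mean_mm) / config.size_sd_mm
        sizes = sps.truncnorm.rvs(
            a, b, loc=config.size_mean_mm, scale=config.size_sd_mm, size=n, random_state=rng
        )
    return pd.DataFrame(
        {
            "bee_id": [f"bee{idx + 1:03d}" for idx in range(n)],
            "colony_id": [f"colony{idx % config.n_colonies + 1}" for idx in range(n)],
            "thorax_width_mm": np.round(sizes, 3),
            "treatment": treatment,
            "dose_ng": [TREATMENT_DOSES[t] for t in treatment],
        }
    )


def generate_experiment(
    config: Optional[ExperimentConfig] = None,
    seed: int = 0,
    base_matrix: Optional[TransitionMatrix] = None,
) -> ExperimentDataset:
    """Simulate a full experiment: 10 training bouts + 1 test bout per bee.

    Per bee and bout, a memory policy is run at strength
    ``ilogit(logit(m(bout)) + u_colony)``; the test bout (bout 11) uses the
    exposure-degraded memory. Bout durations are ``n_visits`` times a
    size-dependent log-normal per-visit time. ``base_matrix`` optionally gives
    the memory policy a stereotyped (rather than uniform) base.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    bees = generate_bees(config, rng)
    colony_u = {
        f"colony{c + 1}": (rng.normal(0.0, config.colony_sd_logit) if config.colony_sd_logit else 0.0)
        for c in range(config.n_colonies)
    }

    visit_rows = []
    bout_rows = []
    n_bouts_total = config.n_training_bouts + 1
    for bee in bees.itertuples(index=False):
        u = colony_u[bee.colony_id]
        m10 = _ilogit(_logit(training_memory(config.n_training_bouts, config)) + u)
        for bout in range(1, n_bouts_total + 1):
            if bout <= config.n_training_bouts:
                phase = "training"
                m_base = training_memory(bout, config)
                m = _ilogit(_logit(m_base) + u) if m_base < 1.0 else 1.0
            else:
                phase = "test"
                m = post_exposure_memory(m10, bee.dose_ng, bee.thorax_width_mm, config)
            seq = simulate_bout(
                memory_policy(m, base_matrix=base_matrix),
                rng,
                max_visits=config.max_visits,
                quit_hazard=config.quit_hazard,
                bee_id=bee.bee_id,
                colony_id=bee.colony_id,
                bout_index=bout,
                phase=phase,
            )
            log_tpv = rng.normal(
                config.time_mu0_log_s
                + config.time_beta_size * (bee.thorax_width_mm - config.size_mean_mm),
                config.time_sigma,
            )
            duration = seq.n_visits * float(np.exp(log_tpv))
            for visit_idx, flower in enumerate(seq.choices, start=1):
                visit_rows.append(
                    (bee.bee_id, bee.colony_id, bout, phase, visit_idx, flower)
                )
            bout_rows.append((bee.bee_id, bout, phase, round(duration, 3)))

    visits = pd.DataFrame(
        visit_rows,
        columns=["bee_id", "colony_id", "bout_index", "phase", "visit_index", "flower_id"],
    )
    bouts = pd.DataFrame(bout_rows, columns=["bee_id", "bout_index", "phase", "duration_s"])
    provenance = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_bees": config.n_bees,
        "n_bouts_per_bee": n_bouts_total,
    }
    return ExperimentDataset(bees=bees, visits=visits, bouts=bouts, provenance=provenance)


def dataset_sequences(dataset: ExperimentDataset, phase: Optional[str] = None) -> list[VisitSequence]:
    """Re-assemble :class:`VisitSequence` objects from an experiment's tables."""
    durations = {
        (r.bee_id, r.bout_index): r.duration_s for r in dataset.bouts.itertuples(index=False)
    }
    out = []
    grouped = dataset.visits.sort_values(["bee_id", "bout_index", "visit_index"]).groupby(
        ["bee_id", "colony_id", "bout_index", "phase"], sort=True
    )
    for (bee_id, colony_id, bout_index, ph), grp in grouped:
        if phase is not None and ph != phase:
            continue
        out.append(
            VisitSequence(
                bee_id=bee_id,
                colony_id=colony_id,
                bout_index=int(bout_index),
                phase=ph,
                choices=grp["flower_id"].tolist(),
                duration_s=durations.get((bee_id, int(bout_index))),
            )
        )
    return out
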