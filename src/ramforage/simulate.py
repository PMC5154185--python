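"""Agent policies and the Monte Carlo null-distribution engine.

Three policies generate visit sequences on the 8-flower array:

* ``chance`` — every choice is uniform over all flowers (self-transitions
  allowed by default; a no-self variant, uniform over the other 7, is a flag).
  Whether a flower has been emptied never influences the choice.
* ``stereotyped`` — the first choice is drawn from an empirical first-choice
  distribution and every subsequent choice from the row of an empirical
  flower-to-flower transition matrix, again with no memory of visited flowers.
  This is the "chance + stereotypy" null.
* ``memory`` — synthetic-data machinery: with probability ``m`` (working-memory
  strength) the base policy's distribution is renormalised over unvisited
  flowers, otherwise the unmodified base distribution is used. ``m=0`` is the
  base policy, ``m=1`` perfect revisit avoidance.

A bout runs until all flowers have been visited (or a hard cap is reached).
``monte_carlo_null`` simulates bouts in vectorised batches and summarises any
of the performance metrics under a policy; ``compare_to_null`` puts an observed
sample's confidence interval next to a simulated null mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, NoDataError, PolicyConfigError
from .maze import VisitSequence

__all__ = [
    "TransitionMatrix",
    "AgentPolicy",
    "NullDistribution",
    "NullComparison",
    "chance_policy",
    "stereotyped_policy",
    "memory_policy",
    "next_choice",
    "simulate_bout",
    "simulate_metrics_batch",
    "monte_carlo_null",
    "transition_counts",
    "estimate_transition_matrix",
    "compare_to_null",
    "METRIC_POLARITY",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-12

#: whether a larger metric value means better maze performance
METRIC_POLARITY = {
    "total_revisits": "lower_better",
    "correct_before_first_revisit": "higher_better",
    "correct_in_first_eight": "higher_better",
}


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic flower-to-flower movement probabilities.

    ``matrix[i, j]`` is the probability of moving to flower j+1 given the bee
    currently sits on flower i+1; ``first_choice`` is the distribution of the
    first flower chosen on entering the arena.
    """

    matrix: np.ndarray
    first_choice: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        fc = np.asarray(self.first_choice, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != fc.shape[0]:
            raise PolicyConfigError(f"matrix shape {m.shape} / first-choice {fc.shape} mismatch")
        if np.any(m < -_PROB_TOL) or np.any(fc < -_PROB_TOL):
            raise PolicyConfigError("negative transition probabilities")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9) or abs(fc.sum() - 1.0) > 1e-9:
            raise PolicyConfigError("rows of a transition matrix must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "first_choice", fc)

    @property
    def n_flowers(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class AgentPolicy:
    """A rule for choosing the next flower.

    ``kind`` ∈ {"chance", "stereotyped", "memory"}. Stereotyped policies need a
    :class:`TransitionMatrix`; memory policies need a strength ``m`` and use
    ``transition_matrix`` as their base when given (chance base otherwise).
    """

    kind: str
    n_flowers: int = 8
    transition_matrix: Optional[TransitionMatrix] = None
    memory_strength: Optional[float] = None
    allow_self: bool = True

    def __post_init__(self):
        if self.kind not in ("chance", "stereotyped", "memory"):
            raise PolicyConfigError(f"unknown policy kind {self.kind!r}")
        if self.kind == "stereotyped" and self.transition_matrix is None:
            raise PolicyConfigError("stereotyped policy requires a transition matrix")
        if self.kind == "memory":
            m = self.memory_strength
            if m is None or not (0.0 <= m <= 1.0):
                raise PolicyConfigError(f"memory strength must be in [0, 1], got {m}")
        if self.transition_matrix is not None and self.transition_matrix.n_flowers != self.n_flowers:
            raise PolicyConfigError("transition matrix size does not match n_flowers")


def chance_policy(n_flowers: int = 8, allow_self: bool = True) -> AgentPolicy:
    return AgentPolicy(kind="chance", n_flowers=n_flowers, allow_self=allow_self)


def stereotyped_policy(matrix: TransitionMatrix) -> AgentPolicy:
    return AgentPolicy(kind="stereotyped", n_flowers=matrix.n_flowers, transition_matrix=matrix)


def memory_policy(
    m: float, base_matrix: Optional[TransitionMatrix] = None, n_flowers: int = 8
) -> AgentPolicy:
    if base_matrix is not None:
        n_flowers = base_matrix.n_flowers
    return AgentPolicy(
        kind="memory", n_flowers=n_flowers, transition_matrix=base_matrix, memory_strength=m
    )


@dataclass
class NullDistribution:
    """Monte Carlo summary of one metric under one policy."""

    metric: str
    n_iterations: int
    mean: float
    sd: float
    seed: Optional[int] = None
    values: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def mc_se(self) -> float:
        return self.sd / math.sqrt(self.n_iterations)


@dataclass(frozen=True)
class NullComparison:
    """Observed-mean confidence interval versus a simulated null mean."""

    metric: str
    n_observed: int
    observed_mean: float
    ci_low: float
    ci_high: float
    null_mean: float
    null_inside_ci: bool
    direction: str  # "better", "worse" or "equal" relative to the null
    level: float


# ---------------------------------------------------------------------------
# choice generation
# ---------------------------------------------------------------------------

def _base_distribution(policy: AgentPolicy, current: Optional[int]) -> np.ndarray:
    """Memory-free next-flower distribution for the policy's base behaviour."""
    n = policy.n_flowers
    if policy.kind == "chance" or (policy.kind == "memory" and policy.transition_matrix is None):
        p = np.full(n, 1.0 / n)
        if not policy.allow_self and current is not None:
            p = np.full(n, 1.0 / (n - 1))
            p[current - 1] = 0.0
        return p
    tm = policy.transition_matrix
    if current is None:
        return tm.first_choice.copy()
    return tm.matrix[current - 1].copy()


def next_choice(
    policy: AgentPolicy,
    current: Optional[int],
    visited: set[int],
    rng: np.random.Generator,
) -> int:
    """Draw the next flower id (1-based) under the policy."""
    n = policy.n_flowers
    if len(visited) >= n and policy.kind == "memory":
        raise PolicyConfigError("memory policy asked for a choice with no unvisited flower")
    p = _base_distribution(policy, current)
    if policy.kind == "memory" and rng.random() < policy.memory_strength:
        mask = np.ones(n)
        for f in visited:
            mask[f - 1] = 0.0
        p = p * mask
        total = p.sum()
        if total <= 0.0:  # base puts no mass on any unvisited flower
            p = mask / mask.sum()
        else:
            p = p / total
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right")) + 1


def simulate_bout(
    policy: AgentPolicy,
    rng: np.random.Generator,
    max_visits: int = 10_000,
    quit_hazard: float = 0.0,
    bee_id: str = "sim",
    colony_id: str = "sim",
    bout_index: int = 1,
    phase: str = "training",
) -> VisitSequence:
    """Generate one bout: choices until all flowers are visited (or capped).

    ``quit_hazard`` is a per-visit probability (after the first visit) of
    abandoning the bout early, used by the synthetic-data generator to produce
    incomplete bouts. Cap-hit bouts are flagged by their ``complete`` property.
    """
    n = policy.n_flowers
    choices: list[int] = []
    visited: set[int] = set()
    current: Optional[int] = None
    while len(visited) < n and len(choices) < max_visits:
        if choices and quit_hazard > 0.0 and rng.random() < quit_hazard:
            break
        current = next_choice(policy, current, visited, rng)
        choices.append(current)
        visited.add(current)
    if len(choices) >= max_visits:
        logger.warning("bout hit the %d-visit cap without completing", max_visits)
    return VisitSequence(
        bee_id=bee_id,
        colony_id=colony_id,
        bout_index=bout_index,
        phase=phase,
        choices=choices,
        n_flowers=n,
    )


# ---------------------------------------------------------------------------
# vectorised batch engine
# ---------------------------------------------------------------------------

def _batch_probs(
    policy: AgentPolicy,
    current: np.ndarray,
    visited: np.ndarray,
    rng: np.random.Generator,
    first_step: bool,
) -> np.ndarray:
    """(n_active, n_flowers) choice probabilities for each active bout."""
    n = policy.n_flowers
    k = current.shape[0]
    if policy.kind == "chance" or (policy.kind == "memory" and policy.transition_matrix is None):
        base = np.full((k, n), 1.0 / n)
        if not policy.allow_self and not first_step:
            base = np.full((k, n), 1.0 / (n - 1))
            base[np.arange(k), current] = 0.0
    else:
        tm = policy.transition_matrix
        if first_step:
            base = np.tile(tm.first_choice, (k, 1))
        else:
            base = tm.matrix[current]
    if policy.kind != "memory":
        return base
    use_mem = rng.random(k) < policy.memory_strength
    probs = base.copy()
    masked = probs[use_mem] * (~visited[use_mem])
    totals = masked.sum(axis=1, keepdims=True)
    fallback = totals[:, 0] <= 0.0
    if np.any(fallback):  # base puts no mass on unvisited: uniform over unvisited
        unif = (~visited[use_mem][fallback]).astype(float)
        masked[fallback] = unif
        totals = masked.sum(axis=1, keepdims=True)
    probs[use_mem] = masked / totals
    return probs


def simulate_metrics_batch(
    policy: AgentPolicy,
    n_iterations: int,
    rng: np.random.Generator,
    max_visits: int = 10_000,
) -> dict[str, np.ndarray]:
    """Simulate many bouts at once; return per-bout metric arrays.

    Returns arrays ``total_revisits``, ``correct_before_first_revisit``,
    ``correct_in_first_eight``, ``n_visits`` and ``complete``. Metrics agree
    exactly with the :mod:`ramforage.metrics` definitions applied to the same
    sequences.
    """
    n = policy.n_flowers
    active = np.arange(n_iterations)
    visited = np.zeros((n_iterations, n), dtype=bool)
    current = np.zeros(n_iterations, dtype=np.int64)
    n_distinct = np.zeros(n_iterations, dtype=np.int64)
    revisits = np.zeros(n_iterations, dtype=np.int64)
    before_first = np.zeros(n_iterations, dtype=np.int64)
    no_revisit_yet = np.ones(n_iterations, dtype=bool)
    first8 = np.zeros(n_iterations, dtype=np.int64)
    n_visits = np.zeros(n_iterations, dtype=np.int64)

    step = 0
    while active.size:
        step += 1
        probs = _batch_probs(policy, current[active], visited[active], rng, step == 1)
        cum = np.cumsum(probs, axis=1)
        r = rng.random(active.size) * cum[:, -1]
        choice = (cum < r[:, None]).sum(axis=1)
        novel = ~visited[active, choice]
        visited[active, choice] = True
        current[active] = choice
        n_distinct[active] += novel
        revisits[active] += ~novel
        nv = no_revisit_yet[active]
        before_first[active[nv]] += novel[nv]
        no_revisit_yet[active[nv & ~novel]] = False
        if step <= 8:
            first8[active] += novel
        n_visits[active] = step
        done = (n_distinct[active] == n) | (step >= max_visits)
        active = active[~done]

    out = {
        "total_revisits": revisits,
        "correct_before_first_revisit": before_first,
        "correct_in_first_eight": first8.astype(float),
        "n_visits": n_visits,
        "complete": n_distinct == n,
    }
    # correct-in-first-eight is undefined for bouts shorter than 8 visits
    out["correct_in_first_eight"][n_visits < 8] = np.nan
    return out


def monte_carlo_null(
    policy: AgentPolicy,
    metrics: Sequence[str] = (
        "total_revisits",
        "correct_before_first_revisit",
        "correct_in_first_eight",
    ),
    n_iterations: int = 1_000_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    keep_values: bool = False,
    max_visits: int = 10_000,
) -> dict[str, NullDistribution]:
    """Monte Carlo null distribution of the performance metrics under a policy.

    One shared batch of simulated bouts feeds all requested metrics.
    Reproducible for a fixed seed.
    """
    if n_iterations < 1:
        raise InsufficientDataError("n_iterations must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    batch = simulate_metrics_batch(policy, n_iterations, rng, max_visits=max_visits)
    out = {}
    for name in metrics:
        if name not in batch:
            raise KeyError(f"unknown metric {name!r}")
        vals = np.asarray(batch[name], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[name] = NullDistribution(
            metric=name,
            n_iterations=vals.size,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            seed=seed,
            values=vals if keep_values else None,
        )
    return out


# ---------------------------------------------------------------------------
# empirical transition matrix
# ---------------------------------------------------------------------------

def transition_counts(
    bouts: Iterable[VisitSequence], n_flowers: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled directed transition counts and first-choice counts."""
    counts = np.zeros((n_flowers, n_flowers))
    first = np.zeros(n_flowers)
    for seq in bouts:
        c = list(seq.choices)
        if not c:
            continue
        first[c[0] - 1] += 1
        for a, b in zip(c[:-1], c[1:]):
            counts[a - 1, b - 1] += 1
    return counts, first


def estimate_transition_matrix(
    bouts: Iterable[VisitSequence],
    pseudocount: float = 0.0,
    n_flowers: int = 8,
) -> TransitionMatrix:
    """Pooled empirical transition matrix over consecutive visit pairs.

    Counts all directed transitions and first choices across the supplied
    bouts, adds ``pseudocount`` to every cell, and row-normalises. A row with
    zero total (and zero pseudocount) falls back to uniform with a warning.
    """
    counts, first = transition_counts(bouts, n_flowers)
    if counts.sum() == 0 and first.sum() == 0:
        raise NoDataError("no transitions observed in the supplied bouts")
    counts += pseudocount
    first = first + pseudocount
    row_tot = counts.sum(axis=1)
    zero_rows = row_tot == 0
    if np.any(zero_rows):
        logger.warning(
            "flowers %s never observed as a transition source; rows fall back to uniform",
            list(np.flatnonzero(zero_rows) + 1),
        )
        counts[zero_rows] = 1.0
        row_tot = counts.sum(axis=1)
    matrix = counts / row_tot[:, None]
    if first.sum() == 0:
        first = np.ones(n_flowers)
    first = first / first.sum()
    return TransitionMatrix(matrix=matrix, first_choice=first)


# ---------------------------------------------------------------------------
# observed vs null
# ---------------------------------------------------------------------------

def compare_to_null(
    observed: Sequence[float],
    null: NullDistribution,
    level: float = 0.95,
    polarity: Optional[str] = None,
    method: str = "t",
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> NullComparison:
    """Two-sided CI of the observed mean versus the simulated null mean.

    ``method="t"`` uses a Student-t interval on the observed mean (the
    default); ``method="bootstrap"`` a percentile bootstrap. ``polarity``
    defaults to the metric's registered direction (fewer revisits = better,
    more correct choices = better).
    """
    obs = np.asarray(observed, dtype=float)
    obs = obs[~np.isnan(obs)]
    if obs.size < 2:
        raise InsufficientDataError("need at least 2 observed values")
    mean = float(obs.mean())
    if method == "t":
        se = obs.std(ddof=1) / math.sqrt(obs.size)
        tq = sps.t.ppf(0.5 + level / 2, df=obs.size - 1)
        lo, hi = mean - tq * se, mean + tq * se
    elif method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.integers(0, obs.size, size=(n_boot, obs.size))
        boots = obs[idx].mean(axis=1)
        alpha = (1 - level) / 2
        lo, hi = (float(q) for q in np.quantile(boots, [alpha, 1 - alpha]))
    else:
        raise ValueError(f"unknown method {method!r}")
    polarity = polarity or METRIC_POLARITY.get(null.metric, "higher_better")
    if mean == null.mean:
        direction = "equal"
    elif (mean < null.mean) == (polarity == "lower_better"):
        direction = "better"
    else:
        direction = "worse"
    return NullComparison(
        metric=null.metric,
        n_observed=int(obs.size),
        observed_mean=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        null_mean=null.mean,
        null_inside_ci=bool(lo <= null.mean <= hi),
        direction=direction,
        level=level,
    )
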