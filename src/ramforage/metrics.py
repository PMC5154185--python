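"""Bout-level performance statistics for the radial-arm-maze task.

Four measures are computed per bout:

i)   total revisits — visits to flowers already emptied in the same bout; each
     is a spatial working-memory error;
ii)  correct choices before the first revisit — length of the initial
     duplicate-free run of choices;
iii) correct choices in the first eight visits — novel flowers among visits
     1..8 (undefined for bouts shorter than 8 visits);
iv)  time per visit — bout duration divided by the number of visits (its
     natural log is what the linear mixed model analyses).

The first-revisit statistic also yields a survival record: the event time is
the choice index of the first revisit; a bout with no revisit is
right-censored at choice 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import NoDataError
from .maze import VisitSequence

__all__ = [
    "BoutMetrics",
    "SurvivalRecord",
    "total_revisits",
    "correct_before_first_revisit",
    "correct_in_first_eight",
    "time_per_visit",
    "first_revisit_survival",
    "binary_choice_expansion",
    "bout_metrics",
    "metrics_table",
]

#: censoring horizon for the first-revisit survival record
CENSOR_TIME = 8


@dataclass(frozen=True)
class BoutMetrics:
    """All four performance statistics for one bout."""

    bee_id: str
    bout_index: int
    phase: str
    n_visits: int
    complete: bool
    total_revisits: int
    correct_before_first_revisit: int
    correct_in_first_eight: Optional[int]  # None when fewer than 8 visits
    time_per_visit_s: Optional[float]  # None when duration absent
    survival_time: int
    survival_event: bool


@dataclass(frozen=True)
class SurvivalRecord:
    """Choice index of the first revisit (or censoring at 8)."""

    bee_id: str
    time: int
    event: bool
    covariates: dict = field(default_factory=dict)


def _require_nonempty(seq: VisitSequence) -> None:
    if seq.n_visits == 0:
        raise NoDataError(f"bee {seq.bee_id} bout {seq.bout_index}: empty sequence")


def total_revisits(seq: VisitSequence) -> int:
    """Count visits whose flower already occurred earlier in the bout."""
    _require_nonempty(seq)
    return seq.n_visits - len(set(seq.choices))


def correct_before_first_revisit(seq: VisitSequence) -> int:
    """Length of the maximal duplicate-free prefix of the choice sequence."""
    _require_nonempty(seq)
    seen: set[int] = set()
    for flower in seq.choices:
        if flower in seen:
            break
        seen.add(flower)
    return len(seen)


def correct_in_first_eight(seq: VisitSequence) -> Optional[int]:
    """Novel-flower choices among visits 1..8; None if the bout is shorter."""
    _require_nonempty(seq)
    if seq.n_visits < 8:
        return None
    seen: set[int] = set()
    correct = 0
    for flower in list(seq.choices)[:8]:
        if flower not in seen:
            correct += 1
            seen.add(flower)
    return correct


def time_per_visit(seq: VisitSequence, per: str = "visits") -> Optional[float]:
    """Bout duration divided by total visits (default) or total revisits.

    ``per="revisits"`` exposes the alternative reading found in some reports;
    it is undefined (None) for error-free bouts.
    """
    _require_nonempty(seq)
    if seq.duration_s is None or seq.duration_s <= 0:
        return None
    if per == "visits":
        return seq.duration_s / seq.n_visits
    if per == "revisits":
        r = total_revisits(seq)
        return seq.duration_s / r if r > 0 else None
    raise ValueError(f"per must be 'visits' or 'revisits', got {per!r}")


def first_revisit_survival(seq: VisitSequence) -> SurvivalRecord:
    """Survival record for the choice index at which the first revisit occurs.

    Event time = 1 + correct choices before the first revisit; bouts with no
    revisit are right-censored at choice 8 regardless of completeness.
    """
    _require_nonempty(seq)
    prefix = correct_before_first_revisit(seq)
    if prefix < seq.n_visits:  # a revisit occurred
        return SurvivalRecord(bee_id=seq.bee_id, time=prefix + 1, event=True)
    return SurvivalRecord(bee_id=seq.bee_id, time=CENSOR_TIME, event=False)


def binary_choice_expansion(seq: VisitSequence) -> Optional[list[int]]:
    """Per-choice success indicators (1 = novel flower) for visits 1..8.

    None when the bout has fewer than 8 visits; the binomial mixed model drops
    such bouts.
    """
    _require_nonempty(seq)
    if seq.n_visits < 8:
        return None
    seen: set[int] = set()
    out = []
    for flower in list(seq.choices)[:8]:
        out.append(1 if flower not in seen else 0)
        seen.add(flower)
    return out


def bout_metrics(seq: VisitSequence) -> BoutMetrics:
    """Compute all four statistics plus the survival record for one bout."""
    surv = first_revisit_survival(seq)
    return BoutMetrics(
        bee_id=seq.bee_id,
        bout_index=seq.bout_index,
        phase=seq.phase,
        n_visits=seq.n_visits,
        complete=seq.complete,
        total_revisits=total_revisits(seq),
        correct_before_first_revisit=correct_before_first_revisit(seq),
        correct_in_first_eight=correct_in_first_eight(seq),
        time_per_visit_s=time_per_visit(seq),
        survival_time=surv.time,
        survival_event=surv.event,
    )


def metrics_table(sequences: Iterable[VisitSequence]) -> pd.DataFrame:
    """Tidy per-bout metrics table (one row per bout)."""
    rows = []
    for seq in sequences:
        m = bout_metrics(seq)
        rows.append(
            {
                "bee_id": m.bee_id,
                "bout_index": m.bout_index,
                "phase": m.phase,
                "n_visits": m.n_visits,
                "complete": m.complete,
                "total_revisits": m.total_revisits,
                "correct_before_first_revisit": m.correct_before_first_revisit,
                "correct_in_first_eight": (
                    math.nan if m.correct_in_first_eight is None else m.correct_in_first_eight
                ),
                "time_per_visit_s": (
                    math.nan if m.time_per_visit_s is None else m.time_per_visit_s
                ),
                "survival_time": m.survival_time,
                "survival_event": m.survival_event,
            }
        )
    if not rows:
        raise NoDataError("no visit sequences supplied")
    return pd.DataFrame(rows)
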