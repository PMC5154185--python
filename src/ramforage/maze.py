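"""Geometry of the circular flower array and validated visit sequences.

The maze is an open-field analogue of the radial-arm maze: ``n`` artificial
flowers arranged on a circle in a vertical plane (x horizontal, y vertical,
centre at the origin). Flower ids are 1-based; flower 1 sits at the top of the
circle and ids increase clockwise. Only relative geometry matters for the
analyses (adjacency, travel angle from vertical), so the labelling origin is a
pure convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, MalformedRecordError, UndefinedDirectionError

__all__ = [
    "FlowerArray",
    "VisitSequence",
    "build_flower_array",
    "travel_angle_from_vertical",
    "neighbor_pairs",
    "validate_sequence",
]


@dataclass(frozen=True)
class FlowerArray:
    """Circular array of flowers in a vertical plane.

    Attributes
    ----------
    n_flowers : int
        Number of flowers (8 in the standard apparatus).
    radius : float
        Circle radius, arbitrary units (angles are scale-free).
    positions : ndarray of shape (n_flowers, 2)
        Cartesian (x, y) coordinates; row k is flower id k+1.
    """

    n_flowers: int
    radius: float
    positions: np.ndarray = field(repr=False)

    def position(self, flower_id: int) -> np.ndarray:
        """Coordinates of a 1-based flower id."""
        if not 1 <= flower_id <= self.n_flowers:
            raise GeometryError(f"flower id {flower_id} outside 1..{self.n_flowers}")
        return self.positions[flower_id - 1]

    def is_adjacent(self, i: int, j: int) -> bool:
        """True when flowers i and j are angular neighbours."""
        d = abs(i - j) % self.n_flowers
        return d in (1, self.n_flowers - 1)


@dataclass
class VisitSequence:
    """One bee's ordered flower choices within a single foraging bout."""

    bee_id: str
    colony_id: str
    bout_index: int
    phase: str  # "training" or "test"
    choices: Sequence[int]
    duration_s: Optional[float] = None
    n_flowers: int = 8

    @property
    def n_visits(self) -> int:
        return len(self.choices)

    @property
    def complete(self) -> bool:
        """True iff every flower of the array occurs at least once."""
        return set(self.choices) >= set(range(1, self.n_flowers + 1))


def build_flower_array(n: int = 8, radius: float = 1.0) -> FlowerArray:
    """Place ``n`` flowers on a circle, flower 1 at the top, ids clockwise.

    Flower k sits at angle ``90° − (k−1)·360°/n`` counter-clockwise from the
    +x axis, so consecutive ids are angular neighbours.
    """
    if n < 3:
        raise GeometryError(f"need at least 3 flowers, got {n}")
    if radius <= 0:
        raise GeometryError(f"radius must be positive, got {radius}")
    k = np.arange(n)
    theta = np.deg2rad(90.0 - k * 360.0 / n)
    positions = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return FlowerArray(n_flowers=n, radius=float(radius), positions=positions)


def travel_angle_from_vertical(
    from_pos: Sequence[float], to_pos: Sequence[float], directed: bool = True
) -> float:
    """Angle in degrees between the travel vector and the upward vertical.

    0° is straight up, 90° horizontal, 180° straight down. With
    ``directed=False`` the angle is folded into [0°, 90°] (up and down
    indistinguishable).
    """
    v = np.asarray(to_pos, dtype=float) - np.asarray(from_pos, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise UndefinedDirectionError("travel angle undefined between identical points")
    angle = float(np.degrees(np.arccos(np.clip(v[1] / norm, -1.0, 1.0))))
    if not directed:
        angle = min(angle, 180.0 - angle)
    return angle


def neighbor_pairs(array: FlowerArray) -> list[tuple[int, int]]:
    """All 2n directed pairs of angularly adjacent flowers (i→i±1, modular)."""
    n = array.n_flowers
    pairs = []
    for i in range(1, n + 1):
        pairs.append((i, i % n + 1))
        pairs.append((i, (i - 2) % n + 1))
    return pairs


def validate_sequence(seq: VisitSequence, array: FlowerArray) -> VisitSequence:
    """Check a visit sequence against the array; returns the sequence.

    Raises :class:`MalformedRecordError` naming the 1-based visit index of the
    first out-of-range flower id.
    """
    if seq.n_visits == 0:
        raise MalformedRecordError(f"bee {seq.bee_id} bout {seq.bout_index}: empty sequence")
    for idx, flower in enumerate(seq.choices, start=1):
        if not (isinstance(flower, (int, np.integer)) and 1 <= flower <= array.n_flowers):
            raise MalformedRecordError(
                f"bee {seq.bee_id} bout {seq.bout_index}: invalid flower id "
                f"{flower!r} at visit {idx}"
            )
    seq.n_flowers = array.n_flowers
    return seq
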