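"""Stereotypy diagnostics: contiguity preference and vertical movement bias.

Bees can inflate apparent maze performance with memory-free movement rules.
Two diagnostics quantify such rules from a pooled transition-count matrix:

* contiguity preference — the proportion of transitions that land on an
  angularly adjacent flower, against its chance expectation;
* vertical bias — the Spearman rank correlation between the transition
  frequency of each directed neighbour pair and that pair's travel angle from
  vertical (a negative rho means bees prefer to fly upwards).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NoDataError, UndefinedCorrelationError
from .maze import FlowerArray, neighbor_pairs, travel_angle_from_vertical

__all__ = ["ContiguityResult", "VerticalBiasResult", "spearman_rho", "contiguity_preference", "vertical_bias"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContiguityResult:
    observed_proportion: float
    expected_proportion: float
    n_transitions: int


@dataclass(frozen=True)
class VerticalBiasResult:
    pairs: pd.DataFrame  # from_flower, to_flower, count, frequency, angle_deg
    rho: Optional[float]
    n_pairs: int


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("rank correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def _validated_counts(counts, array: FlowerArray) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    n = array.n_flowers
    if c.shape != (n, n):
        raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
    if c.sum() <= 0:
        raise NoDataError("no transitions in the count matrix")
    return c


def contiguity_preference(
    counts, array: FlowerArray, allow_self: bool = True
) -> ContiguityResult:
    """Proportion of transitions landing on an angular neighbour.

    The chance expectation is 2/n when the chance model allows
    self-transitions, 2/(n−1) otherwise.
    """
    c = _validated_counts(counts, array)
    n = array.n_flowers
    adjacent = sum(c[i - 1, j - 1] for i, j in neighbor_pairs(array))
    total = c.sum()
    expected = 2.0 / n if allow_self else 2.0 / (n - 1)
    return ContiguityResult(
        observed_proportion=float(adjacent / total),
        expected_proportion=expected,
        n_transitions=int(round(total)),
    )


def vertical_bias(
    counts,
    array: FlowerArray,
    directed: bool = True,
    row_conditional: bool = False,
) -> VerticalBiasResult:
    """Spearman correlation between neighbour-pair frequency and travel angle.

    With ``directed=True`` (default) the 2n directed neighbour pairs are used,
    each with its directed travel angle (0° up … 180° down). The undirected
    variant sums counts over both directions of each of the n undirected
    pairs and folds angles into [0°, 90°]. Frequencies are proportions of all
    transitions by default; ``row_conditional=True`` normalises within each
    source flower instead. Constant frequencies leave rho undefined (None)
    with a warning.
    """
    c = _validated_counts(counts, array)
    total = c.sum()
    row_tot = c.sum(axis=1)

    rows = []
    if directed:
        for i, j in neighbor_pairs(array):
            count = c[i - 1, j - 1]
            denom = row_tot[i - 1] if row_conditional else total
            freq = count / denom if denom > 0 else 0.0
            angle = travel_angle_from_vertical(array.position(i), array.position(j))
            rows.append((i, j, count, freq, angle))
    else:
        n = array.n_flowers
        for i in range(1, n + 1):
            j = i % n + 1
            count = c[i - 1, j - 1] + c[j - 1, i - 1]
            denom = row_tot[i - 1] + row_tot[j - 1] if row_conditional else total
            freq = count / denom if denom > 0 else 0.0
            angle = travel_angle_from_vertical(
                array.position(i), array.position(j), directed=False
            )
            rows.append((i, j, count, freq, angle))
    pairs = pd.DataFrame(
        rows, columns=["from_flower", "to_flower", "count", "frequency", "angle_deg"]
    )
    # geometrically equal angles must tie exactly for the rank correlation
    pairs["angle_deg"] = pairs["angle_deg"].round(9)
    try:
        rho = spearman_rho(pairs["frequency"], pairs["angle_deg"])
    except UndefinedCorrelationError:
        logger.warning("vertical-bias rho undefined: constant frequencies or angles")
        rho = None
    return VerticalBiasResult(pairs=pairs, rho=rho, n_pairs=len(pairs))
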