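"""Triangular-fuzzy transport costs between supply and demand departments.

Moving a bed between two departments has no single crisp price; the cost is
expressed as a triangular fuzzy number (TFN) built from the two departments'
stay loads D and S:

    X~ = (floor, min(D, S), max(D, S))        floor = 5 by default

and defuzzified with the mode-weighted ranking

    x = (a + 8b + c) / 10,

which keeps the crisp cost inside the TFN's support and close to its mode.
By default the load of a department is its annual patient-days, so a pair of
busy departments prices higher than a pair of quiet ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TriangularFuzzyNumber", "make_cost_tfn", "rank_defuzzify", "cost_matrix"]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """TFN (a, b, c) with left support a, mode b, right support c; a <= b <= c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"TFN requires a <= b <= c, got ({self.a}, {self.b}, {self.c})")


def make_cost_tfn(
    demand_load: float, supply_load: float, floor_value: float = 5.0
) -> TriangularFuzzyNumber:
    """TFN (floor, min(D,S), max(D,S)) for one supply/demand department pair.

    Both loads must sit at or above the floor so that the triangle ordering
    holds; which side occupies the D slot is irrelevant under min/max.
    """
    lo, hi = min(demand_load, supply_load), max(demand_load, supply_load)
    if lo < floor_value:
        raise ValueError(
            f"department load {lo} is below the TFN floor {floor_value}; "
            "the triangle ordering (floor, min, max) would be violated"
        )
    return TriangularFuzzyNumber(floor_value, lo, hi)


def rank_defuzzify(t: TriangularFuzzyNumber) -> float:
    """Crisp ranking value (a + 8b + c)/10 — a weighted average dominated by the mode."""
    return (t.a + 8.0 * t.b + t.c) / 10.0


def cost_matrix(
    supply_loads: Sequence[float],
    demand_loads: Sequence[float],
    floor_value: float = 5.0,
) -> np.ndarray:
    """Defuzzified cost matrix, entry (i, j) for supply i shipping to demand j.

    Row/column order follows the input order, so the matrix lines up with the
    transportation instance built from the same department lists.
    """
    if len(supply_loads) == 0 or len(demand_loads) == 0:
        raise ValueError("both the supply side and the demand side must be nonempty")
    out = np.empty((len(supply_loads), len(demand_loads)), dtype=float)
    for i, s in enumerate(supply_loads):
        for j, d in enumerate(demand_loads):
            out[i, j] = rank_defuzzify(make_cost_tfn(d, s, floor_value))
    return out
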