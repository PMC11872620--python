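"""Projected impact of a bed-reallocation plan on each department.

Once the transportation stage has decided which beds move where, the chain
of projections per department is

    new_beds       = old_beds + received - sent
    New ALOS       = (new_beds - old_beds) * 365 / trunc(old ALOS)
    Changes        = patient_days / New ALOS
    new_admissions = admissions + Changes

"New ALOS" here is a *turnover projection* (bed-days gained per year spread
over the old per-stay duration), not a literal average stay; its sign tracks
the direction of the capacity change, and so do Changes and the admission
delta.  The divisor is the old ALOS truncated to a whole day by default —
the convention under which published worked tables reproduce — with a
full-precision mode available.

Reporting conventions (kept out of the stored full-precision values and
applied only when formatting): Changes truncated toward zero at 2 decimals,
new admissions truncated at 1 decimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("bedalloc")

from .ward_metrics import DepartmentRecord, alos

__all__ = [
    "ReallocationReport",
    "apply_plan",
    "new_alos",
    "admission_changes",
    "new_admissions",
    "build_report",
    "summarize",
    "trunc_decimals",
]


def trunc_decimals(x: float, digits: int) -> float:
    """Truncate toward zero at ``digits`` decimals, guarding float artifacts."""
    scaled = x * 10**digits
    nearest = round(scaled)
    if abs(scaled - nearest) < 1e-7:
        scaled = nearest
    return math.trunc(scaled) / 10**digits


def apply_plan(
    records: Sequence[DepartmentRecord],
    moves: Sequence[tuple[str, str, int]],
    overrides: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """New bed capacities after executing ``moves`` (from, to, beds) triples.

    ``overrides`` pins selected departments to an explicit new capacity after
    the moves are applied (used to reproduce published tables that zero out a
    supplier beyond its traded quota); it is never applied silently.
    """
    new_beds = {r.name: r.beds for r in records}
    for src, dst, q in moves:
        if src not in new_beds or dst not in new_beds:
            raise ValueError(f"move {src}->{dst} references an unknown department")
        if q < 0:
            raise ValueError("moves must carry nonnegative bed counts")
        new_beds[src] -= q
        new_beds[dst] += q
    for name, beds in (overrides or {}).items():
        if name not in new_beds:
            raise ValueError(f"override for unknown department {name!r}")
        new_beds[name] = int(beds)
    for name, beds in new_beds.items():
        if beds < 0:
            raise ValueError(f"{name}: plan drives capacity negative ({beds})")
    return new_beds


def new_alos(
    old_beds: int,
    new_beds: int,
    old_alos: float,
    divisor_rule: str = "truncate",
) -> float:
    """Turnover projection (new_beds - old_beds) * 365 / divisor.

    ``divisor_rule='truncate'`` divides by the old ALOS floored to a whole
    day; ``'full'`` uses the exact ALOS.  A sub-1-day ALOS truncates to zero,
    which is rejected under the truncating rule.
    """
    if divisor_rule == "truncate":
        divisor = float(math.trunc(old_alos))
    elif divisor_rule == "full":
        divisor = float(old_alos)
    else:
        raise ValueError(f"unknown divisor rule {divisor_rule!r}")
    if divisor <= 0:
        raise ValueError(
            f"ALOS {old_alos} gives divisor {divisor}; use divisor_rule='full' "
            "for departments with average stays under one day"
        )
    return (new_beds - old_beds) * 365.0 / divisor


def admission_changes(patient_days: float, new_alos_value: float) -> float:
    """Admission delta patient_days / New ALOS (sign inherited)."""
    if new_alos_value == 0:
        raise ValueError("New ALOS is zero: the admission change is undefined")
    return patient_days / new_alos_value


def new_admissions(admissions: float, changes: float) -> float:
    """Projected admissions: old count plus the (signed) change."""
    return admissions + changes


@dataclass(frozen=True)
class ReallocationReport:
    """Per-department projection table plus totals.

    ``frame`` columns: name, old_beds, new_beds, alos, new_alos, changes,
    new_admissions — all at full precision.  ``formatted()`` applies the
    table conventions (truncations) used for display.
    """

    frame: pd.DataFrame
    old_total_admissions: int
    new_total_admissions: float
    increase: float
    unassigned_beds: int

    def formatted(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["new_alos"] = [trunc_decimals(v, 1) for v in out["new_alos"]]
        out["changes"] = [trunc_decimals(v, 2) for v in out["changes"]]
        out["new_admissions"] = [trunc_decimals(v, 1) for v in out["new_admissions"]]
        return out

    def totals(self) -> dict:
        return {
            "old_admissions": self.old_total_admissions,
            "new_admissions": round(self.new_total_admissions, 1),
            "increase": round(self.increase, 1),
            "unassigned_beds": self.unassigned_beds,
        }


def build_report(
    records: Sequence[DepartmentRecord],
    new_beds: Mapping[str, int],
    divisor_rule: str = "truncate",
    unassigned_beds: int = 0,
    redistribute_unassigned: bool = False,
) -> ReallocationReport:
    """Assemble the full projection chain for every department.

    Departments whose capacity is unchanged keep their admissions as-is
    (their New ALOS is zero and no change is projected).  When
    ``redistribute_unassigned`` is set, all unshipped supply beds are added
    to the department with the largest projected new admissions and the
    chain is recomputed once for that department.
    """
    capacities = dict(new_beds)

    def chain(rec: DepartmentRecord) -> dict:
        nb = capacities[rec.name]
        a = alos(rec)
        if nb == rec.beds:
            na_val, ch = 0.0, 0.0
        else:
            rule = divisor_rule
            if rule == "truncate" and math.trunc(a) == 0:
                # sub-1-day average stay: the whole-day divisor degenerates
                logger.warning(
                    "%s: ALOS %.3f truncates to 0; using full-precision divisor",
                    rec.name, a,
                )
                rule = "full"
            na_val = new_alos(rec.beds, nb, a, rule)
            ch = admission_changes(rec.patient_days, na_val)
        return {
            "name": rec.name,
            "old_beds": rec.beds,
            "new_beds": nb,
            "alos": a,
            "new_alos": na_val,
            "changes": ch,
            "new_admissions": new_admissions(rec.admissions, ch),
        }

    rows = [chain(r) for r in records]
    remaining_unassigned = unassigned_beds
    if redistribute_unassigned and unassigned_beds > 0 and rows:
        target = max(rows, key=lambda r: r["new_admissions"])["name"]
        capacities[target] += unassigned_beds
        rows = [chain(r) for r in records]
        remaining_unassigned = 0
    frame = pd.DataFrame(rows)
    old_total = int(sum(r.admissions for r in records))
    new_total = float(frame["new_admissions"].sum()) if rows else 0.0
    return ReallocationReport(
        frame=frame,
        old_total_admissions=old_total,
        new_total_admissions=new_total,
        increase=new_total - old_total,
        unassigned_beds=remaining_unassigned,
    )


def summarize(report: ReallocationReport, optimal_cost: float | None = None) -> dict:
    """Totals block: optimal transport cost, old/new admissions, increase."""
    out = report.totals()
    if optimal_cost is not None:
        out["optimal_cost"] = optimal_cost
    return out
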