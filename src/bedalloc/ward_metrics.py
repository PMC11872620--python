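"""Per-department occupancy metrics and the demand/supply classification.

Each department contributes a row of annual aggregates: installed beds,
admissions and patient-days.  From those we derive

* ALOS            = patient_days / admissions                       (days)
* excess beds     = beds - patient_days / 365                       (beds)
* occupancy %     = 100 * (patient_days / 365) / beds, floored      (percent)
* Needs           = (admissions / 365) * P(LOS) - beds              (beds)

where P(LOS) is the capacity-adjusted stay score from
:mod:`bedalloc.distributions`.  A positive Needs value marks a *demand*
department (it must receive beds), a negative one a *supply* department (it
can release beds); the integer bed quota traded in the transportation stage
is |Needs| truncated toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DepartmentRecord",
    "DepartmentMetrics",
    "alos",
    "excess_beds",
    "occupancy_pct",
    "needs",
    "classify",
    "metrics_frame",
    "read_department_table",
    "write_department_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = ("name", "beds", "admissions", "patient_days")


@dataclass(frozen=True)
class DepartmentRecord:
    """Raw annual inputs for one department."""

    name: str
    beds: int
    admissions: int
    patient_days: int

    def __post_init__(self) -> None:
        if self.beds < 1:
            raise ValueError(f"{self.name}: beds must be >= 1, got {self.beds}")
        if self.admissions < 1:
            raise ValueError(f"{self.name}: admissions must be >= 1")
        if self.patient_days <= 0:
            raise ValueError(f"{self.name}: patient_days must be positive")


@dataclass(frozen=True)
class DepartmentMetrics:
    """Derived metrics for one department (full precision kept throughout)."""

    record: DepartmentRecord
    alos: float
    excess_beds: float
    occupancy_pct: int
    plos: float
    needs: float
    side: str  # "demand" | "supply" | "neutral"
    quota: int


def alos(record: DepartmentRecord) -> float:
    """Average length of stay: annual patient-days per admission."""
    return record.patient_days / record.admissions


def excess_beds(record: DepartmentRecord) -> float:
    """Installed beds minus the average daily census patient_days/365."""
    return record.beds - record.patient_days / 365.0


def occupancy_pct(record: DepartmentRecord) -> int:
    """Average occupancy percentage, truncated to a whole percent.

    Values above 100 indicate a department running beyond its installed
    capacity on the average day.
    """
    value = (record.patient_days / 365.0) / record.beds * 100.0
    # guard against 99.999999 artifacts before flooring
    return math.trunc(round(value, 9))


def needs(record: DepartmentRecord, plos: float) -> float:
    """Bed need: projected admission load (admissions/365)*P(LOS) minus beds."""
    if plos < 0:
        raise ValueError("plos must be nonnegative")
    return (record.admissions / 365.0) * plos - record.beds


def _side_and_quota(needs_value: float) -> tuple[str, int]:
    if needs_value > 0:
        return "demand", math.trunc(needs_value)
    if needs_value < 0:
        return "supply", math.trunc(-needs_value)
    return "neutral", 0


def classify(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach ``side`` and integer ``quota`` columns from a ``needs`` column.

    demand if needs > 0, supply if needs < 0, neutral at exactly 0; the quota
    is |needs| truncated toward zero (whole beds only are traded).
    """
    if "needs" not in frame.columns:
        raise ValueError("frame must carry a 'needs' column")
    out = frame.copy()
    sides, quotas = zip(*(_side_and_quota(v) for v in out["needs"]))
    out["side"] = sides
    out["quota"] = quotas
    return out


def metrics_frame(
    records: Sequence[DepartmentRecord], plos: Sequence[float]
) -> pd.DataFrame:
    """Full metrics table for a set of departments given their P(LOS) scores."""
    if len(records) != len(plos):
        raise ValueError("one plos value per department is required")
    rows = []
    for rec, score in zip(records, plos):
        n = needs(rec, score)
        side, quota = _side_and_quota(n)
        rows.append(
            {
                "name": rec.name,
                "beds": rec.beds,
                "admissions": rec.admissions,
                "patient_days": rec.patient_days,
                "alos": alos(rec),
                "excess_beds": excess_beds(rec),
                "occupancy_pct": occupancy_pct(rec),
                "plos": score,
                "needs": n,
                "side": side,
                "quota": quota,
            }
        )
    return pd.DataFrame(rows)


def read_department_table(path: str | Path) -> list[DepartmentRecord]:
    """Read a department CSV with the strict header name,beds,admissions,patient_days."""
    df = pd.read_csv(path, encoding="utf-8")
    if tuple(df.columns) != TABLE_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(TABLE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    return [
        DepartmentRecord(
            name=str(r.name),
            beds=int(r.beds),
            admissions=int(r.admissions),
            patient_days=int(r.patient_days),
        )
        for r in df.itertuples(index=False)
    ]


def write_department_table(records: Iterable[DepartmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": r.name, "beds": r.beds, "admissions": r.admissions,
             "patient_days": r.patient_days}
            for r in records
        ]
    ).to_csv(path, index=False)
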