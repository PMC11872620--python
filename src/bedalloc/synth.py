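"""Synthetic department tables and raw length-of-stay samples.

The generator emulates the structure of an annual hospital census table:
eight departments by default, each with installed beds, yearly admissions
and total patient-days, where individual stays follow a department-specific
Lomax law (heavy right tail: most stays short, a few very long).

A usable table must feed the transportation stage, so the generator
engineers at least one department onto each market side *under the derived
parameter chain* (rates -> Lomax -> stay mass -> capacity-adjusted P(LOS)
-> Needs):

* department 1 is a high-volume, over-occupied unit (think a large
  emergency/general-medicine service with short stays) — its Needs score is
  positive, i.e. it demands beds;
* department 2 is a long-stay, under-occupied unit — its Needs score is
  negative, i.e. it supplies beds;
* the remaining departments are drawn freely from the configured ranges.

Stays are kept continuous internally and rounded only when the annual
patient-day aggregate is emitted; everything is reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import distributions as dist
from .ward_metrics import DepartmentRecord, needs

__all__ = ["SynthConfig", "simulate_los_samples", "simulate_department_table"]

YEAR_DAYS = 365


@dataclass(frozen=True)
class SynthConfig:
    """Ranges the department generator draws from (all uniform).

    Occupancy is the ratio of average daily census to installed beds.
    Generic departments draw admissions in the 800-5000/yr band, Lomax shape
    1.5-4 and scale 2-12 days (mean stays roughly 0.7-24 days) — the
    magnitudes of real annual department censuses.  The engineered demand
    department runs at 9000-13000 admissions/yr with short stays (2-5 days)
    above full occupancy; the engineered supply department at long stays
    (8-18 days) well below capacity.
    """

    n_departments: int = 8
    admissions_range: tuple[int, int] = (800, 5000)
    shape_range: tuple[float, float] = (1.5, 4.0)
    scale_range: tuple[float, float] = (2.0, 12.0)
    occupancy_range: tuple[float, float] = (0.55, 1.35)
    demand_admissions_range: tuple[int, int] = (9000, 13000)
    demand_alos_range: tuple[float, float] = (2.0, 5.0)
    supply_alos_range: tuple[float, float] = (8.0, 18.0)
    seed: int = 0
    year_days: int = YEAR_DAYS

    def __post_init__(self) -> None:
        if self.n_departments < 1:
            raise ValueError("need at least one department")
        for name in (
            "admissions_range", "shape_range", "scale_range", "occupancy_range",
            "demand_admissions_range", "demand_alos_range", "supply_alos_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) pair, got {(lo, hi)}")


def simulate_los_samples(
    params: dist.LomaxParams, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` stays by inverse-CDF sampling x = beta*((1-u)^(-1/alpha) - 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    return params.scale * ((1.0 - u) ** (-1.0 / params.shape) - 1.0)


def _derived_needs(record: DepartmentRecord) -> float:
    """Needs score under the default derived chain (min stay 5, cap 10%/bed)."""
    rates = dist.rates_from_counts(record.admissions, record.patient_days, record.beds)
    params = dist.params_from_rates(rates)
    zeta = dist.stay_mass(params)
    return needs(record, dist.adjusted_plos(zeta, record.beds))


def _make_department(
    name: str,
    admissions: int,
    params: dist.LomaxParams,
    occupancy: float,
    year_days: int,
    rng: np.random.Generator,
) -> tuple[DepartmentRecord, np.ndarray]:
    stays = simulate_los_samples(params, admissions, rng)
    patient_days = max(1, int(round(float(np.sum(stays)))))
    beds = max(1, int(round(patient_days / (year_days * occupancy))))
    rec = DepartmentRecord(name=name, beds=beds, admissions=admissions,
                          patient_days=patient_days)
    return rec, stays


def simulate_department_table(
    config: SynthConfig = SynthConfig(),
) -> tuple[list[DepartmentRecord], dict[str, np.ndarray]]:
    """Generate a department table plus the raw per-stay samples behind it.

    Returns ``(records, samples)`` where ``samples[name]`` holds the stays
    whose (rounded) sum is that department's patient_days.  Bit-identical
    output under the same config.  With two or more departments the first is
    engineered to demand beds and the second to supply them; a warning is
    emitted if the configured ranges still fail to produce both sides.
    """
    rng = np.random.default_rng(config.seed)
    records: list[DepartmentRecord] = []
    samples: dict[str, np.ndarray] = {}
    occ_lo, occ_hi = config.occupancy_range
    shape_floor = max(2.0, config.shape_range[0])  # finite-mean stays for targets
    for k in range(config.n_departments):
        name = f"D{k + 1:02d}"
        if k == 0 and config.n_departments >= 2:
            admissions = int(rng.integers(*config.demand_admissions_range))
            target_alos = rng.uniform(*config.demand_alos_range)
            shape = rng.uniform(shape_floor, max(shape_floor, config.shape_range[1]))
            params = dist.LomaxParams(shape, target_alos * (shape - 1.0))
            occupancy = rng.uniform(max(1.05, occ_lo), max(1.1, occ_hi))
        elif k == 1:
            admissions = int(rng.integers(config.admissions_range[0],
                                          config.admissions_range[1] + 1))
            target_alos = rng.uniform(*config.supply_alos_range)
            shape = rng.uniform(shape_floor, max(shape_floor, config.shape_range[1]))
            params = dist.LomaxParams(shape, target_alos * (shape - 1.0))
            occupancy = rng.uniform(min(0.55, occ_lo), min(0.9, occ_hi))
        else:
            admissions = int(rng.integers(config.admissions_range[0],
                                          config.admissions_range[1] + 1))
            params = dist.LomaxParams(rng.uniform(*config.shape_range),
                                      rng.uniform(*config.scale_range))
            occupancy = rng.uniform(occ_lo, occ_hi)
        rec, stays = _make_department(name, admissions, params, occupancy,
                                      config.year_days, rng)
        records.append(rec)
        samples[name] = stays
    if config.n_departments >= 2:
        signs = [_derived_needs(r) for r in records]
        if not (max(signs) > 0 and min(signs) < 0):
            warnings.warn(
                "configured ranges did not produce both a demand and a supply "
                "department; the transportation stage may have an empty side",
                stacklevel=2,
            )
    return records, samples
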