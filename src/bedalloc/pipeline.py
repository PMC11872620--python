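"""End-to-end orchestration: census table in, reallocation plan out.

Stages, in order:

1. per-department metrics (ALOS, excess beds, occupancy);
2. Lomax rate parameters (p, m) -> (alpha, beta) -> stay mass zeta ->
   capacity-adjusted P(LOS) (or a caller-supplied P(LOS) column);
3. Needs score, demand/supply classification, integer bed quotas;
4. defuzzified triangular-fuzzy cost matrix between the two sides;
5. balanced minimum-cost transportation solve;
6. projected New ALOS / admission changes / new admissions per department.

The run is a pure function of (table, config): identical inputs give
bit-identical outputs, and every intermediate is captured in a trace dict so
the final report can be audited from the trace alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import distributions as dist
from . import fuzzy_cost, reallocation, transport
from .synth import SynthConfig, simulate_department_table
from .ward_metrics import (
    DepartmentRecord,
    metrics_frame,
    read_department_table,
    write_department_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run", "fit", "simulate", "export_outputs"]

logger = logging.getLogger("bedalloc")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full chain; defaults are the published conventions."""

    min_stay: int = 5
    max_stay: int = 365
    cap_fraction: float = 0.1
    rate_convention: str = "reconstructed"  # or "literal"
    divisor_rule: str = "truncate"  # or "full"
    cost_load: str = "patient_days"  # or "alos" | "needs"
    tfn_floor: float = 5.0
    solver: str = "modi"  # or "lp"
    redistribute_dummy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_stay <= self.max_stay):
            raise ValueError("need 0 <= min_stay <= max_stay")
        if not (0 <= self.cap_fraction <= 1):
            raise ValueError("cap_fraction must lie in [0, 1]")


@dataclass
class PipelineResult:
    """Everything a run produces; ``plan``/``report`` are None when the
    table has no demand or no supply side (``no_instance_reason`` says why)."""

    metrics: pd.DataFrame
    plan: transport.TransportPlan | None
    moves: list[tuple[str, str, int]]
    unassigned: dict[str, int]
    report: reallocation.ReallocationReport | None
    trace: dict
    no_instance_reason: str | None = None


def _department_plos(
    rec: DepartmentRecord, config: PipelineConfig, trace_row: dict
) -> float:
    rates = dist.rates_from_counts(
        rec.admissions, rec.patient_days, rec.beds, config.rate_convention
    )
    params = dist.params_from_rates(rates)
    zeta = dist.stay_mass(params, config.min_stay, config.max_stay)
    plos = dist.adjusted_plos(zeta, rec.beds, config.cap_fraction)
    trace_row.update(
        p=rates.p, m=rates.m, alpha=params.shape, beta=params.scale, zeta=zeta
    )
    return plos


def _loads(metrics: pd.DataFrame, kind: str) -> pd.Series:
    if kind == "patient_days":
        return metrics["patient_days"].astype(float)
    if kind == "alos":
        return metrics["alos"]
    if kind == "needs":
        return metrics["needs"].abs()
    raise ValueError(f"unknown cost load convention {kind!r}")


def run(
    records: Sequence[DepartmentRecord],
    config: PipelineConfig = PipelineConfig(),
    plos: Sequence[float] | Mapping[str, float] | None = None,
    nb_overrides: Mapping[str, int] | None = None,
    moves_override: Sequence[tuple[str, str, int]] | None = None,
) -> PipelineResult:
    """Run the full chain on a department table.

    ``plos`` injects precomputed P(LOS) scores (sequence aligned with
    ``records`` or a name-keyed mapping) instead of deriving them from the
    Lomax chain — useful when reproducing a published table whose underlying
    (alpha, beta) are not recoverable.  ``nb_overrides`` pins new bed counts
    after the plan is applied, and ``moves_override`` replays an externally
    given set of moves instead of solving.
    """
    if len(records) < 1:
        raise ValueError("need at least one department")
    trace: dict = {"config": asdict(config), "departments": {}}
    for rec in records:
        trace["departments"][rec.name] = {
            "beds": rec.beds, "admissions": rec.admissions,
            "patient_days": rec.patient_days,
        }

    logger.info("computing P(LOS) for %d departments", len(records))
    if plos is None:
        plos_values = [
            _department_plos(rec, config, trace["departments"][rec.name])
            for rec in records
        ]
    elif isinstance(plos, Mapping):
        plos_values = [float(plos[rec.name]) for rec in records]
    else:
        if len(plos) != len(records):
            raise ValueError("plos sequence must align with records")
        plos_values = [float(v) for v in plos]

    metrics = metrics_frame(records, plos_values)
    for row in metrics.itertuples(index=False):
        trace["departments"][row.name].update(
            alos=row.alos, excess_beds=row.excess_beds,
            occupancy_pct=row.occupancy_pct, plos=row.plos,
            needs=row.needs, side=row.side, quota=row.quota,
        )

    supply = metrics[(metrics.side == "supply") & (metrics.quota > 0)]
    demand = metrics[(metrics.side == "demand") & (metrics.quota > 0)]
    if supply.empty or demand.empty:
        reason = (
            "no transportation instance: the table has "
            f"{len(demand)} demand and {len(supply)} supply departments "
            "with nonzero quotas"
        )
        logger.warning(reason)
        return PipelineResult(
            metrics=metrics, plan=None, moves=[], unassigned={},
            report=None, trace=trace, no_instance_reason=reason,
        )

    if moves_override is not None:
        moves = [(str(s), str(d), int(q)) for s, d, q in moves_override]
        unassigned_total = int(supply["quota"].sum()) - sum(q for *_, q in moves)
        unassigned = {"(externally given plan)": unassigned_total} if unassigned_total else {}
        plan = None
        trace["moves_override"] = moves
    else:
        costs = fuzzy_cost.cost_matrix(
            _loads(supply, config.cost_load).tolist(),
            _loads(demand, config.cost_load).tolist(),
            config.tfn_floor,
        )
        instance = transport.TransportInstance(
            supplies=tuple(int(q) for q in supply["quota"]),
            demands=tuple(int(q) for q in demand["quota"]),
            costs=costs,
        )
        logger.info(
            "solving %dx%d transport instance (supply %d, demand %d beds)",
            len(instance.supplies), len(instance.demands),
            sum(instance.supplies), sum(instance.demands),
        )
        plan = transport.solve(instance, method=config.solver)
        moves, unassigned = transport.report_allocations(
            plan, supply["name"].tolist(), demand["name"].tolist()
        )
        trace["cost_matrix"] = costs.tolist()
        trace["supplies"] = list(map(int, instance.supplies))
        trace["demands"] = list(map(int, instance.demands))
        trace["supply_names"] = supply["name"].tolist()
        trace["demand_names"] = demand["name"].tolist()
        trace["allocation"] = plan.allocation.tolist()
        trace["objective"] = plan.objective

    new_beds = reallocation.apply_plan(records, moves, overrides=nb_overrides)
    report = reallocation.build_report(
        records,
        new_beds,
        divisor_rule=config.divisor_rule,
        unassigned_beds=sum(unassigned.values()),
        redistribute_unassigned=config.redistribute_dummy,
    )
    trace["moves"] = [list(mv) for mv in moves]
    trace["unassigned"] = dict(unassigned)
    trace["new_beds"] = dict(new_beds)
    trace["totals"] = report.totals()
    return PipelineResult(
        metrics=metrics, plan=plan, moves=list(moves), unassigned=dict(unassigned),
        report=report, trace=trace,
    )


def fit(samples: Sequence[float], families: Sequence[str] = dist.GOF_FAMILIES) -> pd.DataFrame:
    """Goodness-of-fit table (K-S, AIC, BIC) for a raw LOS sample, best first."""
    results = dist.gof_compare(samples, families)
    return pd.DataFrame([r.to_dict() for r in results])


def read_los_samples(path: str | Path) -> np.ndarray:
    """Plain-text LOS sample file: one positive real per line."""
    values = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from exc
    return np.asarray(values, dtype=float)


def simulate(config: SynthConfig, outdir: str | Path) -> dict:
    """Write a synthetic department CSV, per-department sample files and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, samples = simulate_department_table(config)
    table_path = outdir / "departments.csv"
    write_department_table(records, table_path)
    sample_paths = {}
    for name, stays in samples.items():
        p = outdir / f"los_{name}.txt"
        np.savetxt(p, stays, fmt="%.6f")
        sample_paths[name] = p.name
    manifest = {
        "seed": config.seed,
        "n_departments": config.n_departments,
        "table": table_path.name,
        "samples": sample_paths,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def export_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write metrics CSV, report CSV, plan JSON/CSV and totals JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "trace.json").write_text(json.dumps(result.trace, indent=2))
    if result.report is not None:
        result.report.formatted().to_csv(outdir / "report.csv", index=False)
        totals = result.report.totals()
        if result.plan is not None:
            totals["optimal_cost"] = result.plan.objective
        (outdir / "totals.json").write_text(json.dumps(totals, indent=2))
    if result.moves:
        pd.DataFrame(result.moves, columns=["from", "to", "beds"]).to_csv(
            outdir / "plan.csv", index=False
        )


def run_table(path: str | Path, config: PipelineConfig = PipelineConfig(),
              plos_column: str | None = None, **kwargs) -> PipelineResult:
    """Convenience wrapper: read a CSV (optionally with an extra P(LOS) column) and run.

    With ``plos_column`` the CSV may carry a fifth column of precomputed
    P(LOS) scores, which bypasses the Lomax derivation.
    """
    if plos_column is None:
        return run(read_department_table(path), config, **kwargs)
    df = pd.read_csv(path, encoding="utf-8")
    if plos_column not in df.columns:
        raise ValueError(f"{path}: no column {plos_column!r}")
    records = [
        DepartmentRecord(name=str(r["name"]), beds=int(r["beds"]),
                         admissions=int(r["admissions"]),
                         patient_days=int(r["patient_days"]))
        for _, r in df.iterrows()
    ]
    return run(records, config, plos=df[plos_column].tolist(), **kwargs)
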