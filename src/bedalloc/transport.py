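"""Minimum-cost transportation solver for integer bed quotas.

An instance has supplies ``a_i`` (beds each supply department can release),
demands ``b_j`` (beds each demand department must receive) and a cost matrix
``c_ij`` per moved bed; the objective is min sum c_ij x_ij subject to the
row/column constraints with x_ij >= 0.  Hospital instances are typically
*unbalanced* (total supply != total demand), so a zero-cost dummy row or
column absorbs the slack before solving.

Two optimizers are provided: the classical MODI (u-v) method on top of a
northwest-corner or Vogel initial basic solution, and an LP formulation via
``scipy.optimize.linprog`` used as an independent route to the same optimum.
Because the constraint matrix is totally unimodular, integer supplies and
demands always admit an integral optimal allocation; MODI preserves it by
construction and the LP route returns a vertex solution that is rounded back
to integers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "TransportInstance",
    "TransportPlan",
    "balance",
    "initial_solution",
    "optimize",
    "solve",
    "report_allocations",
    "TransportError",
]

_TOL = 1e-9


class TransportError(RuntimeError):
    """Infeasible instance or a solver that failed to converge."""


@dataclass(frozen=True)
class TransportInstance:
    """Supplies, demands and per-unit costs of a transportation problem."""

    supplies: tuple[int, ...]
    demands: tuple[int, ...]
    costs: np.ndarray  # shape (len(supplies), len(demands))

    def __post_init__(self) -> None:
        costs = np.asarray(self.costs, dtype=float)
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "supplies", tuple(int(s) for s in self.supplies))
        object.__setattr__(self, "demands", tuple(int(d) for d in self.demands))
        if any(s < 0 for s in self.supplies) or any(d < 0 for d in self.demands):
            raise ValueError("supplies and demands must be nonnegative")
        if costs.shape != (len(self.supplies), len(self.demands)):
            raise ValueError(
                f"cost matrix shape {costs.shape} does not match "
                f"{len(self.supplies)} supplies x {len(self.demands)} demands"
            )

    @property
    def balanced(self) -> bool:
        return sum(self.supplies) == sum(self.demands)


@dataclass(frozen=True)
class TransportPlan:
    """Integral allocation with its objective over non-dummy cells.

    ``dummy_row``/``dummy_column`` record a zero-cost slack line appended by
    :func:`balance`; allocations into it are unshipped supply (or unmet
    demand), not real moves.
    """

    allocation: np.ndarray  # integer matrix, same shape as instance costs
    objective: float
    dummy_row: int | None = None
    dummy_column: int | None = None
    basis: frozenset = field(default_factory=frozenset)

    def real_allocation(self) -> np.ndarray:
        """Allocation with any dummy line removed."""
        out = self.allocation
        if self.dummy_row is not None:
            out = np.delete(out, self.dummy_row, axis=0)
        if self.dummy_column is not None:
            out = np.delete(out, self.dummy_column, axis=1)
        return out


def balance(instance: TransportInstance) -> tuple[TransportInstance, int | None, int | None]:
    """Append a zero-cost dummy demand (or supply) so totals match.

    Returns ``(balanced_instance, dummy_row, dummy_column)`` where the dummy
    indices are ``None`` if that side was not padded.
    """
    total_s, total_d = sum(instance.supplies), sum(instance.demands)
    if total_s == total_d:
        return instance, None, None
    if total_s > total_d:
        costs = np.hstack([instance.costs, np.zeros((len(instance.supplies), 1))])
        inst = TransportInstance(
            supplies=instance.supplies,
            demands=instance.demands + (total_s - total_d,),
            costs=costs,
        )
        return inst, None, costs.shape[1] - 1
    costs = np.vstack([instance.costs, np.zeros((1, len(instance.demands)))])
    inst = TransportInstance(
        supplies=instance.supplies + (total_d - total_s,),
        demands=instance.demands,
        costs=costs,
    )
    return inst, costs.shape[0] - 1, None


# ---------------------------------------------------------------------------
# Initial basic feasible solutions
# ---------------------------------------------------------------------------


def _northwest(instance: TransportInstance) -> tuple[np.ndarray, set]:
    m, n = instance.costs.shape
    a = list(instance.supplies)
    b = list(instance.demands)
    x = np.zeros((m, n), dtype=np.int64)
    basis: set = set()
    i = j = 0
    while i < m and j < n:
        q = min(a[i], b[j])
        x[i, j] = q
        basis.add((i, j))
        a[i] -= q
        b[j] -= q
        if i == m - 1 and j == n - 1:
            break
        # move down when the row is exhausted, right otherwise; a tie keeps a
        # zero-allocation basic cell on the next step (degeneracy patch)
        if a[i] == 0 and i < m - 1:
            i += 1
        else:
            j += 1
    return x, basis


def _vogel(instance: TransportInstance) -> tuple[np.ndarray, set]:
    m, n = instance.costs.shape
    a = np.array(instance.supplies, dtype=np.int64)
    b = np.array(instance.demands, dtype=np.int64)
    c = instance.costs
    x = np.zeros((m, n), dtype=np.int64)
    basis: set = set()
    row_live = a > 0
    col_live = b > 0
    # rows/cols that start at zero never receive an allocation here; the
    # spanning-tree patch below restores a full basis
    while row_live.any() and col_live.any():
        best = None  # (-penalty, i_or_j, axis) -> choose max penalty, lex ties
        live_cols = np.flatnonzero(col_live)
        live_rows = np.flatnonzero(row_live)
        for i in live_rows:
            vals = np.sort(c[i, live_cols])
            pen = vals[1] - vals[0] if vals.size > 1 else vals[0]
            cand = (-pen, 0, int(i))
            if best is None or cand < best:
                best = cand
        for j in live_cols:
            vals = np.sort(c[live_rows, j])
            pen = vals[1] - vals[0] if vals.size > 1 else vals[0]
            cand = (-pen, 1, int(j))
            if best is None or cand < best:
                best = cand
        _, axis, k = best
        if axis == 0:
            i = k
            j = int(live_cols[np.argmin(c[i, live_cols])])
        else:
            j = k
            i = int(live_rows[np.argmin(c[live_rows, j])])
        q = int(min(a[i], b[j]))
        x[i, j] = q
        basis.add((i, j))
        a[i] -= q
        b[j] -= q
        if a[i] == 0:
            row_live[i] = False
        if b[j] == 0:
            col_live[j] = False
    return x, basis


def _patch_basis(basis: set, m: int, n: int) -> set:
    """Grow ``basis`` to a spanning tree (m+n-1 acyclic cells) with zero cells."""
    parent = list(range(m + n))

    def find(u: int) -> int:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(u: int, v: int) -> bool:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
        return True

    basis = set(basis)
    for (i, j) in sorted(basis):
        union(i, m + j)
    for i in range(m):
        for j in range(n):
            if len(basis) == m + n - 1:
                return basis
            if (i, j) not in basis and union(i, m + j):
                basis.add((i, j))
    if len(basis) != m + n - 1:
        raise TransportError("could not build a spanning basis")
    return basis


def initial_solution(
    instance: TransportInstance, method: Literal["northwest", "vogel"] = "vogel"
) -> TransportPlan:
    """Feasible basic starting plan with exactly m+n-1 basic cells."""
    if not instance.balanced:
        raise TransportError("initial_solution requires a balanced instance")
    m, n = instance.costs.shape
    if m == 0 or n == 0:
        raise TransportError("instance has an empty side")
    if method == "northwest":
        x, basis = _northwest(instance)
    elif method == "vogel":
        x, basis = _vogel(instance)
    else:
        raise ValueError(f"unknown initial method {method!r}")
    basis = _patch_basis(basis, m, n)
    objective = float(np.sum(instance.costs * x))
    return TransportPlan(allocation=x, objective=objective, basis=frozenset(basis))


# ---------------------------------------------------------------------------
# MODI (u-v) optimization
# ---------------------------------------------------------------------------


def _potentials(basis: set, costs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m, n = costs.shape
    u = np.full(m, np.nan)
    v = np.full(n, np.nan)
    u[0] = 0.0
    for _ in range(m + n):
        changed = False
        for (i, j) in basis:
            if not np.isnan(u[i]) and np.isnan(v[j]):
                v[j] = costs[i, j] - u[i]
                changed = True
            elif np.isnan(u[i]) and not np.isnan(v[j]):
                u[i] = costs[i, j] - v[j]
                changed = True
        if not changed:
            break
    if np.isnan(u).any() or np.isnan(v).any():
        raise TransportError("basis graph is disconnected; cannot compute potentials")
    return u, v


def _find_cycle(basis: set, entering: tuple[int, int]) -> list[tuple[int, int]]:
    """Unique alternating cycle created by adding ``entering`` to the tree."""
    rows: dict[int, list] = defaultdict(list)
    cols: dict[int, list] = defaultdict(list)
    for cell in basis:
        rows[cell[0]].append(cell)
        cols[cell[1]].append(cell)
    path = [entering]

    def dfs(along_row: bool) -> bool:
        cur = path[-1]
        if not along_row and cur[1] == entering[1] and len(path) >= 4:
            return True
        nxt_cells = rows[cur[0]] if along_row else cols[cur[1]]
        for nxt in sorted(nxt_cells):
            if nxt == cur or nxt in path:
                continue
            path.append(nxt)
            if dfs(not along_row):
                return True
            path.pop()
        return False

    if not dfs(True):
        raise TransportError(f"no pivot cycle through {entering}")
    return path


def optimize(
    plan: TransportPlan,
    instance: TransportInstance,
    method: Literal["modi", "lp"] = "modi",
    max_iter: int = 10_000,
) -> TransportPlan:
    """Drive a feasible plan to global optimality.

    ``modi`` iterates u-v reduced-cost pivots from the given basic plan;
    ``lp`` ignores the starting allocation and re-solves the balanced
    instance as a linear program.  Both return the same objective (the
    transportation LP has no duality gap), and integral data yield an
    integral allocation.
    """
    if method == "lp":
        return _solve_lp(instance)
    if method != "modi":
        raise ValueError(f"unknown optimize method {method!r}")
    costs = instance.costs
    m, n = costs.shape
    x = plan.allocation.copy()
    basis = set(plan.basis)
    if len(basis) != m + n - 1:
        raise TransportError("MODI needs a basic plan with m+n-1 basic cells")
    for _ in range(max_iter):
        u, v = _potentials(basis, costs)
        reduced = costs - u[:, None] - v[None, :]
        reduced_masked = reduced.copy()
        for (i, j) in basis:
            reduced_masked[i, j] = 0.0
        # most negative reduced cost; lexicographic (row, col) on ties
        entering = None
        best = 0.0
        for i in range(m):
            for j in range(n):
                r = reduced_masked[i, j]
                if r >= -_TOL:
                    continue
                if entering is None or r < best - _TOL:
                    best, entering = r, (i, j)
        if entering is None:
            objective = float(np.sum(costs * x))
            return replace(plan, allocation=x, objective=objective,
                           basis=frozenset(basis))
        cycle = _find_cycle(basis, entering)
        minus = cycle[1::2]
        theta = min(int(x[c]) for c in minus)
        leaving = min(c for c in minus if x[c] == theta)
        for c in cycle[0::2]:
            x[c] += theta
        for c in minus:
            x[c] -= theta
        basis.remove(leaving)
        basis.add(entering)
    raise TransportError(f"MODI did not converge within {max_iter} pivots")


def _solve_lp(instance: TransportInstance) -> TransportPlan:
    m, n = instance.costs.shape
    if not instance.balanced:
        raise TransportError("LP route requires a balanced instance")
    a_eq = []
    b_eq = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n : (i + 1) * n] = 1.0
        a_eq.append(row)
        b_eq.append(instance.supplies[i])
    for j in range(n):
        col = np.zeros(m * n)
        col[j::n] = 1.0
        a_eq.append(col)
        b_eq.append(instance.demands[j])
    res = linprog(
        instance.costs.ravel(), A_eq=np.array(a_eq), b_eq=np.array(b_eq),
        bounds=(0, None), method="highs",
    )
    if not res.success:
        raise TransportError(f"LP solve failed: {res.message}")
    x = res.x.reshape(m, n)
    x_int = np.rint(x).astype(np.int64)
    if np.max(np.abs(x - x_int)) > 1e-6:
        raise TransportError("LP vertex is not integral on integer data")
    return TransportPlan(allocation=x_int, objective=float(res.fun))


def solve(
    instance: TransportInstance,
    method: Literal["modi", "lp"] = "modi",
    initial: Literal["northwest", "vogel"] = "vogel",
) -> TransportPlan:
    """Balance, start and optimize in one call; dummy metadata attached."""
    balanced, dummy_row, dummy_col = balance(instance)
    if method == "lp":
        plan = _solve_lp(balanced)
    else:
        plan = optimize(initial_solution(balanced, initial), balanced, "modi")
    return replace(plan, dummy_row=dummy_row, dummy_column=dummy_col)


def report_allocations(
    plan: TransportPlan,
    supply_names: Sequence[str],
    demand_names: Sequence[str],
) -> tuple[list[tuple[str, str, int]], dict[str, int]]:
    """Nonzero real moves as (from, to, beds) plus per-supplier unshipped beds.

    Allocations into the dummy line never appear as moves; they are returned
    in the second element keyed by supplier name (or by demand name when the
    dummy is a supply row, meaning unmet demand).
    """
    moves: list[tuple[str, str, int]] = []
    unassigned: dict[str, int] = {}
    m, n = plan.allocation.shape
    for i in range(m):
        for j in range(n):
            q = int(plan.allocation[i, j])
            if q == 0:
                continue
            if j == plan.dummy_column:
                unassigned[supply_names[i]] = unassigned.get(supply_names[i], 0) + q
            elif i == plan.dummy_row:
                unassigned[demand_names[j]] = unassigned.get(demand_names[j], 0) + q
            else:
                moves.append((supply_names[i], demand_names[j], q))
    return moves, unassigned
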