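"""Brute-force reference implementations, for verification only.

Exhaustively enumerating every binary schedule (or knapsack subset) is the
independent ground truth against which the MIP and the heuristics are
checked on tiny instances.  Nothing here shares code with the solvers: the
dynamics are re-simulated with :mod:`burnplan.core` primitives and
feasibility is decided by :func:`burnplan.core.validate_schedule`.

Both enumerations refuse instances beyond a hard guard (20 binary decisions
/ 20 items) so they always finish in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import (
    EVCDefinition,
    FuelCurve,
    Landscape,
    LandscapeState,
    PlanningParams,
    TreatmentSchedule,
)

__all__ = ["OracleResult", "enumerate_multiperiod", "enumerate_knapsack"]

OBJECTIVE_TOL = 1e-6  # absolute tonnes, for objective ties


@dataclass
class OracleResult:
    best_objective: float | None
    best_schedules: list[TreatmentSchedule]
    feasible_count: int
    total_count: int


def enumerate_multiperiod(
    landscape: Landscape,
    params: PlanningParams,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
    initial: LandscapeState | None = None,
    guard: int = 20,
) -> OracleResult:
    """Enumerate all 2^(|I| T) schedules; return the feasible optimum.

    The dynamics, feasibility rules and objective accounting are identical
    to :func:`burnplan.core.validate_schedule` /
    :func:`burnplan.core.total_weighted_fuel` (vectorised over schedules for
    speed).  Ties within 1e-6 t are all reported as minimisers.
    """
    n = len(landscape.units)
    T = params.horizon
    nbits = n * T
    if nbits > guard:
        raise ValueError(
            f"enumeration refused: |I|*T = {nbits} exceeds the guard {guard}"
        )
    state0 = initial or LandscapeState.initial(landscape)

    units = list(landscape.units)
    patches = [(u, p) for u in units for p in u.patches]
    P = len(patches)
    unit_of_patch = np.array(
        [units.index(u) for u, _ in patches], dtype=np.int64
    )
    areas_u = np.array([u.area for u in units])
    areas_p = np.array([p.area for _, p in patches])
    w = weights or {}
    w_u = np.array([w.get(u.unit_id, u.weight) for u in units])
    min_tfi = np.array([evc_defs[p.evc_code].min_tfi for _, p in patches])
    max_tfi = np.array([evc_defs[p.evc_code].max_tfi for _, p in patches])
    a0 = np.array(
        [state0.ages[(u.unit_id, p.evc_code)] for u, p in patches],
        dtype=np.int64,
    )

    # fuel-load lookup per patch, plateau-extended to the largest possible age
    kmax = int(a0.max()) + T + 1
    load = np.zeros((P, kmax + 1))
    for j, (u, p) in enumerate(patches):
        curve = curves[evc_defs[p.evc_code].fuel_type]
        for k in range(1, kmax + 1):
            load[j, k] = curve.load(k)

    S = 1 << nbits
    codes = np.arange(S, dtype=np.int64)
    # bit t*n + i <=> unit i treated in period t
    x = np.zeros((S, T, n), dtype=bool)
    for t in range(T):
        for i in range(n):
            x[:, t, i] = (codes >> (t * n + i)) & 1 == 1

    budget = params.treatment_level * landscape.R
    feasible = np.ones(S, dtype=bool)
    ages = np.broadcast_to(a0, (S, P)).copy()
    objective = np.zeros(S)

    for t in range(T):
        treated_u = x[:, t, :]                      # (S, n)
        # budget
        feasible &= treated_u @ areas_u <= budget + 1e-9
        if params.enforce_tfi:
            under = ages < min_tfi                   # (S, P)
            overmax = ages >= max_tfi
            under_u = np.zeros((S, n), dtype=bool)
            over_u = np.zeros((S, n), dtype=bool)
            for i in range(n):
                sel = unit_of_patch == i
                under_u[:, i] = under[:, sel].any(axis=1)
                over_u[:, i] = overmax[:, sel].any(axis=1)
            feasible &= ~(treated_u & under_u & ~over_u).any(axis=1)
        treated_p = treated_u[:, unit_of_patch]      # (S, P)
        ages = np.where(treated_p, 1, ages + 1)
        if params.enforce_tfi:
            feasible &= ~(ages > max_tfi).any(axis=1)
        loads_t = load[np.arange(P)[None, :], ages]       # (S, P)
        objective += (loads_t * areas_p * w_u[unit_of_patch]).sum(axis=1)

    feasible_count = int(feasible.sum())
    if feasible_count == 0:
        return OracleResult(None, [], 0, S)
    objs = np.where(feasible, objective, np.inf)
    best = float(objs.min())
    best_codes = np.flatnonzero(objs <= best + OBJECTIVE_TOL)
    schedules = []
    for code in best_codes:
        treated_by_period = [
            {units[i].unit_id for i in range(n) if x[code, t, i]}
            for t in range(T)
        ]
        schedules.append(
            TreatmentSchedule.from_treated_sets(landscape, treated_by_period)
        )
    return OracleResult(best, schedules, feasible_count, S)


def enumerate_knapsack(
    items: Sequence[tuple[str, float, float]],
    capacity: float,
    guard: int = 20,
) -> tuple[float, list[tuple[str, ...]]]:
    """Exhaustive 0/1 knapsack over all subsets; ties all reported."""
    if len(items) > guard:
        raise ValueError(
            f"enumeration refused: {len(items)} items exceeds the guard {guard}"
        )
    best = 0.0
    best_subsets: list[tuple[str, ...]] = [()]
    for k in range(1, len(items) + 1):
        for combo in combinations(items, k):
            area = sum(a for _, a, _ in combo)
            if area > capacity + 1e-9:
                continue
            value = sum(v for _, _, v in combo)
            ids = tuple(sorted(uid for uid, _, _ in combo))
            if value > best + OBJECTIVE_TOL:
                best, best_subsets = value, [ids]
            elif abs(value - best) <= OBJECTIVE_TOL:
                best_subsets.append(ids)
    return best, best_subsets
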