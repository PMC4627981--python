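"""Single-period decomposition heuristics and the phase-1 repair procedure.

The multi-period schedule is decomposed into a sequence of one-year
subproblems.  Each year the landscape is partitioned by TFI status into
``I_old`` (some vegetation at/over its maximum TFI -- overdue), ``I_middle``
(everything at/over its minimum TFI, nothing overdue) and ``I_young`` (some
vegetation still under its minimum TFI).  With ``r`` the total overdue area
and ``rho * R`` the annual budget, two cases arise:

* Case 1 (``r >= rho R``): only overdue units compete for the whole budget;
* Case 2 (``r < rho R``): every overdue unit is treated outright and the
  remaining budget ``rho R - r`` is allocated over ``I_middle``.

Young units are never treated.  The year's allocation subproblem is a 0/1
knapsack -- select units maximising the fuel load removed subject to the
area budget -- solved either exactly (small MILP) or by a greedy scan in
decreasing fuel-per-hectare order.  Rolling the one-year step forward while
aging the landscape yields a full schedule whose objective is accounted
identically to the exact multi-period model, so the two are comparable.

The same machinery provides the *phase-1 reconciliation*: raw landscapes can
hold far more overdue area than one year's budget (making the multi-period
model infeasible), so the exact single-period step is applied year after
year at an elevated treatment level until the overdue fraction falls below a
threshold; the repaired state then seeds the multi-period model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import (
    EVCDefinition,
    FuelCurve,
    Landscape,
    LandscapeState,
    PlanningParams,
    TreatmentSchedule,
    advance_state,
    classify_units,
    objective_from_schedule,
    unit_fuel_load,
)
from .model import SolveResult, _quiet_native_stdout

__all__ = [
    "PeriodDecision",
    "Phase1Result",
    "knapsack_exact",
    "greedy_select",
    "single_period_step",
    "rolling_horizon",
    "phase1_reconcile",
]


@dataclass
class PeriodDecision:
    """What one single-period step decided and why."""

    period: int
    treated: set[str]
    area_treated: float
    fuel_removed: float
    case_taken: str  # 'case1' | 'case2'
    r: float
    rho_new: float


@dataclass
class Phase1Result:
    """Outcome of the reconciliation loop."""

    state: LandscapeState
    years: int
    decisions: list[PeriodDecision]
    converged: bool
    old_area_fraction: float


Item = tuple[str, float, float]  # (unit_id, area, value)


def knapsack_exact(items: Sequence[Item], capacity: float) -> set[str]:
    """Exact 0/1 knapsack with real-valued areas, solved as a small MILP.

    Maximises total value subject to total area <= capacity.  Zero capacity
    (or no items) selects nothing.
    """
    if capacity <= 0 or not items:
        return set()
    for _, area, value in items:
        if area <= 0:
            raise ValueError("knapsack areas must be > 0")
        if value < 0:
            raise ValueError("knapsack values must be >= 0")
    fits = [it for it in items if it[1] <= capacity]
    if not fits:
        return set()
    c = -np.array([v for _, _, v in fits])
    A = sparse.csc_array(np.array([[a for _, a, _ in fits]]))
    with _quiet_native_stdout():
        res = milp(
            c,
            constraints=LinearConstraint(A, -np.inf, capacity),
            integrality=np.ones(len(fits), dtype=int),
            bounds=Bounds(0, 1),
        )
    if res.status != 0:
        raise RuntimeError(f"knapsack backend failure: {res.message}")
    return {fits[j][0] for j in range(len(fits)) if res.x[j] > 0.5}


def greedy_select(items: Sequence[Item], capacity: float) -> set[str]:
    """Greedy knapsack: scan by decreasing value density, skip what misfits.

    Items are ranked by value per hectare (ties broken by unit id
    ascending); each item that still fits the remaining capacity is taken
    and the scan continues past items that do not fit.
    """
    if capacity <= 0 or not items:
        return set()
    ranked = sorted(items, key=lambda it: (-(it[2] / it[1]), it[0]))
    chosen: set[str] = set()
    remaining = capacity
    eps = 1e-9
    for uid, area, _ in ranked:
        if area <= remaining + eps:
            chosen.add(uid)
            remaining -= area
    return chosen


def single_period_step(
    landscape: Landscape,
    state: LandscapeState,
    rho: float,
    method: str,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
    enforce_tfi: bool = True,
) -> PeriodDecision:
    """Decide one year's burns: forced overdue units plus a knapsack fill.

    ``method`` is ``'kp'`` (exact knapsack) or ``'greedy'``.  Selection
    values are the units' current weighted fuel loads; zero-valued units are
    never selected proactively (treating them cannot reduce the objective).
    With ``enforce_tfi`` off the partition degenerates: every unit is
    treatable and nothing is forced.
    """
    if method not in ("kp", "greedy"):
        raise ValueError(f"method must be 'kp' or 'greedy', got {method!r}")
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    w = weights or {}
    select = knapsack_exact if method == "kp" else greedy_select

    if enforce_tfi:
        part = classify_units(landscape, state, evc_defs)
        old, middle = part["old"], part["middle"]
    else:
        old, middle = [], list(landscape.units)

    budget = rho * landscape.R
    r = sum(u.area for u in old)

    def mk_items(units):
        out = []
        for u in units:
            value = w.get(u.unit_id, u.weight) * unit_fuel_load(
                u, state, curves, evc_defs
            )
            if value > 0:
                out.append((u.unit_id, u.area, value))
        return out

    if r >= budget:
        case = "case1"
        rho_new = rho
        treated = select(mk_items(old), budget)
    else:
        case = "case2"
        rho_new = max(rho - r / landscape.R, 0.0)
        treated = {u.unit_id for u in old}
        treated |= select(mk_items(middle), max(budget - r, 0.0))

    area = sum(landscape.unit(uid).area for uid in treated)
    fuel = sum(
        unit_fuel_load(landscape.unit(uid), state, curves, evc_defs)
        for uid in treated
    )
    return PeriodDecision(
        period=state.period,
        treated=treated,
        area_treated=area,
        fuel_removed=fuel,
        case_taken=case,
        r=r,
        rho_new=rho_new,
    )


def rolling_horizon(
    landscape: Landscape,
    params: PlanningParams,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
    method: str = "kp",
    initial: LandscapeState | None = None,
) -> SolveResult:
    """Apply the single-period step year by year over the whole horizon.

    The returned objective uses the same accounting as the exact model
    (weighted fuel summed over periods 1..T), so the two are directly
    comparable.
    """
    import time as _time

    t0 = _time.perf_counter()
    state = initial or LandscapeState.initial(landscape)
    log: list[PeriodDecision] = []
    treated_by_period = []
    for _ in range(params.horizon):
        dec = single_period_step(
            landscape, state, params.treatment_level, method,
            curves, evc_defs, weights, params.enforce_tfi,
        )
        log.append(dec)
        treated_by_period.append(dec.treated)
        state = advance_state(landscape, state, dec.treated)
    schedule = TreatmentSchedule.from_treated_sets(landscape, treated_by_period)
    objective = objective_from_schedule(
        landscape, schedule, curves, evc_defs, weights, initial
    )
    return SolveResult(
        schedule=schedule,
        objective=objective,
        status="heuristic",
        solve_seconds=_time.perf_counter() - t0,
        method=method,
        period_log=log,
    )


def phase1_reconcile(
    landscape: Landscape,
    state: LandscapeState,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    rho_phase1: float = 0.07,
    old_fraction_threshold: float = 0.05,
    max_years: int = 100,
    method: str = "kp",
) -> Phase1Result:
    """Burn down overdue area until it falls below a fraction of R.

    Runs the single-period step (exact knapsack by default) at the elevated
    phase-1 treatment level, advancing the landscape one year at a time,
    until the area in ``I_old`` is below ``old_fraction_threshold * R`` or
    ``max_years`` is reached.  The returned state satisfies the multi-period
    model's initial-age precondition when converged.
    """
    if not (0 < rho_phase1 <= 1):
        raise ValueError("rho_phase1 must be in (0, 1]")
    if not (0 <= old_fraction_threshold <= 1):
        raise ValueError("old_fraction_threshold must be in [0, 1]")

    def old_fraction(s: LandscapeState) -> float:
        part = classify_units(landscape, s, evc_defs)
        return sum(u.area for u in part["old"]) / landscape.R

    decisions: list[PeriodDecision] = []
    years = 0
    frac = old_fraction(state)
    while frac >= old_fraction_threshold and years < max_years:
        dec = single_period_step(
            landscape, state, rho_phase1, method, curves, evc_defs,
            enforce_tfi=True,
        )
        decisions.append(dec)
        state = advance_state(landscape, state, dec.treated)
        years += 1
        frac = old_fraction(state)
    return Phase1Result(
        state=state,
        years=years,
        decisions=decisions,
        converged=frac < old_fraction_threshold,
        old_area_fraction=frac,
    )
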