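"""Exact multi-period scheduling as a mixed-integer program.

Decision variables are ``x[i,t]`` (treat unit *i* in year *t*, t = 0..T-1)
and age indicators ``y[i,j,k,t]`` (vegetation *j* in unit *i* is at age *k*
in year *t*, t = 0..T).  The constraints encode the deterministic age
dynamics (initial ages, aging by one year when untreated, reset to age 1
after treatment, one age per vegetation per year), the forced treatment of
vegetation that reaches its maximum TFI, the minimum-TFI coupling (a unit
holding under-age vegetation may only be treated when another of its
vegetation types is at/over its maximum TFI), and the annual treat-area
budget ``rho * R``.

Two solution-time devices are available: the age domain of each unit is
restricted to the ages actually reachable under the dynamics (bounded by
the least maximum TFI within the unit), and three families of valid
inequalities tighten the LP relaxation -- an initial treat-by deadline, a
rolling treat-at-least-once-every-p-years cover, and fixing of treat
variables that the TFI limits rule out.  Optionally the ``y`` variables are
relaxed to [0, 1]; integrality of the returned ``y`` is then verified, and
fractional values are reported rather than rounded.

The model is built in a solver-neutral form (variables, linear rows,
objective) and executed through a pluggable mixed-integer backend; the
default backend is HiGHS via :func:`scipy.optimize.milp`.  The reported
objective is always recomputed from the returned schedule with
:mod:`burnplan.core`, never trusted from the backend alone.
"""

from __future__ import annotations

import contextlib
import os
import time
import warnings
from dataclasses import dataclass, field
from typing import Mapping

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
    objective_from_schedule,
)

__all__ = [
    "MipOptions",
    "SolveResult",
    "LinearModel",
    "MultiPeriodModel",
    "InfeasibleInitialAges",
    "build_multiperiod_model",
    "add_valid_inequalities",
    "solve_multiperiod",
]


class InfeasibleInitialAges(ValueError):
    """Initial data violates the maximum TFI; the model would be infeasible.

    Raised before any solve when ``enforce_tfi`` is on and some patch starts
    above its maximum TFI.  The fix is a reconciliation pass
    (:func:`burnplan.heuristics.phase1_reconcile`) that burns the over-mature
    units down below the threshold before the multi-period model runs.
    """

    def __init__(self, offenders: list[tuple[str, str, int, int]]):
        self.offenders = offenders
        units = sorted({u for u, _, _, _ in offenders})
        super().__init__(
            "initial ages exceed the maximum TFI in units "
            f"{units}; run a phase-1 reconciliation before the multi-period model"
        )


@dataclass
class MipOptions:
    """Switches for the exact solver."""

    use_valid_inequalities: bool = True
    relax_y: bool = False
    strict_min_tfi: bool = False  # forbid treating any unit holding under-min vegetation
    time_limit: float = 10_800.0
    gap_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.time_limit <= 0:
            raise ValueError("time_limit must be > 0")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


@dataclass
class SolveResult:
    """Outcome of a scheduling run (exact or heuristic)."""

    schedule: TreatmentSchedule | None
    objective: float | None
    status: str  # 'optimal' | 'feasible_gap' | 'infeasible' | 'time_limit'
    gap: float | None = None
    solve_seconds: float = 0.0
    method: str = "mip"
    fractional_y: list[tuple] = field(default_factory=list)
    diagnostic: str = ""
    period_log: list = field(default_factory=list)


class LinearModel:
    """Solver-neutral MILP container: variables, linear rows, min objective."""

    def __init__(self) -> None:
        self.var_names: list[str] = []
        self.var_lb: list[float] = []
        self.var_ub: list[float] = []
        self.var_integer: list[bool] = []
        self.obj: dict[int, float] = {}
        self.rows: list[tuple[str, dict[int, float], float, float]] = []

    def add_var(
        self, name: str, lb: float = 0.0, ub: float = 1.0, integer: bool = True
    ) -> int:
        self.var_names.append(name)
        self.var_lb.append(lb)
        self.var_ub.append(ub)
        self.var_integer.append(integer)
        return len(self.var_names) - 1

    def add_row(
        self, name: str, coefs: dict[int, float], lb: float, ub: float
    ) -> None:
        self.rows.append((name, coefs, lb, ub))

    def set_objective_coef(self, idx: int, coef: float) -> None:
        self.obj[idx] = self.obj.get(idx, 0.0) + coef

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def row_count(self, prefix: str) -> int:
        return sum(1 for name, *_ in self.rows if name.startswith(prefix))


@dataclass
class MultiPeriodModel:
    """A built multi-period instance: the linear model plus its index maps."""

    lm: LinearModel
    x_idx: dict[tuple[str, int], int]
    y_idx: dict[tuple[str, str, int, int], int]
    landscape: Landscape
    params: PlanningParams
    evc_defs: Mapping[str, EVCDefinition]
    initial_ages: dict[tuple[str, str], int]


def _unit_tfi_stats(unit, evc_defs, ages):
    """(q, p, min_tfi_slack) for the valid inequalities of one unit."""
    q = min(evc_defs[p.evc_code].max_tfi - ages[(unit.unit_id, p.evc_code)]
            for p in unit.patches)
    pp = min(evc_defs[p.evc_code].max_tfi for p in unit.patches)
    bmin = min(evc_defs[p.evc_code].min_tfi - ages[(unit.unit_id, p.evc_code)]
               for p in unit.patches)
    return q, pp, bmin


def build_multiperiod_model(
    landscape: Landscape,
    params: PlanningParams,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
    options: MipOptions | None = None,
    initial: LandscapeState | None = None,
) -> MultiPeriodModel:
    """Assemble the multi-period MIP for a landscape.

    Age indicators are created only for the (age, year) pairs reachable
    under the dynamics: at year *t* a patch can be at its initial age plus
    *t*, or at any age 1..t following a treatment; with TFI enforcement ages
    are additionally capped by the unit's forced treatment cycle.
    """
    options = options or MipOptions()
    T = params.horizon
    w = weights or {}
    state0 = initial or LandscapeState.initial(landscape)
    ages0 = dict(state0.ages)

    if params.enforce_tfi:
        offenders = [
            (u.unit_id, p.evc_code, ages0[(u.unit_id, p.evc_code)],
             evc_defs[p.evc_code].max_tfi)
            for u in landscape.units
            for p in u.patches
            if ages0[(u.unit_id, p.evc_code)] > evc_defs[p.evc_code].max_tfi
        ]
        if offenders:
            raise InfeasibleInitialAges(offenders)

    lm = LinearModel()
    x_idx: dict[tuple[str, int], int] = {}
    y_idx: dict[tuple[str, str, int, int], int] = {}

    for u in landscape.units:
        for t in range(T):
            x_idx[(u.unit_id, t)] = lm.add_var(f"x[{u.unit_id},{t}]")

    # reachable age domain per patch
    def age_cap(u, p) -> int | None:
        if not params.enforce_tfi:
            return None
        q, pp, _ = _unit_tfi_stats(u, evc_defs, ages0)
        a = ages0[(u.unit_id, p.evc_code)]
        return min(evc_defs[p.evc_code].max_tfi, max(pp, a + q))

    domains: dict[tuple[str, str], list[set[int]]] = {}
    for u in landscape.units:
        for p in u.patches:
            a = ages0[(u.unit_id, p.evc_code)]
            cap = age_cap(u, p)
            dom: list[set[int]] = []
            for t in range(T + 1):
                ks = set(range(1, t + 1))
                ks.add(a + t)
                if cap is not None:
                    ks = {k for k in ks if k <= cap}
                dom.append(ks)
            domains[(u.unit_id, p.evc_code)] = dom
            for t in range(T + 1):
                for k in sorted(dom[t]):
                    lb = 1.0 if (t == 0 and k == a) else 0.0
                    y_idx[(u.unit_id, p.evc_code, k, t)] = lm.add_var(
                        f"y[{u.unit_id},{p.evc_code},{k},{t}]",
                        lb=lb,
                        ub=1.0,
                        integer=not options.relax_y,
                    )

    # objective: weighted fuel over periods 1..T
    for u in landscape.units:
        wu = w.get(u.unit_id, u.weight)
        for p in u.patches:
            curve = curves[evc_defs[p.evc_code].fuel_type]
            for t in range(1, T + 1):
                for k in domains[(u.unit_id, p.evc_code)][t]:
                    lm.set_objective_coef(
                        y_idx[(u.unit_id, p.evc_code, k, t)],
                        wu * curve.load(k) * p.area,
                    )

    for u in landscape.units:
        uid = u.unit_id
        nveg = len(u.patches)
        for p in u.patches:
            dom = domains[(uid, p.evc_code)]
            # aging: y[k+1,t+1] >= y[k,t] - x[t]
            for t in range(T):
                for k in dom[t]:
                    if k + 1 in dom[t + 1]:
                        lm.add_row(
                            f"age[{uid},{p.evc_code},{k},{t}]",
                            {
                                y_idx[(uid, p.evc_code, k + 1, t + 1)]: 1.0,
                                y_idx[(uid, p.evc_code, k, t)]: -1.0,
                                x_idx[(uid, t)]: 1.0,
                            },
                            0.0,
                            np.inf,
                        )
            # reset: y[1,t+1] >= x[t]
            for t in range(T):
                lm.add_row(
                    f"reset[{uid},{p.evc_code},{t}]",
                    {
                        y_idx[(uid, p.evc_code, 1, t + 1)]: 1.0,
                        x_idx[(uid, t)]: -1.0,
                    },
                    0.0,
                    np.inf,
                )
            # one age per vegetation per year
            for t in range(1, T + 1):
                lm.add_row(
                    f"one_age[{uid},{p.evc_code},{t}]",
                    {y_idx[(uid, p.evc_code, k, t)]: 1.0 for k in dom[t]},
                    1.0,
                    1.0,
                )
            # forced treatment at the maximum TFI (treatable years only)
            if params.enforce_tfi:
                mx = evc_defs[p.evc_code].max_tfi
                for t in range(T):
                    if mx in dom[t]:
                        lm.add_row(
                            f"force_max[{uid},{p.evc_code},{t}]",
                            {
                                y_idx[(uid, p.evc_code, mx, t)]: 1.0,
                                x_idx[(uid, t)]: -1.0,
                            },
                            -np.inf,
                            0.0,
                        )
        # minimum-TFI coupling
        if params.enforce_tfi:
            for t in range(T):
                coefs: dict[int, float] = {}
                for p in u.patches:
                    dom = domains[(uid, p.evc_code)]
                    mn = evc_defs[p.evc_code].min_tfi
                    mx = evc_defs[p.evc_code].max_tfi
                    for k in dom[t]:
                        if k < mn:
                            coefs[y_idx[(uid, p.evc_code, k, t)]] = (
                                coefs.get(y_idx[(uid, p.evc_code, k, t)], 0.0) + 1.0
                            )
                        if k == mx and not options.strict_min_tfi:
                            coefs[y_idx[(uid, p.evc_code, k, t)]] = (
                                coefs.get(y_idx[(uid, p.evc_code, k, t)], 0.0) - nveg
                            )
                if any(c > 0 for c in coefs.values()):
                    coefs[x_idx[(uid, t)]] = float(nveg)
                    lm.add_row(f"min_tfi[{uid},{t}]", coefs, -np.inf, float(nveg))

    # annual budget
    budget = params.treatment_level * landscape.R
    for t in range(T):
        lm.add_row(
            f"budget[{t}]",
            {x_idx[(u.unit_id, t)]: u.area for u in landscape.units},
            -np.inf,
            budget,
        )

    mp = MultiPeriodModel(
        lm=lm,
        x_idx=x_idx,
        y_idx=y_idx,
        landscape=landscape,
        params=params,
        evc_defs=evc_defs,
        initial_ages=ages0,
    )
    if options.use_valid_inequalities and params.enforce_tfi:
        add_valid_inequalities(mp)
    return mp


def add_valid_inequalities(mp: MultiPeriodModel) -> MultiPeriodModel:
    """Tighten the formulation with TFI-derived cuts.

    Per unit, with ``q = min_j (maxTFI_j - a_j)`` and ``p = min_j maxTFI_j``:

    * treat-by deadline: the unit must be treated by the year its most
      critical vegetation reaches its maximum TFI, i.e. within years 0..q
      (added when the deadline falls inside the treatable horizon);
    * rolling cover: at least one treatment in every window of p
      consecutive years (added only when T >= p);
    * variable fixing: x[i,t] = 0 for all t below the earliest year any
      treatment could be permitted, min(min_j(minTFI_j - a_j), q).
    """
    if not mp.params.enforce_tfi:
        raise ValueError("valid inequalities derive from the TFI limits; "
                         "they require enforce_tfi")
    lm, T = mp.lm, mp.params.horizon
    for u in mp.landscape.units:
        uid = u.unit_id
        q, p, bmin = _unit_tfi_stats(u, mp.evc_defs, mp.initial_ages)
        if q <= T - 1:
            lm.add_row(
                f"vi_deadline[{uid}]",
                {mp.x_idx[(uid, t)]: 1.0 for t in range(0, max(q, 0) + 1)},
                1.0,
                np.inf,
            )
        if T >= p:
            for t in range(0, T - p + 1):
                lm.add_row(
                    f"vi_cover[{uid},{t}]",
                    {mp.x_idx[(uid, tau)]: 1.0 for tau in range(t, t + p)},
                    1.0,
                    np.inf,
                )
        fix_before = min(bmin, q)
        if fix_before > 0:
            for t in range(min(fix_before, T)):
                lm.var_ub[mp.x_idx[(uid, t)]] = 0.0
    return mp


# ---------------------------------------------------------------------------
# backend
# ---------------------------------------------------------------------------


@contextlib.contextmanager
def _quiet_native_stdout():
    """Mute the solver library's direct C-level stdout/stderr chatter."""
    try:
        saved = [os.dup(1), os.dup(2)]
    except OSError:  # no usable standard streams (unusual embedding)
        yield
        return
    try:
        with open(os.devnull, "wb") as devnull:
            os.dup2(devnull.fileno(), 1)
            os.dup2(devnull.fileno(), 2)
            try:
                yield
            finally:
                try:  # flush libc buffers before the real streams return
                    import ctypes

                    ctypes.CDLL(None).fflush(None)
                except Exception:
                    pass
                os.dup2(saved[0], 1)
                os.dup2(saved[1], 2)
    finally:
        for fd in saved:
            os.close(fd)


def _solve_linear_model(
    lm: LinearModel, time_limit: float, gap_tolerance: float
) -> tuple[np.ndarray | None, str, float | None]:
    """Run a LinearModel through HiGHS; returns (solution, status, gap)."""
    n = lm.n_vars
    c = np.zeros(n)
    for idx, coef in lm.obj.items():
        c[idx] = coef
    rows_i, cols_j, vals = [], [], []
    lbs, ubs = [], []
    for r, (_, coefs, lb, ub) in enumerate(lm.rows):
        for j, v in coefs.items():
            rows_i.append(r)
            cols_j.append(j)
            vals.append(v)
        lbs.append(lb)
        ubs.append(ub)
    if lm.rows:
        A = sparse.csc_array(
            (vals, (rows_i, cols_j)), shape=(len(lm.rows), n)
        )
        constraints = LinearConstraint(A, np.array(lbs), np.array(ubs))
    else:
        constraints = ()
    with _quiet_native_stdout():
        res = milp(
            c,
            constraints=constraints,
            integrality=np.array(lm.var_integer, dtype=int),
            bounds=Bounds(np.array(lm.var_lb), np.array(lm.var_ub)),
            options={"time_limit": time_limit, "mip_rel_gap": gap_tolerance},
        )
    gap = getattr(res, "mip_gap", None)
    if res.status == 0:
        return res.x, "optimal", gap
    if res.status == 1:  # hit a limit
        if res.x is not None:
            return res.x, "feasible_gap", gap
        return None, "time_limit", None
    if res.status == 2:
        return None, "infeasible", None
    raise RuntimeError(f"MILP backend failure: {res.message}")


def _infeasibility_diagnostic(mp: MultiPeriodModel) -> str:
    """Point at the constraints most likely in conflict."""
    T = mp.params.horizon
    budget = mp.params.treatment_level * mp.landscape.R
    forced = []
    for u in mp.landscape.units:
        q, _, _ = _unit_tfi_stats(u, mp.evc_defs, mp.initial_ages)
        if q <= T - 1:
            forced.append((u.unit_id, q, u.area))
    msg = [f"annual budget rho*R = {budget:.3f} ha"]
    if forced:
        area = sum(a for _, _, a in forced)
        msg.append(
            f"{len(forced)} unit(s) must be treated within the horizon "
            f"(total {area:.3f} ha): "
            + ", ".join(f"{u} by t={q} ({a:.2f} ha)" for u, q, a in forced[:10])
        )
        over = [u for u, _, a in forced if a > budget]
        if over:
            msg.append(f"units larger than one year's budget: {over}")
    return "; ".join(msg)


def solve_multiperiod(
    landscape: Landscape,
    params: PlanningParams,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
    options: MipOptions | None = None,
    initial: LandscapeState | None = None,
) -> SolveResult:
    """Build and solve the multi-period model; objective is recomputed.

    Returns the proven optimum when the backend converges within its limits,
    otherwise the best incumbent with its optimality gap.  The reported
    objective always comes from re-simulating the returned schedule.
    """
    options = options or MipOptions()
    mp = build_multiperiod_model(
        landscape, params, curves, evc_defs, weights, options, initial
    )
    t0 = time.perf_counter()
    sol, status, gap = _solve_linear_model(
        mp.lm, options.time_limit, options.gap_tolerance
    )
    elapsed = time.perf_counter() - t0
    if sol is None:
        diag = _infeasibility_diagnostic(mp) if status == "infeasible" else ""
        return SolveResult(
            schedule=None, objective=None, status=status, gap=gap,
            solve_seconds=elapsed, method="mip", diagnostic=diag,
        )
    T = params.horizon
    treated_by_period = [
        {uid for uid in landscape.unit_ids if sol[mp.x_idx[(uid, t)]] > 0.5}
        for t in range(T)
    ]
    schedule = TreatmentSchedule.from_treated_sets(landscape, treated_by_period)
    fractional = []
    if options.relax_y:
        for key, idx in mp.y_idx.items():
            v = sol[idx]
            if abs(v - round(v)) > 1e-6:
                fractional.append((key, float(v)))
        if fractional:
            warnings.warn(
                f"{len(fractional)} age indicator(s) came back fractional "
                "under the continuous-y relaxation; reporting, not rounding",
                stacklevel=2,
            )
    objective = objective_from_schedule(
        landscape, schedule, curves, evc_defs, weights, initial
    )
    return SolveResult(
        schedule=schedule,
        objective=objective,
        status=status,
        gap=gap,
        solve_seconds=elapsed,
        method="mip",
        fractional_y=fractional,
    )
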