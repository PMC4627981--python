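"""CSV readers/writers and the end-to-end run driver.

File schemas (UTF-8, header row required):

* ``units.csv``   -- unit_id, evc_code, area_ha, age (one row per patch);
* ``evc.csv``     -- evc_code, evc_name, min_tfi, max_tfi, fuel_type;
* ``curves.csv``  -- fuel_type, age, load_t_per_ha (ages consecutive from 1);
* ``weights.csv`` -- unit_id, weight (optional);
* ``schedule.csv``-- unit_id, period, treated (0/1), written by the solvers;
* ``summary.csv`` -- period, area_treated_ha, fraction_of_R, total_fuel_t.

Schema violations are reported with the file, row and column; dangling
references (a unit's EVC missing from the catalogue, a fuel type without a
curve) name the offending code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    ConfigurationError,
    EVCDefinition,
    FuelCurve,
    Landscape,
    LandscapeState,
    PlanningParams,
    TreatmentSchedule,
    TreatmentUnit,
    VegPatch,
    make_weights,
    objective_from_schedule,
    simulate,
    total_weighted_fuel,
    unit_fuel_load,
    validate_schedule,
)
from .heuristics import phase1_reconcile, rolling_horizon
from .model import MipOptions, SolveResult, solve_multiperiod
from .synth import default_fuel_curves

__all__ = [
    "read_landscape",
    "read_curves",
    "write_curves",
    "write_units",
    "write_evc",
    "write_schedule",
    "read_schedule",
    "summary_frame",
    "RunConfig",
    "run",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")


def read_curves(path) -> dict[str, FuelCurve]:
    """Read long-form fuel curves (fuel_type, age, load_t_per_ha)."""
    df = pd.read_csv(path)
    _require_columns(df, ["fuel_type", "age", "load_t_per_ha"], path)
    curves = {}
    for ft, grp in df.groupby("fuel_type", sort=True):
        loads = {}
        for row in grp.itertuples():
            age = int(row.age)
            if age in loads:
                raise ConfigurationError(
                    f"{path}: duplicate age {age} for fuel type {ft}"
                )
            loads[age] = float(row.load_t_per_ha)
        try:
            curves[str(ft)] = FuelCurve(fuel_type=str(ft), loads=loads)
        except ConfigurationError as exc:
            raise ConfigurationError(f"{path}: {exc}") from None
    return curves


def read_landscape(
    units_path,
    evc_path,
    curves_path=None,
    weights_path=None,
) -> tuple[Landscape, dict[str, EVCDefinition], dict[str, FuelCurve],
           dict[str, float] | None]:
    """Read and cross-validate a landscape and its supporting tables.

    When ``curves_path`` is omitted, the package's default parametric curve
    set is used (it covers every catalogue fuel type).
    """
    evc_df = pd.read_csv(evc_path, dtype={"evc_code": str, "fuel_type": str})
    _require_columns(
        evc_df, ["evc_code", "evc_name", "min_tfi", "max_tfi", "fuel_type"],
        evc_path,
    )
    evc_defs: dict[str, EVCDefinition] = {}
    for idx, row in evc_df.iterrows():
        code = str(row["evc_code"])
        if code in evc_defs:
            raise ConfigurationError(f"{evc_path}: row {idx}: duplicate EVC {code}")
        try:
            evc_defs[code] = EVCDefinition(
                evc_code=code,
                name=str(row["evc_name"]),
                min_tfi=int(row["min_tfi"]),
                max_tfi=int(row["max_tfi"]),
                fuel_type=str(row["fuel_type"]),
            )
        except (ConfigurationError, ValueError) as exc:
            raise ConfigurationError(f"{evc_path}: row {idx}: {exc}") from None

    units_df = pd.read_csv(units_path, dtype={"unit_id": str, "evc_code": str})
    _require_columns(units_df, ["unit_id", "evc_code", "area_ha", "age"], units_path)
    by_unit: dict[str, list[VegPatch]] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in units_df.iterrows():
        uid, code = str(row["unit_id"]), str(row["evc_code"])
        if code not in evc_defs:
            raise ConfigurationError(
                f"{units_path}: row {idx}: EVC {code} not in catalogue"
            )
        if (uid, code) in seen:
            raise ConfigurationError(
                f"{units_path}: row {idx}: duplicate (unit, EVC) = ({uid}, {code})"
            )
        seen.add((uid, code))
        try:
            patch = VegPatch(
                evc_code=code, area=float(row["area_ha"]), age=int(row["age"])
            )
        except (ConfigurationError, ValueError) as exc:
            raise ConfigurationError(f"{units_path}: row {idx}: {exc}") from None
        by_unit.setdefault(uid, []).append(patch)
    landscape = Landscape(
        units=tuple(
            TreatmentUnit(unit_id=uid, patches=tuple(ps))
            for uid, ps in by_unit.items()
        )
    )

    if curves_path is not None:
        curves = read_curves(curves_path)
    else:
        curves = default_fuel_curves()
    for code, evc in evc_defs.items():
        if evc.fuel_type not in curves:
            raise ConfigurationError(
                f"fuel type {evc.fuel_type!r} (EVC {code}) has no curve"
            )

    weights = None
    if weights_path is not None:
        wdf = pd.read_csv(weights_path, dtype={"unit_id": str})
        _require_columns(wdf, ["unit_id", "weight"], weights_path)
        weights = {}
        for idx, row in wdf.iterrows():
            uid = str(row["unit_id"])
            if uid not in set(landscape.unit_ids):
                raise ConfigurationError(
                    f"{weights_path}: row {idx}: unknown unit {uid}"
                )
            weights[uid] = float(row["weight"])
    return landscape, evc_defs, curves, weights


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_units(landscape: Landscape, path) -> None:
    rows = [
        {"unit_id": u.unit_id, "evc_code": p.evc_code,
         "area_ha": p.area, "age": p.age}
        for u in landscape.units
        for p in u.patches
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_evc(evc_defs: Mapping[str, EVCDefinition], path) -> None:
    rows = [
        {"evc_code": e.evc_code, "evc_name": e.name, "min_tfi": e.min_tfi,
         "max_tfi": e.max_tfi, "fuel_type": e.fuel_type}
        for e in evc_defs.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curves(curves: Mapping[str, FuelCurve], path) -> None:
    rows = [
        {"fuel_type": c.fuel_type, "age": k, "load_t_per_ha": c.loads[k]}
        for c in curves.values()
        for k in sorted(c.loads)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_schedule(schedule: TreatmentSchedule, path) -> None:
    rows = [
        {"unit_id": uid, "period": t, "treated": x}
        for (uid, t), x in sorted(schedule.decisions.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_schedule(path) -> TreatmentSchedule:
    df = pd.read_csv(path, dtype={"unit_id": str})
    _require_columns(df, ["unit_id", "period", "treated"], path)
    decisions = {
        (str(r.unit_id), int(r.period)): int(r.treated) for r in df.itertuples()
    }
    horizon = max(t for _, t in decisions) + 1 if decisions else 0
    return TreatmentSchedule(decisions=decisions, horizon=horizon)


def summary_frame(
    landscape: Landscape,
    schedule: TreatmentSchedule,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    initial=None,
) -> pd.DataFrame:
    """Per-period treated area and landscape fuel (period 0 = initial)."""
    states = simulate(landscape, schedule, initial)
    rows = []
    for t, state in enumerate(states):
        treated = schedule.treated(t) if t < schedule.horizon else set()
        area = sum(landscape.unit(uid).area for uid in treated)
        fuel = sum(
            unit_fuel_load(u, state, curves, evc_defs) for u in landscape.units
        )
        rows.append(
            {
                "period": t,
                "area_treated_ha": area,
                "fraction_of_R": area / landscape.R,
                "total_fuel_t": fuel,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One complete run: inputs, method, parameters, outputs."""

    units_path: str
    evc_path: str
    out_dir: str
    curves_path: str | None = None
    weights_path: str | None = None
    method: str = "kp"  # 'mip' | 'kp' | 'greedy'
    horizon: int = 10
    level: float = 0.05
    enforce_tfi: bool = True
    weights_mode: str = "total"  # 'total' | 'subset' | 'random'
    subset_path: str | None = None
    phase1: bool = False
    phase1_level: float = 0.07
    phase1_threshold: float = 0.05
    phase1_max_years: int = 100
    seed: int = 0
    time_limit: float = 10_800.0
    gap: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("mip", "kp", "greedy"):
            raise ConfigurationError(f"unknown method {self.method!r}")


def run(config: RunConfig) -> SolveResult:
    """Execute a configured run and write schedule, summary and log files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape, evc_defs, curves, file_weights = read_landscape(
        config.units_path, config.evc_path, config.curves_path,
        config.weights_path,
    )
    if file_weights is not None and config.weights_mode == "total":
        weights = file_weights
    elif config.weights_mode == "subset":
        if config.subset_path is None:
            raise ConfigurationError("weights_mode 'subset' needs subset_path")
        subset = [
            line.strip()
            for line in Path(config.subset_path).read_text().splitlines()
            if line.strip()
        ]
        weights = make_weights(landscape, "subset", subset=subset)
    else:
        weights = make_weights(landscape, config.weights_mode, seed=config.seed)

    params = PlanningParams(
        horizon=config.horizon,
        treatment_level=config.level,
        enforce_tfi=config.enforce_tfi,
        time_limit=config.time_limit,
        gap_tolerance=config.gap,
        seed=config.seed,
    )

    log: dict = {"config": dataclasses.asdict(config)}
    initial = None
    if config.phase1:
        p1 = phase1_reconcile(
            landscape,
            LandscapeState.initial(landscape),
            curves,
            evc_defs,
            rho_phase1=config.phase1_level,
            old_fraction_threshold=config.phase1_threshold,
            max_years=config.phase1_max_years,
        )
        log["phase1"] = {
            "years": p1.years,
            "converged": p1.converged,
            "old_area_fraction": p1.old_area_fraction,
        }
        if not p1.converged:
            log["error"] = "phase 1 did not reconcile within max_years"
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
            raise RuntimeError(log["error"])
        initial = p1.state

    if config.method == "mip":
        result = solve_multiperiod(
            landscape, params, curves, evc_defs, weights,
            MipOptions(time_limit=config.time_limit,
                       gap_tolerance=config.gap),
            initial,
        )
    else:
        result = rolling_horizon(
            landscape, params, curves, evc_defs, weights,
            method=config.method, initial=initial,
        )

    log["status"] = result.status
    log["method"] = config.method
    log["seed"] = config.seed
    if result.schedule is None:
        log["diagnostic"] = result.diagnostic
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        return result

    write_schedule(result.schedule, out / "schedule.csv")
    summary = summary_frame(landscape, result.schedule, curves, evc_defs, initial)
    summary.to_csv(out / "summary.csv", index=False)
    violations = validate_schedule(
        landscape, result.schedule, params, curves, evc_defs, initial
    )
    log.update(
        {
            "objective_t": result.objective,
            "gap": result.gap,
            "solve_seconds": result.solve_seconds,
            "n_violations": len(violations),
            "period_log": [
                {
                    "period": d.period,
                    "case": d.case_taken,
                    "r_ha": d.r,
                    "rho_new": d.rho_new,
                    "area_treated_ha": d.area_treated,
                    "fuel_removed_t": d.fuel_removed,
                }
                for d in result.period_log
            ],
        }
    )
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return result
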