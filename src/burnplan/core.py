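"""Domain model for prescribed-burn planning on a multi-vegetation landscape.

A landscape is a collection of *treatment units* (the atomic decision
entities of a burn plan).  Each unit holds one or more vegetation patches,
each belonging to an Ecological Vegetation Class (EVC) with a known area and
a single representative age (years since last fire).  Every EVC carries two
ecological limits -- the minimum and maximum Tolerable Fire Interval (TFI) --
and maps to a fuel type whose fuel-accumulation curve gives the fuel load
(tonnes/ha) as a function of age.

Age dynamics are deterministic: an untreated patch ages by one year per
period; treating a unit resets every patch in it to age 1 the following
year.  All scheduling methods in this package (exact multi-period MIP,
knapsack and greedy single-period heuristics) share these dynamics, the same
treat-area budget ``rho * R`` per year, and the same objective: the weighted
total fuel load summed over periods 1..T of the plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FuelCurve",
    "EVCDefinition",
    "VegPatch",
    "TreatmentUnit",
    "Landscape",
    "LandscapeState",
    "TreatmentSchedule",
    "PlanningParams",
    "Violation",
    "unit_area",
    "unit_fuel_load",
    "total_weighted_fuel",
    "advance_state",
    "simulate",
    "classify_units",
    "validate_schedule",
    "make_weights",
    "objective_from_schedule",
]


class ConfigurationError(ValueError):
    """A landscape, curve set or catalogue is internally inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuelCurve:
    """Fuel load (tonnes/ha) as a function of vegetation age.

    ``loads[k]`` is the load at integer age ``k`` (years, 1-based).  Ages
    beyond the last tabulated age return the final value: accumulation
    curves saturate, and raw landscapes may carry over-mature stands whose
    age exceeds any tabulated domain.
    """

    fuel_type: str
    loads: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.loads:
            raise ConfigurationError(f"fuel curve {self.fuel_type!r} is empty")
        ages = sorted(self.loads)
        if ages[0] != 1 or ages != list(range(1, len(ages) + 1)):
            raise ConfigurationError(
                f"fuel curve {self.fuel_type!r}: ages must be consecutive from 1"
            )
        if any(v < 0 for v in self.loads.values()):
            raise ConfigurationError(f"fuel curve {self.fuel_type!r}: negative load")
        object.__setattr__(self, "_kmax", ages[-1])

    @property
    def max_age(self) -> int:
        return self._kmax  # type: ignore[attr-defined]

    def load(self, age: int) -> float:
        """Load at ``age``, with plateau extension beyond the tabulated domain."""
        if age < 1:
            raise ValueError(f"age must be >= 1, got {age}")
        return self.loads[min(age, self.max_age)]


@dataclass(frozen=True)
class EVCDefinition:
    """Ecological limits and fuel type of one Ecological Vegetation Class."""

    evc_code: str
    name: str
    min_tfi: int
    max_tfi: int
    fuel_type: str

    def __post_init__(self) -> None:
        if not (1 <= self.min_tfi <= self.max_tfi):
            raise ConfigurationError(
                f"EVC {self.evc_code}: need 1 <= min_tfi <= max_tfi, "
                f"got ({self.min_tfi}, {self.max_tfi})"
            )


@dataclass(frozen=True)
class VegPatch:
    """One vegetation type within a treatment unit: EVC, extent, initial age."""

    evc_code: str
    area: float
    age: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ConfigurationError(f"patch {self.evc_code}: area must be > 0")
        if self.age < 1:
            raise ConfigurationError(f"patch {self.evc_code}: age must be >= 1")


@dataclass(frozen=True)
class TreatmentUnit:
    """A parcel treatable as a whole.  ``weight`` is its relative importance."""

    unit_id: str
    patches: tuple[VegPatch, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.patches:
            raise ConfigurationError(f"unit {self.unit_id}: no patches")
        object.__setattr__(self, "patches", tuple(self.patches))
        codes = [p.evc_code for p in self.patches]
        if len(set(codes)) != len(codes):
            raise ConfigurationError(
                f"unit {self.unit_id}: duplicate EVC in {codes}"
            )
        if self.weight < 0:
            raise ConfigurationError(f"unit {self.unit_id}: negative weight")

    @property
    def area(self) -> float:
        """Unit area c_i, always the sum of its patch areas."""
        return sum(p.area for p in self.patches)


@dataclass(frozen=True)
class Landscape:
    """All treatment units plus the total treatable area R.

    ``total_treatable_area`` defaults to the sum of unit areas but may be
    overridden: the budget is defined against the whole treatable landscape,
    which can exceed the modelled subset.
    """

    units: tuple[TreatmentUnit, ...]
    total_treatable_area: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate unit ids: {dupes}")

    @property
    def R(self) -> float:
        if self.total_treatable_area is not None:
            return self.total_treatable_area
        return sum(u.area for u in self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> TreatmentUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass(frozen=True)
class LandscapeState:
    """Ages of every (unit, EVC) patch at one period.

    By construction all vegetation of a given type in a unit has a single
    age, so the state is a plain mapping ``(unit_id, evc_code) -> age``.
    """

    ages: Mapping[tuple[str, str], int]
    period: int = 0

    @classmethod
    def initial(cls, landscape: Landscape) -> "LandscapeState":
        return cls(
            ages={
                (u.unit_id, p.evc_code): p.age
                for u in landscape.units
                for p in u.patches
            },
            period=0,
        )

    def age(self, unit_id: str, evc_code: str) -> int:
        return self.ages[(unit_id, evc_code)]


@dataclass(frozen=True)
class TreatmentSchedule:
    """Binary treat/no-treat decision per unit per period t = 0..T-1."""

    decisions: Mapping[tuple[str, int], int]
    horizon: int

    def treated(self, period: int) -> set[str]:
        return {
            uid for (uid, t), x in self.decisions.items() if t == period and x
        }

    @classmethod
    def from_treated_sets(
        cls, landscape: Landscape, treated_by_period: Sequence[Iterable[str]]
    ) -> "TreatmentSchedule":
        horizon = len(treated_by_period)
        dec = {}
        for t, treated in enumerate(treated_by_period):
            treated = set(treated)
            for uid in landscape.unit_ids:
                dec[(uid, t)] = 1 if uid in treated else 0
        return cls(decisions=dec, horizon=horizon)


@dataclass
class PlanningParams:
    """Run parameters shared by all solution methods.

    treatment_level is a fraction (0.05 means 5 % of R may be treated per
    year).  ``time_limit``/``gap_tolerance`` bound the MIP backend.
    """

    horizon: int
    treatment_level: float
    enforce_tfi: bool = True
    time_limit: float = 10_800.0
    gap_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if not (0 < self.treatment_level <= 1):
            raise ConfigurationError("treatment_level must be in (0, 1]")


@dataclass(frozen=True)
class Violation:
    """One feasibility failure of a realised schedule."""

    constraint: str  # 'budget' | 'max_tfi' | 'min_tfi'
    unit_id: str | None
    period: int
    detail: str = ""


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def unit_area(unit: TreatmentUnit) -> float:
    """Area c_i of a treatment unit: the sum of its patch areas."""
    return unit.area


def _curve_for(
    evc_code: str,
    evc_defs: Mapping[str, EVCDefinition],
    curves: Mapping[str, FuelCurve],
) -> FuelCurve:
    try:
        evc = evc_defs[evc_code]
    except KeyError:
        raise ConfigurationError(f"EVC {evc_code!r} missing from catalogue") from None
    try:
        return curves[evc.fuel_type]
    except KeyError:
        raise ConfigurationError(
            f"fuel type {evc.fuel_type!r} (EVC {evc_code}) has no curve"
        ) from None


def unit_fuel_load(
    unit: TreatmentUnit,
    state: LandscapeState,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
) -> float:
    """Total fuel load L_i of a unit (tonnes) at the ages in ``state``."""
    total = 0.0
    for p in unit.patches:
        curve = _curve_for(p.evc_code, evc_defs, curves)
        total += curve.load(state.age(unit.unit_id, p.evc_code)) * p.area
    return total


def total_weighted_fuel(
    landscape: Landscape,
    trajectory: Sequence[LandscapeState],
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Objective value: sum over t=1..T of w_i * (unit fuel at period t).

    ``trajectory`` must cover the T consecutive periods after the planning
    start; the starting state itself is deliberately excluded from the
    objective.
    """
    periods = [s.period for s in trajectory]
    if trajectory and periods != list(
        range(periods[0], periods[0] + len(trajectory))
    ):
        raise ValueError(f"trajectory periods must be consecutive, got {periods}")
    w = weights or {}
    total = 0.0
    for state in trajectory:
        for u in landscape.units:
            wu = w.get(u.unit_id, u.weight)
            if wu:
                total += wu * unit_fuel_load(u, state, curves, evc_defs)
    return total


def advance_state(
    landscape: Landscape, state: LandscapeState, treated: Iterable[str]
) -> LandscapeState:
    """One year of dynamics: treated units reset to age 1, the rest age by 1."""
    treated = set(treated)
    unknown = treated - set(landscape.unit_ids)
    if unknown:
        raise ValueError(f"treated units not in landscape: {sorted(unknown)}")
    ages = {}
    for u in landscape.units:
        reset = u.unit_id in treated
        for p in u.patches:
            key = (u.unit_id, p.evc_code)
            ages[key] = 1 if reset else state.ages[key] + 1
    return LandscapeState(ages=ages, period=state.period + 1)


def simulate(
    landscape: Landscape,
    schedule: TreatmentSchedule,
    initial: LandscapeState | None = None,
) -> list[LandscapeState]:
    """Run the age dynamics under a schedule; returns states for t=0..T."""
    state = initial or LandscapeState.initial(landscape)
    out = [state]
    for t in range(schedule.horizon):
        state = advance_state(landscape, state, schedule.treated(t))
        out.append(state)
    return out


def classify_units(
    landscape: Landscape,
    state: LandscapeState,
    evc_defs: Mapping[str, EVCDefinition],
) -> dict[str, list[TreatmentUnit]]:
    """Partition units by TFI status into I_old / I_middle / I_young.

    * old    -- some patch at or over its EVC's maximum TFI (overdue; the
                old condition takes precedence over everything else);
    * middle -- every patch at or over its minimum TFI, none at/over max
                (treatable at will);
    * young  -- no patch at/over max and some patch under its minimum TFI
                (treatment would breach species maturity).
    """
    out: dict[str, list[TreatmentUnit]] = {"old": [], "middle": [], "young": []}
    for u in landscape.units:
        over_max = False
        under_min = False
        for p in u.patches:
            evc = evc_defs[p.evc_code]
            age = state.age(u.unit_id, p.evc_code)
            if age >= evc.max_tfi:
                over_max = True
            if age < evc.min_tfi:
                under_min = True
        if over_max:
            out["old"].append(u)
        elif under_min:
            out["young"].append(u)
        else:
            out["middle"].append(u)
    return out


def validate_schedule(
    landscape: Landscape,
    schedule: TreatmentSchedule,
    params: PlanningParams,
    curves: Mapping[str, FuelCurve] | None,
    evc_defs: Mapping[str, EVCDefinition],
    initial: LandscapeState | None = None,
    tol: float = 1e-9,
) -> list[Violation]:
    """Check a realised schedule against budget and TFI rules.

    Reported violations:

    * ``budget``  -- treated area in some period exceeds rho * R;
    * ``max_tfi`` -- a patch exceeds its maximum TFI at any period 1..T
                     (only when ``params.enforce_tfi``);
    * ``min_tfi`` -- a unit is treated while some patch is under its minimum
                     TFI and no patch in the unit is at/over its maximum TFI
                     (only when ``params.enforce_tfi``).

    An empty list means the schedule is feasible.
    """
    if schedule.horizon != params.horizon:
        raise ValueError(
            f"schedule horizon {schedule.horizon} != params horizon {params.horizon}"
        )
    violations: list[Violation] = []
    budget = params.treatment_level * landscape.R
    states = simulate(landscape, schedule, initial)

    for t in range(schedule.horizon):
        treated = schedule.treated(t)
        area = sum(landscape.unit(uid).area for uid in treated)
        if area > budget + tol:
            violations.append(
                Violation(
                    "budget",
                    None,
                    t,
                    f"treated {area:.4f} ha > budget {budget:.4f} ha",
                )
            )
        if params.enforce_tfi:
            state = states[t]
            for uid in treated:
                u = landscape.unit(uid)
                over_max = any(
                    state.age(uid, p.evc_code) >= evc_defs[p.evc_code].max_tfi
                    for p in u.patches
                )
                under = [
                    p.evc_code
                    for p in u.patches
                    if state.age(uid, p.evc_code) < evc_defs[p.evc_code].min_tfi
                ]
                if under and not over_max:
                    violations.append(
                        Violation(
                            "min_tfi",
                            uid,
                            t,
                            f"treated with EVCs {under} under minimum TFI",
                        )
                    )

    if params.enforce_tfi:
        for state in states[1:]:
            for u in landscape.units:
                for p in u.patches:
                    age = state.age(u.unit_id, p.evc_code)
                    limit = evc_defs[p.evc_code].max_tfi
                    if age > limit:
                        violations.append(
                            Violation(
                                "max_tfi",
                                u.unit_id,
                                state.period,
                                f"EVC {p.evc_code} at age {age} > maxTFI {limit}",
                            )
                        )
    return violations


def make_weights(
    landscape: Landscape,
    mode: str = "total",
    subset: Iterable[str] | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Unit weights for the three objective configurations.

    ``total``  -- every unit weighs 1 (minimise landscape-wide fuel);
    ``subset`` -- weight 1 on the given priority units, 0 elsewhere;
    ``random`` -- seeded uniform(0, 1) draws, one per unit.
    """
    if mode == "total":
        return {uid: 1.0 for uid in landscape.unit_ids}
    if mode == "subset":
        if subset is None:
            raise ConfigurationError("subset mode requires a unit list")
        chosen = set(subset)
        unknown = chosen - set(landscape.unit_ids)
        if unknown:
            raise ConfigurationError(f"subset units not in landscape: {sorted(unknown)}")
        return {uid: 1.0 if uid in chosen else 0.0 for uid in landscape.unit_ids}
    if mode == "random":
        rng = np.random.default_rng(seed)
        return {uid: float(rng.uniform()) for uid in landscape.unit_ids}
    raise ConfigurationError(f"unknown weights mode {mode!r}")


def objective_from_schedule(
    landscape: Landscape,
    schedule: TreatmentSchedule,
    curves: Mapping[str, FuelCurve],
    evc_defs: Mapping[str, EVCDefinition],
    weights: Mapping[str, float] | None = None,
    initial: LandscapeState | None = None,
) -> float:
    """Recompute the objective of a schedule from first principles."""
    states = simulate(landscape, schedule, initial)
    return total_weighted_fuel(landscape, states[1:], curves, evc_defs, weights)
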