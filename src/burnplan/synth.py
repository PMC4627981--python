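"""Synthetic landscapes, parametric fuel curves and the packaged demo data.

The published demonstration instance (40 treatment units with their EVC
composition, areas and stand ages, plus the 40-row EVC catalogue with
min/max TFI and fuel types) ships with the package as plain CSV.  The
source tables do not publish numeric fuel-accumulation curves, only their
shapes, so this module substitutes a saturating-exponential family

    L(k) = L_max * (1 - exp(-rate * k)),   k = 1 .. age_span (years),

with per-fuel-type parameters chosen so the relative magnitudes of the
curves (wet forest > dry forest > woodland > heath > grassland) match the
qualitative ordering and the per-hectare load scale of the region.  All
acceptance checks downstream are property-based and never tied to the
substituted numbers.

The random generator emulates the structure of the full case-study dataset
(hundreds of units, 1-3 vegetation patches each, catalogue EVCs, mixed
ages, optionally a share of over-mature units to exercise the phase-1
repair); it makes no attempt at spatial autocorrelation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    EVCDefinition,
    FuelCurve,
    Landscape,
    TreatmentUnit,
    VegPatch,
)

__all__ = [
    "CurveFamilyParams",
    "GeneratorConfig",
    "make_fuel_curve",
    "default_fuel_curves",
    "generate_landscape",
    "demo_catalogue",
    "demo_landscape",
    "tiny_instance",
]


@dataclass(frozen=True)
class CurveFamilyParams:
    """Parameters of one parametric fuel-accumulation curve."""

    family: str = "saturating_exponential"
    L_max: float = 20.0   # asymptotic load, tonnes/ha
    rate: float = 0.10    # accumulation rate, 1/years
    age_span: int = 150   # tabulated ages 1..age_span (plateau beyond)
    table: Mapping[int, float] | None = None  # for family='piecewise_table'

    def __post_init__(self) -> None:
        if self.L_max < 0 or self.rate <= 0 or self.age_span < 1:
            raise ConfigurationError("need L_max >= 0, rate > 0, age_span >= 1")


def make_fuel_curve(fuel_type: str, params: CurveFamilyParams) -> FuelCurve:
    """Tabulate one fuel curve from its family parameters."""
    if params.family == "saturating_exponential":
        loads = {
            k: params.L_max * (1.0 - float(np.exp(-params.rate * k)))
            for k in range(1, params.age_span + 1)
        }
        return FuelCurve(fuel_type=fuel_type, loads=loads)
    if params.family == "piecewise_table":
        if not params.table:
            raise ConfigurationError("piecewise_table family needs a table")
        return FuelCurve(fuel_type=fuel_type, loads=dict(params.table))
    raise ConfigurationError(f"unknown curve family {params.family!r}")


# Substituted per-fuel-type parameters.  L_max magnitudes follow the
# region's per-hectare load scale (forests tens of t/ha, scrub and heath
# ~10-15, grassland and saltmarsh below that); rates make grass-dominated
# types saturate within a decade and tall forests over several decades.
_CURVE_PARAMS: dict[str, tuple[float, float]] = {
    "1": (11.0, 0.15),   # coastal scrub complexes
    "2": (3.5, 0.25),    # saltmarsh / mangrove
    "3": (8.0, 0.35),    # tussock grassland
    "4": (19.0, 0.12),   # heathy woodland
    "5": (25.0, 0.09),   # dry forest
    "6": (20.0, 0.10),   # foothill / grassy dry forest
    "7": (10.0, 0.15),   # grassy and herb-rich woodlands
    "9": (40.0, 0.05),   # wet forest
    "10": (28.0, 0.07),  # riparian forest
    "11": (12.0, 0.14),  # riparian scrub / thicket
    "13": (15.0, 0.16),  # wet/damp heath
    "14": (12.0, 0.18),  # sand and clay heathland
}


def default_fuel_curves(age_span: int = 150) -> dict[str, FuelCurve]:
    """The substituted curve set covering every catalogue fuel type."""
    return {
        ft: make_fuel_curve(
            ft, CurveFamilyParams(L_max=lm, rate=rt, age_span=age_span)
        )
        for ft, (lm, rt) in _CURVE_PARAMS.items()
    }


# ---------------------------------------------------------------------------
# packaged demonstration instance
# ---------------------------------------------------------------------------


def _read_packaged(name: str) -> list[dict[str, str]]:
    with resources.files("burnplan.data").joinpath(name).open() as f:
        return list(csv.DictReader(f))


def demo_catalogue() -> dict[str, EVCDefinition]:
    """The 40-row EVC catalogue (min/max TFI and fuel type per class)."""
    return {
        row["evc_code"]: EVCDefinition(
            evc_code=row["evc_code"],
            name=row["evc_name"],
            min_tfi=int(row["min_tfi"]),
            max_tfi=int(row["max_tfi"]),
            fuel_type=row["fuel_type"],
        )
        for row in _read_packaged("demo_evc.csv")
    }


def demo_landscape() -> tuple[Landscape, dict[str, EVCDefinition]]:
    """The packaged 40-unit demonstration landscape and its catalogue.

    83 vegetation patches over 40 treatment units (23-29 ha each, about
    1039 ha in total).  Fuel curves are not part of the published tables;
    pair this landscape with :func:`default_fuel_curves` (or your own).
    """
    rows = _read_packaged("demo_units.csv")
    by_unit: dict[str, list[VegPatch]] = {}
    for row in rows:
        by_unit.setdefault(row["unit_id"], []).append(
            VegPatch(
                evc_code=row["evc_code"],
                area=float(row["area_ha"]),
                age=int(row["age"]),
            )
        )
    units = [
        TreatmentUnit(unit_id=uid, patches=tuple(ps))
        for uid, ps in by_unit.items()
    ]
    return Landscape(units=tuple(units)), demo_catalogue()


# ---------------------------------------------------------------------------
# random landscapes
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Controls for the random landscape generator.

    ``over_max_fraction`` marks that share of units as over-mature: one of
    their patches starts at or above its EVC's maximum TFI, which makes the
    raw landscape infeasible for the exact model and exercises the phase-1
    repair.  Ages are drawn per EVC in [1, maxTFI) unless overridden.
    """

    n_units: int = 100
    area_range: tuple[float, float] = (5.0, 200.0)
    patches_per_unit: tuple[int, int] = (1, 3)
    evc_catalogue: Mapping[str, EVCDefinition] | None = None
    age_range: tuple[int, int] | None = None
    over_max_fraction: float = 0.0
    over_max_age_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        lo, hi = self.area_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid area_range")
        plo, phi = self.patches_per_unit
        if not (1 <= plo <= phi):
            raise ConfigurationError("invalid patches_per_unit")
        if not (0 <= self.over_max_fraction <= 1):
            raise ConfigurationError("over_max_fraction must be in [0, 1]")


def generate_landscape(
    config: GeneratorConfig,
) -> tuple[Landscape, dict[str, FuelCurve], dict[str, EVCDefinition]]:
    """Draw a random landscape; deterministic under ``config.seed``."""
    evc_defs = dict(config.evc_catalogue or demo_catalogue())
    if not evc_defs:
        raise ConfigurationError("EVC catalogue is empty")
    codes = sorted(evc_defs)
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_units))
    units = []
    for i in range(config.n_units):
        npatch = int(rng.integers(config.patches_per_unit[0],
                                  config.patches_per_unit[1] + 1))
        npatch = min(npatch, len(codes))
        chosen = rng.choice(codes, size=npatch, replace=False)
        total = float(rng.uniform(*config.area_range))
        shares = rng.dirichlet(np.ones(npatch))
        over_mature = rng.uniform() < config.over_max_fraction
        over_patch = int(rng.integers(npatch)) if over_mature else -1
        patches = []
        for j, code in enumerate(chosen):
            evc = evc_defs[code]
            if j == over_patch:
                hi = max(int(evc.max_tfi * config.over_max_age_factor),
                         evc.max_tfi + 1)
                age = int(rng.integers(evc.max_tfi, hi + 1))
            elif config.age_range is not None:
                age = int(rng.integers(config.age_range[0],
                                       config.age_range[1] + 1))
            else:
                age = int(rng.integers(1, max(evc.max_tfi, 2)))
            patches.append(VegPatch(evc_code=code,
                                    area=max(total * shares[j], 1e-3),
                                    age=age))
        units.append(
            TreatmentUnit(unit_id=f"u{i + 1:0{width}d}", patches=tuple(patches))
        )
    curves = default_fuel_curves()
    missing = {evc.fuel_type for evc in evc_defs.values()} - set(curves)
    for ft in sorted(missing):
        curves[ft] = make_fuel_curve(ft, CurveFamilyParams())
    return Landscape(units=tuple(units)), curves, evc_defs


# ---------------------------------------------------------------------------
# verification-scale instances
# ---------------------------------------------------------------------------


def tiny_instance(
    seed: int,
    n_units: int = 4,
    max_patches: int = 2,
    horizon: int = 4,
    forcing: bool = True,
) -> tuple[Landscape, dict[str, FuelCurve], dict[str, EVCDefinition], float]:
    """A small random instance for exhaustive verification.

    TFI limits are scaled down so the dynamics play out within a handful of
    periods: minimum TFIs of 1-2 years and (with ``forcing``) maximum TFIs
    of 3-6 years, so forced treatments, the min-TFI coupling and the budget
    all interact inside the enumeration guard.  With ``forcing`` off the
    maximum TFIs sit beyond reach of the horizon, so no treatment is ever
    compulsory (the regime in which the myopic heuristics are guaranteed
    feasible).  Returns (landscape, curves, evc_defs, rho).
    """
    rng = np.random.default_rng(seed)
    evc_defs: dict[str, EVCDefinition] = {}
    curves: dict[str, FuelCurve] = {}
    n_evc = 3
    for e in range(n_evc):
        code = f"E{e + 1}"
        min_tfi = int(rng.integers(1, 3))
        if forcing:
            max_tfi = int(rng.integers(max(min_tfi, 3), 7))
        else:
            max_tfi = int(rng.integers(horizon + 10, horizon + 20))
        evc_defs[code] = EVCDefinition(
            evc_code=code, name=f"synthetic class {code}",
            min_tfi=min_tfi, max_tfi=max_tfi, fuel_type=code,
        )
        slope = float(rng.uniform(0.5, 3.0))
        curves[code] = FuelCurve(
            fuel_type=code,
            loads={k: slope * k for k in range(1, 41)},
        )
    units = []
    for i in range(n_units):
        npatch = int(rng.integers(1, max_patches + 1))
        chosen = rng.choice(sorted(evc_defs), size=npatch, replace=False)
        patches = []
        for code in chosen:
            evc = evc_defs[code]
            age = int(rng.integers(1, evc.max_tfi + 1)) if forcing else int(
                rng.integers(1, 6)
            )
            patches.append(
                VegPatch(evc_code=code, area=float(rng.integers(1, 6)), age=age)
            )
        units.append(TreatmentUnit(unit_id=f"u{i + 1}", patches=tuple(patches)))
    landscape = Landscape(units=tuple(units))
    rho = float(rng.uniform(0.3, 0.6))
    return landscape, curves, evc_defs, rho
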