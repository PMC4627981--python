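import pytest

from burnplan.core import (
    EVCDefinition,
    FuelCurve,
    Landscape,
    TreatmentUnit,
    VegPatch,
)


def make_curve(fuel_type="F", const=None, slope=None, kmax=40):
    """A constant or linear fuel curve for hand-computable tests."""
    if const is not None:
        loads = {k: float(const) for k in range(1, kmax + 1)}
    else:
        loads = {k: float(slope) * k for k in range(1, kmax + 1)}
    return FuelCurve(fuel_type=fuel_type, loads=loads)


def make_instance(patch_specs, min_tfi=1, max_tfi=99, const_load=10.0):
    """One-EVC landscape from [(unit_id, area, age), ...] triples."""
    evc = EVCDefinition(
        evc_code="E", name="test class", min_tfi=min_tfi, max_tfi=max_tfi,
        fuel_type="F",
    )
    units = tuple(
        TreatmentUnit(
            unit_id=uid,
            patches=(VegPatch(evc_code="E", area=area, age=age),),
        )
        for uid, area, age in patch_specs
    )
    curves = {"F": make_curve(const=const_load, kmax=200)}
    return Landscape(units=units), curves, {"E": evc}


@pytest.fixture(scope="session")
def demo():
    from burnplan.synth import default_fuel_curves, demo_landscape

    landscape, evc_defs = demo_landscape()
    return landscape, evc_defs, default_fuel_curves()
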