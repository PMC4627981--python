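"""Unit tests for the landscape domain model and its dynamics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnplan.core import (
    ConfigurationError,
    EVCDefinition,
    FuelCurve,
    Landscape,
    LandscapeState,
    PlanningParams,
    TreatmentSchedule,
    TreatmentUnit,
    VegPatch,
    advance_state,
    classify_units,
    make_weights,
    simulate,
    total_weighted_fuel,
    unit_area,
    unit_fuel_load,
    validate_schedule,
)

from conftest import make_curve, make_instance


# ---------------------------------------------------------------------------
# areas and fuel loads
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "areas, expected",
    [([6.07], 6.07), ([3.0, 4.0], 7.0), ([0.72], 0.72)],
)
def test_unit_area_is_sum_of_patches(areas, expected):
    unit = TreatmentUnit(
        unit_id="u",
        patches=tuple(
            VegPatch(evc_code=f"E{i}", area=a, age=5) for i, a in enumerate(areas)
        ),
    )
    assert unit_area(unit) == pytest.approx(expected)


def test_unit_fuel_load_constant_curve():
    landscape, curves, defs = make_instance([("u", 2.0, 5)], const_load=10.0)
    state = LandscapeState.initial(landscape)
    assert unit_fuel_load(landscape.units[0], state, curves, defs) == pytest.approx(20.0)


def test_unit_fuel_load_weighted_sum_over_patches():
    defs = {
        "A": EVCDefinition("A", "a", 1, 99, "fa"),
        "B": EVCDefinition("B", "b", 1, 99, "fb"),
    }
    curves = {"fa": make_curve("fa", const=5.0), "fb": make_curve("fb", const=2.0)}
    unit = TreatmentUnit(
        "u", (VegPatch("A", 1.0, 3), VegPatch("B", 3.0, 7))
    )
    landscape = Landscape(units=(unit,))
    state = LandscapeState.initial(landscape)
    assert unit_fuel_load(unit, state, curves, defs) == pytest.approx(1 * 5 + 3 * 2)


def test_fuel_curve_plateau_beyond_tabulated_ages():
    curve = FuelCurve("F", {k: float(k) for k in range(1, 101)})
    assert curve.load(200) == curve.load(100) == 100.0


def test_missing_curve_is_a_configuration_error():
    landscape, curves, defs = make_instance([("u", 1.0, 1)])
    state = LandscapeState.initial(landscape)
    with pytest.raises(ConfigurationError):
        unit_fuel_load(landscape.units[0], state, {}, defs)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def test_advance_state_ages_and_resets():
    landscape, _, _ = make_instance([("a", 1.0, 7), ("b", 2.0, 7)])
    state = LandscapeState.initial(landscape)
    nxt = advance_state(landscape, state, {"b"})
    assert nxt.age("a", "E") == 8          # untreated: +1
    assert nxt.age("b", "E") == 1          # treated: reset
    assert nxt.period == 1


def test_advance_state_untreated_induction():
    landscape, _, _ = make_instance([("a", 1.0, 3)])
    state = LandscapeState.initial(landscape)
    for t in range(6):
        state = advance_state(landscape, state, set())
    assert state.age("a", "E") == 3 + 6


def test_advance_state_preserves_patch_structure():
    landscape, _, _ = make_instance([("a", 1.0, 3), ("b", 2.0, 9)])
    state = LandscapeState.initial(landscape)
    nxt = advance_state(landscape, state, {"a"})
    assert set(nxt.ages) == set(state.ages)


def test_advance_state_rejects_unknown_unit():
    landscape, _, _ = make_instance([("a", 1.0, 3)])
    with pytest.raises(ValueError, match="zz"):
        advance_state(landscape, LandscapeState.initial(landscape), {"zz"})


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def test_objective_zero_weights_and_single_period():
    landscape, curves, defs = make_instance([("u", 2.0, 5)], const_load=10.0)
    sched = TreatmentSchedule.from_treated_sets(landscape, [set()])
    states = simulate(landscape, sched)
    assert total_weighted_fuel(
        landscape, states[1:], curves, defs, {"u": 0.0}
    ) == 0.0
    assert total_weighted_fuel(
        landscape, states[1:], curves, defs, {"u": 1.0}
    ) == pytest.approx(20.0)


def test_objective_additive_over_periods_and_linear_in_weights():
    landscape, curves, defs = make_instance([("u", 2.0, 5)], const_load=10.0)
    sched = TreatmentSchedule.from_treated_sets(landscape, [set(), set()])
    states = simulate(landscape, sched)
    one = total_weighted_fuel(landscape, states[1:2], curves, defs)
    both = total_weighted_fuel(landscape, states[1:], curves, defs)
    assert both == pytest.approx(2 * one) == pytest.approx(40.0)
    tripled = total_weighted_fuel(landscape, states[1:], curves, defs, {"u": 3.0})
    assert tripled == pytest.approx(3 * both)


def test_objective_rejects_gappy_trajectory():
    landscape, curves, defs = make_instance([("u", 2.0, 5)])
    sched = TreatmentSchedule.from_treated_sets(landscape, [set()] * 3)
    states = simulate(landscape, sched)
    with pytest.raises(ValueError):
        total_weighted_fuel(landscape, [states[1], states[3]], curves, defs)


# ---------------------------------------------------------------------------
# TFI classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("age, expected", [(50, "old"), (45, "old"), (20, "middle"),
                                           (5, "middle"), (3, "young")])
def test_classify_single_patch_against_tfi_window(age, expected):
    landscape, _, defs = make_instance([("u", 1.0, age)], min_tfi=5, max_tfi=45)
    part = classify_units(landscape, LandscapeState.initial(landscape), defs)
    assert [u.unit_id for u in part[expected]] == ["u"]


def test_classify_old_takes_precedence_over_young():
    defs = {
        "A": EVCDefinition("A", "a", 5, 45, "f"),
        "B": EVCDefinition("B", "b", 5, 45, "f"),
    }
    unit = TreatmentUnit("u", (VegPatch("A", 1.0, 45), VegPatch("B", 1.0, 2)))
    landscape = Landscape(units=(unit,))
    part = classify_units(landscape, LandscapeState.initial(landscape), defs)
    assert [u.unit_id for u in part["old"]] == ["u"]
    assert not part["young"] and not part["middle"]


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    ages=st.lists(st.integers(1, 120), min_size=1, max_size=8),
    min_tfi=st.integers(1, 20),
    span=st.integers(0, 80),
)
def test_classification_is_a_partition(ages, min_tfi, span):
    """Old/middle/young are disjoint and cover every unit."""
    max_tfi = min_tfi + span
    defs = {"E": EVCDefinition("E", "e", min_tfi, max_tfi, "f")}
    units = tuple(
        TreatmentUnit(f"u{i}", (VegPatch("E", 1.0, a),)) for i, a in enumerate(ages)
    )
    landscape = Landscape(units=units)
    part = classify_units(landscape, LandscapeState.initial(landscape), defs)
    ids = [u.unit_id for group in part.values() for u in group]
    assert sorted(ids) == sorted(landscape.unit_ids)
    assert len(ids) == len(set(ids))


# ---------------------------------------------------------------------------
# schedule validation
# ---------------------------------------------------------------------------


def test_budget_violation_detected():
    landscape, curves, defs = make_instance([("a", 8.0, 10), ("b", 2.0, 10)])
    landscape = Landscape(units=landscape.units, total_treatable_area=70.0)
    params = PlanningParams(horizon=1, treatment_level=0.1)  # budget 7 ha
    sched = TreatmentSchedule.from_treated_sets(landscape, [{"a"}])
    viols = validate_schedule(landscape, sched, params, curves, defs)
    assert [v.constraint for v in viols] == ["budget"]


def test_max_tfi_violation_appears_when_age_first_exceeds_limit():
    landscape, curves, defs = make_instance([("a", 1.0, 44)], min_tfi=5, max_tfi=45)
    params = PlanningParams(horizon=3, treatment_level=1.0)
    sched = TreatmentSchedule.from_treated_sets(landscape, [set()] * 3)
    viols = validate_schedule(landscape, sched, params, curves, defs)
    max_viols = [v for v in viols if v.constraint == "max_tfi"]
    # age 44 -> 45 (= max, ok) at t=1, 46 (> max) at t=2 and 47 at t=3
    assert [v.period for v in max_viols] == [2, 3]


def test_tfi_flag_off_checks_budget_only():
    landscape, curves, defs = make_instance([("a", 1.0, 44)], min_tfi=5, max_tfi=45)
    params = PlanningParams(horizon=3, treatment_level=1.0, enforce_tfi=False)
    sched = TreatmentSchedule.from_treated_sets(landscape, [set()] * 3)
    assert validate_schedule(landscape, sched, params, curves, defs) == []


def test_min_tfi_violation_unless_overdue_patch_present():
    defs = {
        "A": EVCDefinition("A", "a", 5, 45, "f"),
        "B": EVCDefinition("B", "b", 5, 45, "f"),
    }
    curves = {"f": make_curve("f", const=1.0)}
    young = TreatmentUnit("y", (VegPatch("A", 1.0, 2),))
    mixed = TreatmentUnit("m", (VegPatch("A", 1.0, 2), VegPatch("B", 1.0, 45)))
    landscape = Landscape(units=(young, mixed))
    params = PlanningParams(horizon=1, treatment_level=1.0)
    sched = TreatmentSchedule.from_treated_sets(landscape, [{"y", "m"}])
    viols = validate_schedule(landscape, sched, params, curves, defs)
    assert [(v.constraint, v.unit_id) for v in viols] == [("min_tfi", "y")]


def test_age_law_closed_form_matches_simulation():
    landscape, curves, defs = make_instance([("a", 1.0, 4)])
    sched = TreatmentSchedule.from_treated_sets(
        landscape, [set(), {"a"}, set(), set()]
    )
    states = simulate(landscape, sched)
    # untreated until t=1: age 4+t; treated at t=1 -> age t-1 afterwards
    assert [s.age("a", "E") for s in states] == [4, 5, 1, 2, 3]


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def test_weight_configurations():
    landscape, _, _ = make_instance([("a", 1.0, 1), ("b", 1.0, 1), ("c", 1.0, 1)])
    assert make_weights(landscape, "total") == {"a": 1.0, "b": 1.0, "c": 1.0}
    assert make_weights(landscape, "subset", subset=["b"]) == {
        "a": 0.0, "b": 1.0, "c": 0.0,
    }
    r1 = make_weights(landscape, "random", seed=11)
    r2 = make_weights(landscape, "random", seed=11)
    assert r1 == r2
    assert all(0 < v < 1 for v in r1.values())
    with pytest.raises(ConfigurationError):
        make_weights(landscape, "subset", subset=["nope"])
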