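"""Single-period decomposition: knapsack, greedy, cases, rolling horizon, phase 1."""

import pytest

from burnplan.core import (
    EVCDefinition,
    Landscape,
    LandscapeState,
    PlanningParams,
    TreatmentUnit,
    VegPatch,
    advance_state,
    classify_units,
    objective_from_schedule,
)
from burnplan.heuristics import (
    greedy_select,
    knapsack_exact,
    phase1_reconcile,
    rolling_horizon,
    single_period_step,
)

from conftest import make_curve, make_instance

ITEMS = [("i1", 3.0, 10.0), ("i2", 4.0, 12.0), ("i3", 5.0, 21.0)]


# ---------------------------------------------------------------------------
# knapsack / greedy
# ---------------------------------------------------------------------------


def test_exact_knapsack_beats_density_ranking_on_worked_example():
    # densities are 3.33 / 3.0 / 4.2, so the greedy scan takes i3 (5 ha) and
    # can fit nothing else: value 21.  The exact solution packs i1+i2 for 22.
    assert knapsack_exact(ITEMS, 7.0) == {"i1", "i2"}
    assert greedy_select(ITEMS, 7.0) == {"i3"}


@pytest.mark.parametrize("select", [knapsack_exact, greedy_select])
def test_selection_edge_cases(select):
    assert select(ITEMS, 0.0) == set()
    assert select([], 10.0) == set()
    assert select([("solo", 2.0, 5.0)], 3.0) == {"solo"}
    assert select(ITEMS, 100.0) == {"i1", "i2", "i3"}


def test_greedy_breaks_density_ties_by_unit_id():
    items = [("b", 2.0, 4.0), ("a", 2.0, 4.0), ("c", 2.0, 4.0)]
    assert greedy_select(items, 2.0) == {"a"}


def test_greedy_skips_misfits_and_continues():
    items = [("big", 8.0, 80.0), ("s1", 2.0, 6.0), ("s2", 2.0, 5.0)]
    # 'big' has the best density but does not fit; the scan continues
    assert greedy_select(items, 5.0) == {"s1", "s2"}


# ---------------------------------------------------------------------------
# single-period case logic
# ---------------------------------------------------------------------------


def _two_tier_landscape():
    """4 overdue units (10 ha each) and 4 treatable mid-age units."""
    defs = {"E": EVCDefinition("E", "e", 5, 45, "F")}
    units = [
        TreatmentUnit(f"old{i}", (VegPatch("E", 10.0, 50),)) for i in range(4)
    ] + [
        TreatmentUnit(f"mid{i}", (VegPatch("E", 10.0, 20),)) for i in range(4)
    ]
    curves = {"F": make_curve(slope=1.0, kmax=60)}
    return Landscape(units=tuple(units)), curves, defs


def test_case1_spends_whole_budget_on_overdue_units_only():
    landscape, curves, defs = _two_tier_landscape()  # R=80, r=40
    state = LandscapeState.initial(landscape)
    dec = single_period_step(landscape, state, 0.25, "kp", curves, defs)  # budget 20
    assert dec.case_taken == "case1"
    assert dec.r == pytest.approx(40.0)
    assert dec.rho_new == pytest.approx(0.25)
    assert dec.treated <= {f"old{i}" for i in range(4)}
    assert dec.area_treated <= 20.0 + 1e-9


def test_case2_forces_all_overdue_then_fills_from_middle():
    landscape, curves, defs = _two_tier_landscape()  # r=40
    state = LandscapeState.initial(landscape)
    dec = single_period_step(landscape, state, 0.75, "kp", curves, defs)  # budget 60
    assert dec.case_taken == "case2"
    assert {f"old{i}" for i in range(4)} <= dec.treated
    assert dec.rho_new == pytest.approx(0.75 - 40.0 / 80.0)
    extra = dec.treated - {f"old{i}" for i in range(4)}
    assert extra and extra <= {f"mid{i}" for i in range(4)}
    assert dec.area_treated <= 60.0 + 1e-9


def test_young_units_are_never_treated():
    defs = {"E": EVCDefinition("E", "e", 5, 45, "F")}
    units = tuple(
        TreatmentUnit(f"y{i}", (VegPatch("E", 5.0, 2),)) for i in range(3)
    )
    landscape = Landscape(units=units)
    curves = {"F": make_curve(slope=1.0)}
    dec = single_period_step(
        landscape, LandscapeState.initial(landscape), 1.0, "kp", curves, defs
    )
    assert dec.treated == set()


def test_without_tfi_every_unit_competes_and_nothing_is_forced():
    landscape, curves, defs = _two_tier_landscape()
    state = LandscapeState.initial(landscape)
    dec = single_period_step(
        landscape, state, 0.25, "kp", curves, defs, enforce_tfi=False
    )
    assert dec.case_taken == "case2"  # r == 0 < budget
    assert dec.r == 0.0
    # overdue units carry the most fuel (age 50 > 20) so they are chosen anyway
    assert dec.area_treated <= 20.0 + 1e-9


def test_greedy_never_removes_more_fuel_than_exact_knapsack():
    landscape, curves, defs = _two_tier_landscape()
    state = LandscapeState.initial(landscape)
    for rho in (0.2, 0.4, 0.6):
        kp = single_period_step(landscape, state, rho, "kp", curves, defs)
        gr = single_period_step(landscape, state, rho, "greedy", curves, defs)
        assert gr.fuel_removed <= kp.fuel_removed + 1e-9


# ---------------------------------------------------------------------------
# rolling horizon
# ---------------------------------------------------------------------------


def test_rolling_horizon_with_t1_reduces_to_single_step():
    landscape, curves, defs = _two_tier_landscape()
    params = PlanningParams(horizon=1, treatment_level=0.25)
    res = rolling_horizon(landscape, params, curves, defs, method="kp")
    dec = single_period_step(
        landscape, LandscapeState.initial(landscape), 0.25, "kp", curves, defs
    )
    assert res.schedule.treated(0) == dec.treated
    assert res.objective == pytest.approx(
        objective_from_schedule(landscape, res.schedule, curves, defs)
    )


@pytest.mark.parametrize("method", ["kp", "greedy"])
def test_rolling_horizon_respects_budget_every_period(method):
    landscape, curves, defs = _two_tier_landscape()
    params = PlanningParams(horizon=6, treatment_level=0.3)
    res = rolling_horizon(landscape, params, curves, defs, method=method)
    budget = 0.3 * landscape.R
    assert len(res.period_log) == 6
    for dec in res.period_log:
        assert dec.area_treated <= budget + 1e-9


# ---------------------------------------------------------------------------
# phase 1 reconciliation
# ---------------------------------------------------------------------------


def _phase1_instance():
    """20 ha of overdue area in 1-ha units plus 80 ha of stable forest."""
    defs = {
        "O": EVCDefinition("O", "overdue", 2, 10, "F"),
        "S": EVCDefinition("S", "stable", 1, 500, "F"),
    }
    units = [
        TreatmentUnit(f"old{i}", (VegPatch("O", 1.0, 15),)) for i in range(20)
    ] + [
        TreatmentUnit(f"bg{i}", (VegPatch("S", 8.0, 5),)) for i in range(10)
    ]
    curves = {"F": make_curve(const=3.0, kmax=600)}
    return Landscape(units=tuple(units)), curves, defs


def test_phase1_clears_static_overdue_area_in_ceiling_of_20_over_7_years():
    landscape, curves, defs = _phase1_instance()  # R = 100
    res = phase1_reconcile(
        landscape, LandscapeState.initial(landscape), curves, defs,
        rho_phase1=0.07, old_fraction_threshold=0.05,
    )
    assert res.converged
    assert res.years == 3  # ceil(20 / 7)
    part = classify_units(landscape, res.state, defs)
    assert sum(u.area for u in part["old"]) < 0.05 * landscape.R


def test_phase1_returns_zero_years_when_already_reconciled():
    landscape, curves, defs = _phase1_instance()
    state = LandscapeState.initial(landscape)
    # age everything down: treat all overdue units first
    state = advance_state(landscape, state, {f"old{i}" for i in range(20)})
    res = phase1_reconcile(landscape, state, curves, defs)
    assert (res.years, res.converged) == (0, True)


def test_phase1_reports_nonconvergence_at_the_year_guard():
    landscape, curves, defs = _phase1_instance()
    res = phase1_reconcile(
        landscape, LandscapeState.initial(landscape), curves, defs,
        rho_phase1=0.07, old_fraction_threshold=0.0, max_years=5,
    )
    assert not res.converged
    assert res.years == 5
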