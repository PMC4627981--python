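# Methods

## The planning problem

A fire-management agency divides its estate into *treatment units*: parcels
that are burned (or not) as a whole.  Each unit `i` holds one or more
vegetation patches, one per Ecological Vegetation Class (EVC) `j`, with area
`A_{i,j}` (ha) and a single representative age `a_{i,j}` (years since last
fire).  Each EVC carries a minimum and maximum Tolerable Fire Interval
(minTFI, maxTFI) and a fuel type `f(j)` whose accumulation curve `L_f(k)`
gives fuel load (t/ha) at age `k`.

The plan chooses binary decisions `x_{i,t}` (treat unit `i` in year
`t = 0..T-1`) to minimise the weighted fuel load carried over the horizon,

    z = sum_{t=1..T} sum_i w_i sum_{j in V_i} L_{f(j)}(k_{i,j,t}) A_{i,j},

where ages evolve deterministically — `k` increments by one each untreated
year and resets to 1 the year after treatment — subject to:

* **budget**: treated area per year is at most `rho * R`, with `rho` the
  treatment level (a fraction, e.g. 0.05) and `R` the total treatable area;
* **maximum TFI**: a unit must be treated in the year any of its vegetation
  reaches its maxTFI (fire-adapted species need fire to rejuvenate);
* **minimum TFI**: a unit holding vegetation younger than its minTFI may
  only be treated if another of its vegetation types is at/over its maxTFI
  (the escape clause that resolves the deadlock in mixed units).

Only periods 1..T are scored; the initial state is data, not a decision
outcome.  `R` defaults to the summed unit area but can be overridden when
the modelled units are a subset of the treatable landscape.

Conventions chosen where the problem statement leaves slack: ages are
1-based (treatment produces age 1 the following year; age 0 does not
exist); "over the maximum TFI" means `age >= maxTFI` and "under the
minimum" means `age < minTFI`; an age equal to maxTFI in the final year
`T` is a legal terminal state, because the treatment that it would force
lies outside the horizon.  The schedule validator and the exact model
implement identical semantics — this is what makes the enumeration oracle a
meaningful referee.

## Exact multi-period model

`burnplan.model` builds the MIP with age indicators `y_{i,j,k,t}` (vegetation
`j` in unit `i` has age `k` in year `t`).  Aging is encoded as
`y_{k+1,t+1} >= y_{k,t} - x_{i,t}`, reset as `y_{1,t+1} >= x_{i,t}`, forced
treatment as `y_{maxTFI,t} <= x_{i,t}` for treatable years, and the
minimum-TFI coupling in big-M form with `|V_i|` as the constant.  Each
vegetation has exactly one age per year; writing that row as an equality
(rather than `<= 1`) is valid here because the age domain always contains
the true age, and it tightens the LP relaxation noticeably.

Two size reductions keep the model small:

* **reachable ages only.**  At year `t` a patch can only be at age
  `a_{i,j} + t` (never treated) or at an age in `1..t` (treated since);
  indicators exist only for those pairs, so the per-patch variable count is
  O(T), not O(maxTFI x T).
* **TFI cap.**  With TFI enforced, no age can exceed
  `min(maxTFI_j, max(p_i, a_{i,j} + q_i))`, where `p_i = min_j maxTFI_j`
  and `q_i = min_j (maxTFI_j - a_{i,j})` — the unit must be treated within
  `q_i` years and at least every `p_i` years thereafter.

Optional valid inequalities (on by default when TFI is enforced): a
treat-by deadline `sum_{t=0..q_i} x_{i,t} >= 1` whenever the deadline falls
inside the treatable horizon; rolling covers
`sum_{tau=t..t+p_i-1} x_{i,tau} >= 1` when `T >= p_i`; and fixing
`x_{i,t} = 0` for years in which no treatment could be legal,
`t < min(min_j(minTFI_j - a_{i,j}), q_i)`.  The deadline window runs to
`q_i` *inclusive*: the forced treatment happens in the year the critical
vegetation *reaches* its maxTFI, and a window ending one year earlier can
cut optimal solutions (it can even contradict the variable fixing when
`minTFI = maxTFI`).  A test asserts the inequalities never change the
optimum on enumeration-scale instances.

A `relax_y` option solves with continuous `y` in [0, 1].  Whenever the
returned `x` is binary the forcing chain makes the optimal `y` integral;
the implementation verifies this and reports (never rounds) fractional
values.

The model is held in a solver-neutral container (variables, linear rows,
objective) and executed by HiGHS through `scipy.optimize.milp`.  Default
limits: `time_limit` 10 800 s, `gap_tolerance` 0.  The reported objective
is always recomputed by re-simulating the returned schedule through
`burnplan.core` — backend objectives are cross-checked, not trusted.  With
an initial age above its maxTFI the model is infeasible at t = 0, so the
build refuses such landscapes up front and names the offending units; the
intended fix is the phase-1 repair below.

## Single-period decomposition

Each year, units partition by TFI status into `I_old` (some patch at/over
maxTFI), `I_middle` (all patches at/over minTFI, none at/over max) and
`I_young` (the rest).  With `r` the overdue area and `rho R` the budget:
if `r >= rho R` (case 1) only overdue units compete for the whole budget;
otherwise (case 2) all overdue units are treated and the remainder
`rho R - r` (equivalently a new level `rho_new = rho - r/R`) is allocated
over `I_middle`.  Young units are never treated.  The allocation step
maximises the fuel load removed subject to the area budget — a 0/1
knapsack, solved exactly as a small MILP (areas are real-valued, so a
dynamic program over integer weights does not apply) or greedily by
descending fuel per hectare with skip-and-continue scanning (ties broken by
unit id; skipping misfits rather than stopping uses the budget more fully,
which is where the greedy variant loses least).  Item values are weighted
by `w_i`, generalising the heuristics to all three weight configurations;
zero-valued units are never selected proactively.  Without TFI enforcement
the partition degenerates (everything is `middle`, nothing is forced).

The rolling-horizon driver applies this step at `t = 0..T-1`, advancing the
landscape between steps, and scores the assembled schedule with the same
periods-1..T accounting as the exact model.  The exact multi-period optimum
is provably a lower bound on both rolling objectives; no ordering between
the two single-period variants holds in general, and a three-item example
in the tests realises the strict gap (greedy 21 vs knapsack 22).

A caveat inherent to the decomposition: in case 1 the budget cannot clear
the overdue backlog, so some units remain above their maxTFI — such
schedules fail the max-TFI validation even when an exact schedule would
have prevented the backlog.  Ages keep incrementing and fuel loads follow
the curve plateau.  The dominance comparisons in the acceptance suite
therefore use instances whose maximum TFIs lie beyond the horizon (no
forcing), where the myopic heuristics are feasible by construction; the
exact-vs-oracle comparisons do include forcing.

## Phase 1 reconciliation

Raw landscapes can carry far more overdue area than a year's budget (the
motivating case study had 35 % of treatable area overdue against a 5 %
annual level).  `phase1_reconcile` runs the exact single-period step year
after year at an elevated level (default 7 % — the level at which planned
burning has been observed to displace essentially all unplanned fire) until
overdue area falls below a threshold fraction of `R` (default 5 %), then
hands the repaired state to the multi-period model.  The approximate step
is available by flag.  A `max_years` guard turns a non-converging repair
(e.g. vegetation re-maturing faster than the budget cycles the landscape)
into an explicit report rather than a loop.

## Verification oracles

`burnplan.oracle` re-solves tiny instances by exhaustive enumeration:
every one of the `2^(|I| T)` schedules is simulated with the same
`advance_state` dynamics and filtered with the same `validate_schedule`
rules (vectorised across schedules), and every knapsack subset is tried
directly.  Hard guards (20 binary decisions / 20 items) keep enumeration in
seconds.  Objective ties use an absolute tolerance of 1e-6 t.

## Packaged demonstration landscape

The 40-unit demonstration instance and the 40-row EVC catalogue ship as
CSVs under `burnplan/data/`.  The tables were transcribed from a flattened
four-column typeset layout; the transcription was reconstructed under three
structural constraints — every EVC code must exist in the catalogue, unit
ids form non-decreasing runs down the columns (two units span column
boundaries), and exactly 40 distinct units — and the 27 locally ambiguous
rows were resolved by the requirement that unit totals fall in the 23-29 ha
band exhibited by every unambiguous unit, which admitted exactly one
reading per row.  Catalogue rows for EVC 894 and EVC 31 remain ambiguous in
the source (resolutions are noted in `data/README.md`); neither occurs in
the 40-unit landscape.  The reconstruction is internally consistent in two
independent ways: no patch starts at or above its maxTFI (the demonstration
is TFI-feasible as published), and the one unit whose grassy-woodland patch
forces treatment in year 1 is exactly the unit whose under-minTFI patch the
escape clause covers in that year.

## Substituted fuel curves

Numeric fuel-accumulation data are not published for this landscape, so the
package substitutes a saturating-exponential family
`L(k) = L_max (1 - e^{-rate k})` tabulated at integer ages with a plateau
beyond the table (raw landscapes carry over-mature stands, so curves must
evaluate at any age).  Per-fuel-type defaults span `L_max` 3.5-40 t/ha and
`rate` 0.05-0.35 /yr, ordered so wet forest > riparian/dry forest >
woodland/heath > grassland > saltmarsh, matching the region's qualitative
curve ordering and per-hectare load scale.  Absolute objective values
therefore are not comparable to published figures; every quantitative check
in the acceptance suite is a property (equivalence, dominance, monotonicity,
feasibility, counts), not a number tied to the substituted curves.

## Synthetic landscapes

`generate_landscape` emulates the case-study data structure: `n` units with
1-3 patches drawn without replacement from the catalogue, unit areas
uniform in a configured range split by a Dirichlet draw, ages uniform in
[1, maxTFI) per EVC, and an optional fraction of units seeded with one
patch at/above its maxTFI (default 0.35 at case-study scale) to exercise
phase 1.  Everything is driven by one seed.  It does not model spatial
adjacency, correlated fire history beyond the single over-mature patch, or
heavy-tailed unit sizes — so passing tests say nothing about spatial
treatment patterns, only about scheduling logic, budgets and TFI handling.
`tiny_instance` produces enumeration-scale instances (3 synthetic EVCs,
linear curves, minTFI 1-2) in two regimes: `forcing=True` scales maxTFI
down to 3-6 years so forced treatment, the escape clause and the budget
interact within four periods; `forcing=False` pushes maxTFI beyond the
horizon for the heuristic-dominance regime.

## Problem sizes and numerical choices

The acceptance suite and script use 4-unit x 4-period instances
(2^16 schedules) for enumeration, 20 instances for exact-vs-oracle and
valid-inequality checks, 15 for dominance, 100 knapsack instances of 5-15
items, a 10 000-state partition property, the 40-unit landscape for budget
monotonicity, and one 711-unit, 100-year run per heuristic.  On the
demonstration landscape the exact model is solved to a 1 % optimality gap;
the 10-year no-TFI configurations are checked with the knapsack rolling
horizon instead, because without TFI structure the LP relaxation is weak
and branch-and-bound does not close those instances in reasonable time (the
original experiments report the same behaviour), and gap-based termination
is deterministic across machines where wall-clock cut-offs are not.
Feasibility tolerances: 1e-9 ha on budgets during validation, 1e-6 t on
objective comparisons.  Ties among equally optimal schedules are left to
the backend; all comparisons are on objectives, never on schedules.

## Known limitations

* No spatial interaction: treating adjacent units in the same year is
  neither rewarded nor penalised, and fire spread is not modelled.
* One representative age per (unit, EVC); partial burns are out of scope.
* The exact model's practical reach is 15-20 units-years of binaries per
  branch-and-bound node cluster; beyond T ~ 15 on realistic landscapes the
  decomposition heuristics are the intended tool.
* Substituted curves mean absolute fuel figures are illustrative; relative
  comparisons between methods and levels are the supported use.
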