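# Methods

This note records the models, numerical choices and limitations behind
`pkreplay`, in the order the pipeline runs.

## Pharmacokinetic model

The model is the classical one-compartment open model with first-order
absorption and elimination. A single oral dose *D* given at t = 0 produces

    C(t) = D · s · ka/(ka − ke) · (exp(−ke·t) − exp(−ka·t)),  t ≥ 0,

where ka and ke are first-order rate constants (1/h) and s = F/V is a
dose-normalised scale (concentration units per dose unit) lumping
bioavailability F and apparent distribution volume V. F and V are not
separately identifiable from concentration data and the package never
separates them. C(t) = 0 for t < 0 by convention (dose not yet given);
times are hours with t = 0 at the first dose of the first cycle.

Two degeneracies are handled explicitly:

- **ka ≈ ke** is a removable singularity. When |ka − ke| < 1e−9·ka the
  analytic limit D·s·ka·t·exp(−ka·t) is used, avoiding catastrophic
  cancellation.
- **Exchange symmetry.** (ka, ke, s) and (ke, ka, s·ka/ke) generate the
  identical curve, so the flip-flop ambiguity is unresolvable from data.
  Fits are canonicalised to ka ≥ ke (absorption at least as fast as
  elimination), the common situation for the oral small molecules this
  workflow targets.

Multi-dose regimens (`DosingRegimen`) are ordered dose events within a
repeating cycle (default 24 h); QD is one event at 0 h and BID is events
at 0 h and 8 h (morning/evening doses 8 h apart). The regimen
concentration is the linear superposition of one Bateman term per elapsed
event, evaluated exactly — no steady-state approximation.

### Fitting

`fit_pk` minimises squared residuals on the linear concentration scale
(default) or on log concentrations (`log_scale=True`; positive
observations only). Predictions are dose-proportional: a series annotated
with dose D is predicted as D·C_unit(t), so several dose levels pool into
one fit. `per_series_scale=True` adds a free multiplier per series
(relaxing strict dose proportionality when studies disagree); the first
series' multiplier is pinned to 1 because a multiplier on every series
would be collinear with the shared scale.

Optimisation uses Levenberg–Marquardt (`scipy.optimize.least_squares`)
on log-parameters, which enforces positivity without bounds. The
initialiser is method-of-moments — ke from the terminal slope of
log-concentration over the later half of the observations, ka a multiple
of ke, scale matched to the observed Cmax — expanded into a fixed
deterministic grid of 12 starts (ka/ke ∈ {1.2, 2, 5, 10} × ke ∈
{½, 1, 2}·ke₀); the best residual sum of squares wins. The procedure is
fully deterministic: there is no random multi-start. Fewer than three
distinct time points raises an error; non-convergence is flagged in the
result, never silent.

Noise-free synthetic data are recovered to ≤ 1e−6 relative error; with 5%
multiplicative noise on 24 points, parameters come back within 15% of
truth (both exercised in the test suite).

### Units

The package is unit-agnostic but carries unit labels through I/O and
refuses to combine series whose labels differ. Doses in dose units (e.g.
mg/kg), concentrations in the unit the data are labelled with (e.g. uM):
the scale s absorbs the conversion. No internal unit conversion exists,
by design — implicit conversion is the failure mode, not the feature.

## Discretization

A continuous cycle curve becomes a `StepProfile`: intervals tiling the
cycle exactly, each with one target concentration.

- **Tiling.** `tile_cycle(cycle_length, fine_duration, fine_window,
  coarse_duration)` places fine intervals over `[0, fine_window)` and
  coarse intervals over the remainder; indivisible arguments raise a
  tiling error naming the remainder. The default daily layout — 1-h steps
  over the first 2 h after dosing, 2-h steps over the remaining 22 h —
  gives 13 steps per 24 h and puts the fine steps where absorption makes
  the curve steepest. The early placement of the fine window is the only
  1-/2-h mix consistent with 13 steps per day; the window is
  configurable.
- **Targets.** Each step's target is the median of the curve over its
  interval, computed on a uniform midpoint grid (cell centres of the
  half-open interval) at 1-minute default spacing. The median is robust
  and reproducible; midpoint placement keeps targets stable under grid
  refinement (halving the spacing moves targets by ≪ 0.5%), which a
  left-aligned grid does not achieve on steep intervals. For a monotone
  curve the median sits at the interval's temporal midpoint. Curves
  supplied as sampled series are evaluated by linear interpolation.
- **Coverage profiles.** `build_coverage_profile(level, hold_h, ...)`
  holds a fixed concentration (e.g. an IC50 or IC90) for part of the
  cycle and targets 0 for the rest — the hold-then-washout programs used
  to separate depth from duration of target inhibition.

The 13-interval tiling keeps the stepwise daily AUC within 10% of the
continuous AUC for Bateman curves with Tmax ≥ 0.5 h (asserted on the
fixture parameter sets; ~0.3% for the default fixture).

## Schedule compilation

Each concentration change is a partial media exchange: aspirate down to
the residual volume V_r, refill with blank medium plus per-drug stock
volumes to the working volume V_w. Under ideal mixing,

    C_new = (C_prev·V_r + V_d·S) / V_w   ⇒   V_d = (C*·V_w − C_prev·V_r)/S.

One exchange cannot go below the carryover floor C_prev·V_r/V_w. When a
target sits below the floor, the compiler prepends the minimal number k
of full blank washout exchanges — each multiplies the carried
concentration by V_r/V_w — such that the final dispense is nonnegative
(k found by iteration, not logarithms, to avoid edge-of-precision
miscounts). A target of exactly 0 is unreachable by finite washouts; the
compiler washes until the carried concentration is below
`washout_tolerance` (default 1e−3 relative to the pre-step value, i.e.
three exchanges at the default 5% carryover) and records the achieved
nonzero residue in the operation's audit fields. For nonzero targets the
compiler is exact: simulating the returned operation reproduces the
target to machine precision (asserted at ≤ 1e−9 relative throughout).

Checked constraints, each with a named error:

- a single drug's volume, or the sum over drugs sharing one refill,
  exceeding V_w − V_r → infeasible target, naming the limiting drug;
- a nonzero volume below `min_dispense` (default 1 uL) → quantization
  error carrying the nearest achievable target (never silent rounding);
- per-step pump time: all wells at one start time are served by one pump,
  so Σ pumped volume / flow rate must fit in the step duration; aspirate
  and dispense are charged at the same rate, (k+1)·2·(V_w − V_r) per well
  per step. Violations report required vs available minutes.

Device defaults: V_w = 1000 uL, V_r = 50 uL (5% carryover; the physical
device fixes the aspiration needle height, so V_r is a required geometry
input rather than something derivable), flow 500 uL/min within the
400–750 uL/min operating range (device calibration spans 2.4–890 uL/min,
enforced as hard bounds), ≤ 24 wells per valve unit (a 25-port valve
addresses 24 wells plus a flush port) on a 24-well plate or one quadrant
of a 96-well plate. Blank is dispensed before drug stocks, matching
device operation; the order is irrelevant under ideal mixing but recorded
for fidelity.

Schedules are stored fully unrolled across cycles. The first cycle starts
from blank wells while later cycles inherit the previous cycle's final
carryover, so the first cycle's volumes genuinely differ; per-cycle
recompilation is what makes every end-of-step concentration exact in
every cycle. Two-drug programs (e.g. a QD compound plus a BID partner)
share exchanges with independent stock volumes and must share a tiling;
wells are individually addressable, so each well may carry its own
profile assignment.

Validation staircases (`build_staircase_program`) ascend
base·fold^0..fold^(n−1) and descend symmetrically; the 8-level 3-fold
program spans 3^7 = 2187-fold between extreme plateaus. At a stock of
1.5× the top level, maintaining the base level needs ~0.3 uL dispenses,
so staircase configs use a smaller dispense quantum (0.05 uL in the
shipped programs) — a device-configuration requirement for the program to
compile, with no effect on the simulated plateau values.

## Digital twin

`simulate` executes schedules with exact mixing arithmetic and is
bit-deterministic. Wells start blank at V_w. Assumptions, which are also
the simulator's limitations relative to a physical device:

- **Ideal instantaneous mixing** at each exchange; no mixing model is
  attempted.
- **No intra-step kinetics** by default: concentration is constant
  between exchanges. An optional per-step `loss_factor` (retention
  multiplier < 1) emulates first-order evaporation/adsorption losses for
  sensitivity studies; PDMS absorption in real devices is a known effect
  the default ignores.
- **No pump error model**: measured flow-rate spreads are hardware
  characterisation, not a specified stochastic model, so none is invented.

A per-drug mass ledger (cumulative dispensed stock mass − aspirated mass
= mass in well) is carried through every step and exposed in the trace;
tests assert it balances to 1e−9 relative. Blank exchanges scale every
drug concentration by exactly V_r/V_w (closed form equals iterative
simulation), and one drug's trace is unaffected by the other's profile
(stocks are single-drug).

Scoring: `replication_error` compares a stepped trace against the
continuous reference — AUC ratio (rectangle sum over steps vs trapezoid
on a 1-min grid), Cmax ratio, and the largest deviation of end-of-step
concentrations from the reference's interval medians. `staircase_audit`
extracts plateaus at scheduled level boundaries (the schedule is known;
change-point inference would add nothing), reports consecutive
ascending/descending ratios and the max/min ratio over nonzero-target
plateaus, excluding and counting zero-target plateaus.

## Exposure metrics

- `auc`: trapezoidal for continuous series; exact rectangle sum for
  stepped traces (a recorded value is held backward to the previous
  boundary, matching end-of-step trace semantics). Exactly additive over
  adjacent windows.
- `cmax_tmax`: maximum and first time attaining it (ties break to the
  earliest time).
- `time_above`: linear interpolation at threshold crossings for
  continuous series; whole-step counting without interpolation for
  stepped traces. Monotone non-increasing in the threshold.
- `hill_inhibition`: C^n/(C^n + IC50^n), strictly increasing, range
  [0, 1). Slope defaults to 1, under which IC90 = 9·IC50 — consistent
  with the 0.1/0.9 uM IC50/IC90 pair used in the coverage programs; the
  slope is configurable. IC50/IC90 values are user inputs from external
  potency assays, not quantities the package estimates.
- `coverage_summary`: per-cycle time-weighted mean inhibition and hours
  above IC50/IC90; trailing partial cycles are reported separately and
  flagged. Thresholds are shaved by one part in 1e12 so a trace held
  exactly at the IC90 counts as covered despite float round-off.

## Synthetic data

`generate_pk_fixture` produces model concentrations under a regimen times
multiplicative lognormal noise of a given CV (unit mean; σ² = ln(1+CV²)),
deterministic per seed and refusing noise without a seed. It emulates
assay noise on an otherwise correct model; it does not emulate model
misspecification, below-quantification censoring, sparse/irregular
sampling designs, or between-animal variability — parameter-recovery
results therefore demonstrate numerical correctness of the fitting
machinery, not robustness to those real-data features.

The shipped parameter sets are synthetic stand-ins, chosen to be
pharmacologically plausible: `erki` (ka = 1.2/h, ke = 0.18/h,
s = 0.0604 uM per mg/kg) mimics a rapidly absorbed QD kinase inhibitor —
at 50 mg/kg it peaks at ≈ 2.16 uM around t ≈ 1.9 h with a ~3.9 h
elimination half-life; `dnapki` (ka = 1.5/h, ke = 0.35/h, s = 0.03)
mimics a faster-clearing BID partner. No fitted parameters from any
study are shipped because none are published for these workflows.

## Problem sizes

The test suite and acceptance script run entirely at desk scale: fits on
12–24 points, schedules of 13–182 steps over 1–14 daily cycles, one to a
few wells, staircases of 15 plateaus — sizes matching the experiments
the workflow supports (a 24-well plate dosed for up to three weeks), and
all computable in seconds.

## Known limitations

- One-compartment linear PK only: no multi-compartment models, saturable
  clearance, protein binding, or allometric scaling.
- Rule-based tilings only; no error-optimal interval placement.
- Wells are untouched between scheduled steps (no within-step refresh).
- No pharmacodynamic (growth/kill) model: the package quantifies exposure
  and target coverage, and deliberately stops there.
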