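"""Compile step profiles into executable per-well volume schedules.

Each concentration change in a well is a partial media exchange: aspirate
down to the residual volume V_r (set by the fixed needle height), then
refill to the working volume V_w with blank medium plus per-drug stock
volumes. Under ideal mixing the single-exchange mass balance is

    C_new = (C_prev * V_r + V_d * S) / V_w

so the dispense volume solving for a target C* is

    V_d = (C* * V_w - C_prev * V_r) / S.

Carryover sets a floor: one exchange can only reduce a concentration to
C_prev * V_r / V_w. Targets below the floor need preceding full blank
washout exchanges, each multiplying the carried concentration by V_r / V_w.
The compiler is exact: simulating a compiled operation reproduces its
(nonzero) targets to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (InfeasibleTargetError, InvalidParameterError,
                     QuantizationError, SchedulingError)
from .plates import get_layout
from .profiles import Step, StepProfile, profile_from_steps

__all__ = [
    "DeviceConfig",
    "StockSet",
    "StepOperation",
    "WellSchedule",
    "Schedule",
    "compile_step",
    "compile_profile",
    "compile_wells",
    "fixed_dose_reference",
    "build_staircase_program",
]

#: Device flow-rate calibration range (uL/min).
FLOW_RATE_MIN = 2.4
FLOW_RATE_MAX = 890.0

_REL_TOL = 1e-12
_MAX_WASHOUTS = 200


@dataclass(frozen=True)
class DeviceConfig:
    """Physical constraints of the dosing device.

    Attributes
    ----------
    working_volume : float
        Well volume after refill, V_w (uL).
    residual_volume : float
        Volume left after aspirating to the needle stop, V_r (uL). The
        needle sits at a fixed height so a well is never emptied below it.
    flow_rate : float
        Pump flow rate Q (uL/min), charged identically for aspiration and
        dispense.
    min_dispense : float
        Smallest deliverable nonzero volume (uL); smaller demands raise a
        quantization error rather than being silently rounded.
    n_wells : int
        Wells driven by this valve unit (<= 24).
    plate_layout : str
        Named layout wells are drawn from.
    washout_tolerance : float
        For a target of exactly 0 (unreachable by finite washouts) the
        compiler washes until the carried concentration is below this
        fraction of the pre-step concentration.
    loss_factor : float
        Optional per-step first-order retention multiplier applied to well
        concentrations before each exchange (1.0 = no loss); models
        evaporation/adsorption for sensitivity studies.
    """

    working_volume: float = 1000.0
    residual_volume: float = 50.0
    flow_rate: float = 500.0
    min_dispense: float = 1.0
    n_wells: int = 24
    plate_layout: str = "24-well"
    washout_tolerance: float = 1e-3
    loss_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.residual_volume < self.working_volume):
            raise InvalidParameterError(
                f"need 0 < residual_volume < working_volume, got "
                f"{self.residual_volume} / {self.working_volume}")
        if not (FLOW_RATE_MIN <= self.flow_rate <= FLOW_RATE_MAX):
            raise InvalidParameterError(
                f"flow_rate {self.flow_rate} uL/min outside device range "
                f"[{FLOW_RATE_MIN}, {FLOW_RATE_MAX}]")
        layout = get_layout(self.plate_layout)
        if not (1 <= self.n_wells <= layout.n_wells):
            raise InvalidParameterError(
                f"n_wells {self.n_wells} outside 1..{layout.n_wells} for "
                f"layout {self.plate_layout!r}")
        if self.min_dispense < 0:
            raise InvalidParameterError("min_dispense must be >= 0")
        if not (0 < self.washout_tolerance < 1):
            raise InvalidParameterError("washout_tolerance must be in (0, 1)")
        if not (0 < self.loss_factor <= 1):
            raise InvalidParameterError("loss_factor must be in (0, 1]")

    @property
    def refill_volume(self) -> float:
        """Volume added (and removed) per exchange: V_w - V_r (uL)."""
        return self.working_volume - self.residual_volume

    @property
    def carryover_fraction(self) -> float:
        """V_r / V_w: concentration retained by one blank exchange."""
        return self.residual_volume / self.working_volume

    def wells(self) -> tuple[str, ...]:
        return get_layout(self.plate_layout).wells[: self.n_wells]


@dataclass(frozen=True)
class StockSet:
    """Per-drug stock concentrations; blank medium is implicitly 0.

    Stocks are single-drug: combinations are made in the well, never in a
    bottle, so there is no cross-contamination between compounds.
    """

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", dict(self.concentrations))
        for drug, s in self.concentrations.items():
            if not (math.isfinite(s) and s > 0):
                raise InvalidParameterError(
                    f"stock concentration for {drug!r} must be > 0, got {s!r}")

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    def __getitem__(self, drug: str) -> float:
        return self.concentrations[drug]


@dataclass(frozen=True)
class StepOperation:
    """One scheduled exchange: washouts, then blank + drug dispenses.

    ``n_washouts`` full blank exchanges precede the final exchange.
    ``achieved`` records the concentrations the operation produces under
    ideal mixing (equal to the targets except for exact-zero targets,
    where the carryover floor remains). Dispense order is blank first,
    then drugs; irrelevant to the end state under ideal mixing but
    recorded for fidelity to device operation.
    """

    start: float
    duration: float
    n_washouts: int
    blank_volume: float
    drug_volumes: dict[str, float]
    targets: dict[str, float]
    achieved: dict[str, float]

    @property
    def total_dispensed(self) -> float:
        return self.blank_volume + sum(self.drug_volumes.values())

    def pumped_volume(self, config: DeviceConfig) -> float:
        """Total liquid moved (aspirated + dispensed) by this operation."""
        return 2.0 * (self.n_washouts + 1) * config.refill_volume


@dataclass(frozen=True)
class WellSchedule:
    well_id: str
    steps: tuple[StepOperation, ...]


@dataclass(frozen=True)
class Schedule:
    """Executable program: per-well operation lists plus device context.

    Steps are stored fully unrolled over all cycles (absolute start
    times): the first cycle starts from blank wells while later cycles
    inherit carryover from the previous cycle's last step, so their
    compiled volumes can differ.
    """

    device: DeviceConfig
    stocks: StockSet
    cycle_length: float
    n_cycles: int
    wells: tuple[WellSchedule, ...]

    @property
    def total_duration(self) -> float:
        return self.cycle_length * self.n_cycles

    def validate_time_budget(self) -> None:
        """Check every step slot fits the pump's time budget.

        All wells sharing a start time are served sequentially by one
        pump, so the summed pumped volume divided by the flow rate must
        fit within the step duration.
        """
        slots: dict[float, tuple[float, float]] = {}
        for ws in self.wells:
            for op in ws.steps:
                vol, _ = slots.get(op.start, (0.0, op.duration))
                slots[op.start] = (vol + op.pumped_volume(self.device), op.duration)
        for start, (vol, duration) in sorted(slots.items()):
            required = vol / self.device.flow_rate
            available = duration * 60.0
            if required > available:
                raise SchedulingError(
                    f"step at t={start} h needs {required:.1f} min of pumping "
                    f"but only {available:.1f} min are available",
                    required_min=required, available_min=available)


def _zero_target_washouts(config: DeviceConfig) -> int:
    # exchanges (washouts + final) reducing carryover below tolerance
    r = config.carryover_fraction
    n_exchanges = max(1, math.ceil(math.log(config.washout_tolerance) / math.log(r) - 1e-12))
    return n_exchanges - 1


def compile_step(prev_conc: Mapping[str, float], targets: Mapping[str, float],
                 config: DeviceConfig, stocks: StockSet, *,
                 start: float = 0.0, duration: float = 1.0) -> StepOperation:
    """Solve one step's aspirate/blank/stock volumes for the given targets.

    Raises
    ------
    InfeasibleTargetError
        If a target exceeds what pure stock can deliver in one exchange.
    QuantizationError
        If a required nonzero dispense is below ``config.min_dispense``;
        the error carries the nearest feasible target.
    """
    V_w, V_r = config.working_volume, config.residual_volume
    refill = config.refill_volume
    r = config.carryover_fraction
    unknown = set(targets) - set(stocks.drugs)
    if unknown:
        raise InvalidParameterError(f"no stock configured for drug(s) {sorted(unknown)}")
    drugs = [d for d in stocks.drugs if d in targets or prev_conc.get(d, 0.0) > 0]
    tgt = {d: float(targets.get(d, 0.0)) for d in drugs}
    prev = {d: float(prev_conc.get(d, 0.0)) for d in drugs}
    for d, t in tgt.items():
        if t < 0:
            raise InvalidParameterError(f"target for {d!r} must be >= 0")

    # minimal washout count so every dispense volume is >= 0
    k = 0
    for d in drugs:
        if prev[d] <= 0:
            continue
        if tgt[d] == 0.0:
            k = max(k, _zero_target_washouts(config))
            continue
        kd = 0
        while prev[d] * r**kd * V_r > tgt[d] * V_w * (1 + _REL_TOL):
            kd += 1
            if kd > _MAX_WASHOUTS:
                raise InfeasibleTargetError(
                    f"washout for {d!r} did not converge", drug=d)
        k = max(k, kd)

    carried = {d: prev[d] * r**k for d in drugs}
    vols: dict[str, float] = {}
    for d in drugs:
        v = (tgt[d] * V_w - carried[d] * V_r) / stocks[d]
        if v < 0:  # only for exact-zero targets below the washed floor
            v = 0.0
        if v > refill * (1 + _REL_TOL):
            raise InfeasibleTargetError(
                f"target {tgt[d]} for {d!r} needs {v:.1f} uL of stock but only "
                f"{refill:.1f} uL can be dispensed; raise the stock "
                f"concentration ({stocks[d]})", drug=d)
        if 0 < v < config.min_dispense * (1 - _REL_TOL):
            floor = carried[d] * r
            with_min = (carried[d] * V_r + config.min_dispense * stocks[d]) / V_w
            suggestion = floor if abs(tgt[d] - floor) <= abs(tgt[d] - with_min) else with_min
            raise QuantizationError(
                f"target {tgt[d]} for {d!r} needs {v:.4f} uL, below the "
                f"minimum dispense {config.min_dispense} uL; nearest feasible "
                f"target is {suggestion:.6g}", drug=d, suggested_target=suggestion)
        vols[d] = v
    total = sum(vols.values())
    if total > refill * (1 + _REL_TOL):
        limiting = max(vols, key=vols.get)
        raise InfeasibleTargetError(
            f"combined stock volumes {total:.1f} uL exceed the refill volume "
            f"{refill:.1f} uL; limiting drug {limiting!r}", drug=limiting)
    achieved = {d: (carried[d] * V_r + vols[d] * stocks[d]) / V_w for d in drugs}
    return StepOperation(start=start, duration=duration, n_washouts=k,
                         blank_volume=refill - total, drug_volumes=vols,
                         targets=tgt, achieved=achieved)


def _compile_well(profiles: Sequence[StepProfile], config: DeviceConfig,
                  stocks: StockSet, n_cycles: int) -> tuple[StepOperation, ...]:
    prev: dict[str, float] = {p.drug: 0.0 for p in profiles}
    ops: list[StepOperation] = []
    cycle_length = profiles[0].cycle_length
    for cycle in range(n_cycles):
        offset = cycle * cycle_length
        for i in range(len(profiles[0].steps)):
            step0 = profiles[0].steps[i]
            targets = {p.drug: p.steps[i].target for p in profiles}
            op = compile_step(prev, targets, config, stocks,
                              start=offset + step0.start, duration=step0.duration)
            ops.append(op)
            prev = {**prev, **op.achieved}
    return tuple(ops)


def compile_profile(profiles: StepProfile | Sequence[StepProfile],
                    config: DeviceConfig, stocks: StockSet, *,
                    n_cycles: int = 1, wells: Sequence[str] | None = None) -> Schedule:
    """Compile one or two step profiles into a schedule for a set of wells.

    With two profiles (one per drug, e.g. a QD compound plus a BID
    partner) the tilings must match; both drugs are delivered in the same
    exchanges with independent stock volumes. Every listed well receives
    the same program; use :func:`compile_wells` to assign distinct
    profiles per well.
    """
    if isinstance(profiles, StepProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if not 1 <= len(profiles) <= 2:
        raise InvalidParameterError("compile_profile takes 1 or 2 profiles")
    if len(profiles) == 2:
        a, b = profiles
        if a.drug == b.drug:
            raise InvalidParameterError("two profiles must name distinct drugs")
        if a.tiling.boundaries != b.tiling.boundaries:
            raise InvalidParameterError("two profiles must share an identical tiling")
    well_ids = tuple(wells) if wells is not None else config.wells()
    assignments = {w: profiles for w in well_ids}
    return compile_wells(assignments, config, stocks, n_cycles=n_cycles)


def compile_wells(assignments: Mapping[str, Sequence[StepProfile]],
                  config: DeviceConfig, stocks: StockSet, *,
                  n_cycles: int = 1) -> Schedule:
    """Compile per-well profile assignments (wells are individually addressable)."""
    if not assignments:
        raise InvalidParameterError("no wells assigned")
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    cycle_lengths = {p.cycle_length for profs in assignments.values() for p in profs}
    if len(cycle_lengths) != 1:
        raise InvalidParameterError("all profiles must share one cycle length")
    cycle_length = cycle_lengths.pop()
    compiled = []
    cache: dict[tuple, tuple[StepOperation, ...]] = {}
    for well_id, profs in assignments.items():
        profs = list(profs)
        key = tuple(id(p) for p in profs)
        if key not in cache:
            cache[key] = _compile_well(profs, config, stocks, n_cycles)
        compiled.append(WellSchedule(well_id=well_id, steps=cache[key]))
    schedule = Schedule(device=config, stocks=stocks, cycle_length=cycle_length,
                        n_cycles=n_cycles, wells=tuple(compiled))
    schedule.validate_time_budget()
    return schedule


def fixed_dose_reference(profile: StepProfile) -> float:
    """Bolus concentration matched to the highest step target of a profile.

    The conventional static-dosing comparator: a fixed dose at the
    maximum concentration the dynamic program ever delivers.
    """
    if not profile.steps:
        raise InvalidParameterError("profile is empty")
    return max(profile.targets)


def staircase_levels(base: float, fold: float, n_levels: int) -> tuple[float, ...]:
    """Ascending then descending plateau levels: base*fold^0..^(n-1)..^0."""
    up = [base * fold**i for i in range(n_levels)]
    return tuple(up + up[-2::-1])


def build_staircase_program(base: float, fold: float, n_levels: int,
                            config: DeviceConfig, stocks: StockSet, *,
                            drug: str | None = None, hold_steps: int = 1,
                            step_h: float = 1.0,
                            wells: Sequence[str] | None = None) -> Schedule:
    """Compile a fold-change staircase used to validate dynamic range.

    Plateaus ascend ``base * fold**k`` for k = 0..n_levels-1 and then
    descend symmetrically, each level held for ``hold_steps`` steps of
    ``step_h`` hours. The top level must be achievable from the stock.
    """
    if fold <= 1:
        raise InvalidParameterError(f"fold must be > 1, got {fold}")
    if n_levels < 2:
        raise InvalidParameterError(f"n_levels must be >= 2, got {n_levels}")
    if base <= 0:
        raise InvalidParameterError("base must be > 0")
    if drug is None:
        if len(stocks.drugs) != 1:
            raise InvalidParameterError("drug must be named when several stocks exist")
        drug = stocks.drugs[0]
    top = base * fold ** (n_levels - 1)
    achievable = stocks[drug] * config.refill_volume / config.working_volume
    if top > achievable * (1 + _REL_TOL):
        raise InfeasibleTargetError(
            f"top level {top:.4g} exceeds the stock-achievable maximum "
            f"{achievable:.4g}", drug=drug)
    targets = [lvl for lvl in staircase_levels(base, fold, n_levels)
               for _ in range(hold_steps)]
    profile = profile_from_steps(targets, step_h, drug=drug)
    well_ids = wells if wells is not None else config.wells()[:1]
    return compile_profile(profile, config, stocks, wells=well_ids)
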