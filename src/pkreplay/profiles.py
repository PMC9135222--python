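"""Discretization of continuous concentration curves into step profiles.

The dosing device changes well concentrations at discrete times (every 1 or
2 hours), so a continuous PK curve over one dosing cycle is approximated by
a piecewise-constant profile: the cycle is tiled with intervals and each
interval's target is the median of the curve over that interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .errors import InvalidParameterError, TilingError
from .pk import ConcentrationSeries

__all__ = [
    "IntervalTiling",
    "Step",
    "StepProfile",
    "tile_cycle",
    "discretize",
    "build_coverage_profile",
]

#: Default within-interval sampling grid for the median (h); 1 minute.
DEFAULT_SAMPLE_STEP = 1.0 / 60.0

_DIV_TOL = 1e-9


def _divisible(a: float, b: float) -> bool:
    if b <= 0:
        return False
    r = a / b
    return abs(r - round(r)) < _DIV_TOL


@dataclass(frozen=True)
class IntervalTiling:
    """Ordered interval boundaries tiling [0, cycle_length]."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2 or b[0] != 0.0:
            raise TilingError("tiling must start at 0 and contain >= 1 interval")
        if any(b[i + 1] <= b[i] for i in range(len(b) - 1)):
            raise TilingError("boundaries must be strictly increasing")

    @property
    def cycle_length(self) -> float:
        return self.boundaries[-1]

    @property
    def durations(self) -> tuple[float, ...]:
        b = self.boundaries
        return tuple(b[i + 1] - b[i] for i in range(len(b) - 1))

    def __len__(self) -> int:
        return len(self.boundaries) - 1


@dataclass(frozen=True)
class Step:
    """One interval of a step profile: start, duration (h) and target."""

    start: float
    duration: float
    target: float


@dataclass(frozen=True)
class StepProfile:
    """Piecewise-constant target concentrations tiling one dosing cycle."""

    steps: tuple[Step, ...]
    cycle_length: float
    drug: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise InvalidParameterError("profile must contain >= 1 step")
        t = 0.0
        for s in self.steps:
            if abs(s.start - t) > _DIV_TOL or s.duration <= 0:
                raise TilingError("steps must tile the cycle with no gaps or overlaps")
            if s.target < 0:
                raise InvalidParameterError("step targets must be >= 0")
            t += s.duration
        if abs(t - self.cycle_length) > _DIV_TOL:
            raise TilingError(
                f"steps cover {t} h but cycle_length is {self.cycle_length} h")

    @property
    def targets(self) -> tuple[float, ...]:
        return tuple(s.target for s in self.steps)

    @property
    def tiling(self) -> IntervalTiling:
        return IntervalTiling((0.0,) + tuple(
            np.cumsum([s.duration for s in self.steps]).tolist()))

    def step_auc(self) -> float:
        """Exposure of the profile over one cycle: sum of target*duration."""
        return sum(s.target * s.duration for s in self.steps)


def tile_cycle(cycle_length: float, fine_duration: float, fine_window: float,
               coarse_duration: float) -> IntervalTiling:
    """Tile a cycle with fine intervals early and coarse intervals after.

    Fine intervals of ``fine_duration`` cover [0, fine_window); coarse
    intervals of ``coarse_duration`` cover the remainder. The canonical
    once-daily layout — 1-h steps over the first 2 h after dosing (where
    absorption makes the curve steep) and 2-h steps over the remaining
    22 h — yields 13 intervals per 24 h.
    """
    if fine_window > cycle_length:
        raise TilingError(f"fine_window {fine_window} exceeds cycle_length {cycle_length}")
    if fine_window > 0 and not _divisible(fine_window, fine_duration):
        raise TilingError(
            f"fine_window {fine_window} not divisible by fine_duration "
            f"{fine_duration} (remainder {math.fmod(fine_window, fine_duration)})")
    rest = cycle_length - fine_window
    if rest > _DIV_TOL and not _divisible(rest, coarse_duration):
        raise TilingError(
            f"remaining window {rest} not divisible by coarse_duration "
            f"{coarse_duration} (remainder {math.fmod(rest, coarse_duration)})")
    n_fine = int(round(fine_window / fine_duration)) if fine_window > 0 else 0
    n_coarse = int(round(rest / coarse_duration)) if rest > _DIV_TOL else 0
    bounds = [i * fine_duration for i in range(n_fine + 1)]
    bounds += [fine_window + i * coarse_duration for i in range(1, n_coarse + 1)]
    if not bounds or bounds[0] != 0.0:
        bounds = [0.0] + bounds
    bounds[-1] = cycle_length
    return IntervalTiling(tuple(bounds))


Curve = Union[Callable[[np.ndarray], np.ndarray], ConcentrationSeries]


def _as_callable(curve: Curve) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(curve, ConcentrationSeries):
        return curve.interpolator()
    return curve


def discretize(curve: Curve, tiling: IntervalTiling,
               sample_step: float = DEFAULT_SAMPLE_STEP,
               drug: str = "") -> StepProfile:
    """Median-of-interval discretization of a curve onto a tiling.

    Each interval [start, end) is sampled on a uniform midpoint grid of
    spacing ``sample_step`` (cell centres of the half-open interval, so
    the right endpoint is excluded) and the step target is the median of
    those samples; midpoint placement keeps the median stable under grid
    refinement. Sampled series are evaluated by linear interpolation.
    """
    if sample_step <= 0:
        raise InvalidParameterError("sample_step must be > 0")
    if sample_step > min(tiling.durations) / 10 + _DIV_TOL:
        raise InvalidParameterError(
            f"sample_step {sample_step} too coarse for smallest interval "
            f"{min(tiling.durations)} (need <= interval/10)")
    f = _as_callable(curve)
    steps = []
    for start, dur in zip(tiling.boundaries, tiling.durations):
        n = int(math.floor(dur / sample_step + _DIV_TOL))
        if n < 1:
            raise InvalidParameterError("empty interval sample")
        grid = start + sample_step * (np.arange(n) + 0.5)
        target = float(np.median(np.asarray(f(grid), dtype=float)))
        steps.append(Step(start, dur, max(target, 0.0)))
    return StepProfile(tuple(steps), tiling.cycle_length, drug=drug)


def build_coverage_profile(level: float, hold_h: float, cycle_length: float,
                           step_h: float, drug: str = "") -> StepProfile:
    """A hold-then-washout profile: ``level`` for ``hold_h`` hours, then 0.

    Used for target-coverage programs holding a fixed concentration (e.g.
    an IC50 or IC90) for part of each day and washing out for the rest.
    """
    if not (0 < hold_h <= cycle_length):
        raise InvalidParameterError(f"need 0 < hold_h <= cycle_length, got {hold_h}")
    if level < 0:
        raise InvalidParameterError("level must be >= 0")
    for name, dur in (("hold_h", hold_h), ("cycle_length", cycle_length)):
        if not _divisible(dur, step_h):
            raise TilingError(f"{name} {dur} not divisible by step_h {step_h} "
                              f"(remainder {math.fmod(dur, step_h)})")
    n = int(round(cycle_length / step_h))
    n_hold = int(round(hold_h / step_h))
    steps = tuple(Step(i * step_h, step_h, level if i < n_hold else 0.0)
                  for i in range(n))
    return StepProfile(steps, cycle_length, drug=drug)


def profile_from_steps(targets: Sequence[float], step_h: float,
                       drug: str = "") -> StepProfile:
    """Uniform-duration profile from an explicit target sequence."""
    steps = tuple(Step(i * step_h, step_h, float(t)) for i, t in enumerate(targets))
    return StepProfile(steps, step_h * len(targets), drug=drug)
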