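"""One-compartment, first-order absorption pharmacokinetic model.

The concentration after a single oral dose ``D`` is the Bateman function

    C(t) = D * s * ka/(ka - ke) * (exp(-ke*t) - exp(-ka*t)),   t >= 0,

where ``ka`` and ``ke`` are the absorption and elimination rate constants
(1/h) and ``s = F/V`` is the dose-normalised concentration scale combining
bioavailability F and apparent volume of distribution V (the two are not
separately identifiable from concentration data and are never separated
here). Repeated dosing is handled by linear superposition of Bateman terms,
one per elapsed dose event.

Parameters are estimated from pooled concentration-time data across dose
levels by nonlinear least squares, assuming dose-proportional exposure by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "PKParameters",
    "DoseEvent",
    "DosingRegimen",
    "ConcentrationSeries",
    "FitResult",
    "concentration_single_dose",
    "concentration_regimen",
    "sample_regimen",
    "fit_pk",
]

#: Relative |ka - ke| threshold below which the ka == ke analytic limit is
#: used (removable singularity; avoids catastrophic cancellation).
KA_KE_EPSILON = 1e-9


def _require_finite_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class PKParameters:
    """Rate constants and scale of the one-compartment oral model.

    Attributes
    ----------
    ka : float
        First-order absorption rate constant (1/h).
    ke : float
        First-order elimination rate constant (1/h).
    scale : float
        Dose-normalised concentration scale F/V (concentration units per
        dose unit).
    """

    ka: float
    ke: float
    scale: float

    def __post_init__(self) -> None:
        _require_finite_positive("ka", self.ka)
        _require_finite_positive("ke", self.ke)
        _require_finite_positive("scale", self.scale)

    def swapped(self) -> "PKParameters":
        """The equivalent parameter set with ka and ke exchanged.

        The Bateman curve is invariant under (ka, ke, s) ->
        (ke, ka, s*ka/ke); this returns that exchanged set.
        """
        return PKParameters(ka=self.ke, ke=self.ka,
                            scale=self.scale * self.ka / self.ke)

    @property
    def tmax(self) -> float:
        """Time of peak concentration after a single dose (h)."""
        if abs(self.ka - self.ke) < KA_KE_EPSILON * self.ka:
            return 1.0 / self.ka
        return math.log(self.ka / self.ke) / (self.ka - self.ke)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: offset from cycle start (h) and amount."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time >= 0):
            raise InvalidParameterError(f"dose time must be >= 0, got {self.time!r}")
        if not (math.isfinite(self.amount) and self.amount >= 0):
            raise InvalidParameterError(f"dose amount must be >= 0, got {self.amount!r}")


@dataclass(frozen=True)
class DosingRegimen:
    """Dose events composing one repeating cycle.

    QD is a single event at 0 h; BID here means events at 0 h and 8 h
    (morning and evening doses 8 h apart, then 16 h to the next morning).
    """

    events: tuple[DoseEvent, ...]
    cycle_length: float = 24.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.n_cycles < 1:
            raise InvalidParameterError(f"n_cycles must be >= 1, got {self.n_cycles}")
        _require_finite_positive("cycle_length", self.cycle_length)
        times = [e.time for e in self.events]
        if any(t >= self.cycle_length for t in times):
            raise InvalidParameterError("all event times must be < cycle_length")
        if times != sorted(times):
            raise InvalidParameterError("events must be sorted by time")

    @classmethod
    def qd(cls, amount: float, cycle_length: float = 24.0,
           n_cycles: int = 1) -> "DosingRegimen":
        return cls((DoseEvent(0.0, amount),), cycle_length, n_cycles)

    @classmethod
    def bid(cls, amount: float, spacing: float = 8.0, cycle_length: float = 24.0,
            n_cycles: int = 1) -> "DosingRegimen":
        return cls((DoseEvent(0.0, amount), DoseEvent(spacing, amount)),
                   cycle_length, n_cycles)

    @property
    def total_duration(self) -> float:
        return self.cycle_length * self.n_cycles

    def dose_times_amounts(self) -> tuple[np.ndarray, np.ndarray]:
        """Absolute times and amounts of every dose across all cycles."""
        times = np.array([c * self.cycle_length + e.time
                          for c in range(self.n_cycles) for e in self.events])
        amounts = np.array([e.amount
                            for _ in range(self.n_cycles) for e in self.events])
        return times, amounts

    def scaled(self, factor: float) -> "DosingRegimen":
        return replace(self, events=tuple(DoseEvent(e.time, e.amount * factor)
                                          for e in self.events))


@dataclass
class SeriesMeta:
    """Labels carried with a concentration series through I/O."""

    drug: str = ""
    dose: float = float("nan")
    unit: str = ""
    series_id: str = ""


@dataclass
class ConcentrationSeries:
    """An ordered concentration-time record C(t)."""

    times: np.ndarray
    concentrations: np.ndarray
    meta: SeriesMeta = field(default_factory=SeriesMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise InvalidParameterError("times and concentrations must be equal-length 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise InvalidParameterError("concentrations must be >= 0")

    def __len__(self) -> int:
        return self.times.size

    def interpolator(self) -> Callable[[np.ndarray], np.ndarray]:
        """Piecewise-linear interpolant over the series span."""
        return lambda t: np.interp(t, self.times, self.concentrations)


def concentration_single_dose(params: PKParameters, dose: float,
                              t: float | np.ndarray) -> float | np.ndarray:
    """Bateman concentration at time(s) ``t`` hours after a single dose.

    ``t < 0`` returns 0 (dose not yet given). For ``ka`` within
    ``KA_KE_EPSILON`` of ``ke`` the analytic limit
    ``dose*scale*ka*t*exp(-ka*t)`` is used.
    """
    if not (math.isfinite(dose) and dose >= 0):
        raise InvalidParameterError(f"dose must be finite and >= 0, got {dose!r}")
    ka, ke, s = params.ka, params.ke, params.scale
    tt = np.asarray(t, dtype=float)
    pos = np.clip(tt, 0.0, None)
    if abs(ka - ke) < KA_KE_EPSILON * ka:
        c = dose * s * ka * pos * np.exp(-ka * pos)
    else:
        c = dose * s * ka / (ka - ke) * (np.exp(-ke * pos) - np.exp(-ka * pos))
    c = np.where(tt < 0, 0.0, np.clip(c, 0.0, None))
    return float(c) if np.isscalar(t) or np.ndim(t) == 0 else c


def concentration_regimen(params: PKParameters, regimen: DosingRegimen,
                          t: float | np.ndarray) -> float | np.ndarray:
    """Superposed concentration for a multi-dose regimen at time(s) ``t``.

    Linear superposition: one Bateman term per dose event already given
    (event time <= t), across all elapsed cycles.
    """
    dose_times, amounts = regimen.dose_times_amounts()
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros_like(tt)
    unit = PKParameters(params.ka, params.ke, params.scale)
    for t0, amt in zip(dose_times, amounts):
        if amt == 0:
            continue
        total += concentration_single_dose(unit, amt, tt - t0)
    return float(total[0]) if np.ndim(t) == 0 else total


def sample_regimen(params: PKParameters, regimen: DosingRegimen,
                   grid_step: float) -> ConcentrationSeries:
    """Evaluate a regimen on a regular grid from 0 to the regimen end."""
    _require_finite_positive("grid_step", grid_step)
    total = regimen.total_duration
    n = int(math.floor(total / grid_step + 1e-9))
    times = grid_step * np.arange(n + 1)
    conc = concentration_regimen(params, regimen, times)
    return ConcentrationSeries(times, np.atleast_1d(conc))


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitResult:
    """Outcome of a PK fit: estimates, residual norm and diagnostics."""

    params: PKParameters
    rss: float
    converged: bool
    n_points: int
    n_starts: int
    series_scales: tuple[float, ...] | None = None


def _initial_guesses(times: np.ndarray, norm_conc: np.ndarray) -> list[tuple[float, float, float]]:
    """Method-of-moments start plus a deterministic multi-start grid.

    ke from the terminal slope of log-concentration (last half of the
    positive observations), ka a multiple of ke, scale matched to Cmax.
    """
    pos = norm_conc > 0
    ke0 = 0.1
    if pos.sum() >= 3:
        t_pos, c_pos = times[pos], norm_conc[pos]
        order = np.argsort(t_pos)
        t_tail = t_pos[order][len(order) // 2:]
        c_tail = c_pos[order][len(order) // 2:]
        if len(t_tail) >= 2 and np.ptp(t_tail) > 0:
            slope = np.polyfit(t_tail, np.log(c_tail), 1)[0]
            if slope < 0:
                ke0 = -slope
    cmax = float(norm_conc.max()) if norm_conc.size else 1.0
    guesses = []
    for ka_mult in (5.0, 2.0, 10.0, 1.2):
        for ke in (ke0, 2 * ke0, 0.5 * ke0):
            ka = ka_mult * ke
            peak = concentration_single_dose(PKParameters(ka, ke, 1.0), 1.0,
                                             math.log(ka / ke) / (ka - ke))
            scale = cmax / peak if peak > 0 else 1.0
            guesses.append((ka, ke, scale))
    return guesses


def fit_pk(datasets: Sequence[ConcentrationSeries], *,
           log_scale: bool = False,
           per_series_scale: bool = False,
           xtol: float = 1e-14) -> FitResult:
    """Fit (ka, ke, scale) jointly to one or more dose-annotated series.

    Exposure is assumed dose-proportional: predictions for a series with
    dose D are ``D * C_unit(t)``. With ``per_series_scale=True`` each series
    additionally gets its own free scale multiplier (relaxes strict dose
    proportionality); the reported ``scale`` is then the shared component
    and ``series_scales`` the per-series multipliers.

    Parameters are optimised in log space (positivity by construction) with
    a deterministic multi-start around a method-of-moments initialiser; the
    best start by residual sum of squares wins. The returned parameters are
    canonicalised to ka >= ke via the exchange symmetry of the Bateman
    curve.

    ``log_scale=True`` fits residuals on log(concentration) instead of the
    linear scale (positive observations only).
    """
    if not datasets:
        raise InsufficientDataError("no datasets given")
    times_l, conc_l, dose_l, sid_l = [], [], [], []
    for i, s in enumerate(datasets):
        d = s.meta.dose
        if not (math.isfinite(d) and d > 0):
            raise InvalidParameterError(
                f"series {s.meta.series_id or i} lacks a positive dose annotation")
        times_l.append(s.times)
        conc_l.append(s.concentrations)
        dose_l.append(np.full(len(s), d))
        sid_l.append(np.full(len(s), i))
    times = np.concatenate(times_l)
    conc = np.concatenate(conc_l)
    doses = np.concatenate(dose_l)
    sids = np.concatenate(sid_l)
    if np.unique(times).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct time points, got {np.unique(times).size}")

    n_series = len(datasets)
    norm = conc / doses

    if log_scale:
        mask = conc > 0
        if mask.sum() < 3:
            raise InsufficientDataError("log-scale fit needs >= 3 positive observations")
    else:
        mask = np.ones_like(conc, dtype=bool)
    tm, cm, dm, sm = times[mask], conc[mask], doses[mask], sids[mask]

    def residuals(theta: np.ndarray) -> np.ndarray:
        ka, ke, scale = np.exp(theta[:3])
        if per_series_scale:
            # first series pinned to 1: a free multiplier on every series
            # would be collinear with the shared scale
            extra = np.concatenate([[1.0], np.exp(theta[3:])])
        else:
            extra = None
        p = PKParameters(ka, ke, scale)
        pred = dm * np.asarray(concentration_single_dose(p, 1.0, tm))
        if extra is not None:
            pred = pred * extra[sm]
        if log_scale:
            return np.log(np.maximum(pred, 1e-300)) - np.log(cm)
        return pred - cm

    best = None
    starts = _initial_guesses(times, norm)
    for ka0, ke0, s0 in starts:
        theta0 = np.log([ka0, ke0, s0])
        if per_series_scale:
            theta0 = np.concatenate([theta0, np.zeros(n_series - 1)])
        try:
            res = least_squares(residuals, theta0, method="lm",
                                xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=2000)
        except Exception:
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise InvalidParameterError("all fit starts failed")
    rss, res = best
    ka, ke, scale = np.exp(res.x[:3])
    params = PKParameters(float(ka), float(ke), float(scale))
    if params.ka < params.ke:  # canonical orientation: absorption faster
        params = params.swapped()
    series_scales = ((1.0,) + tuple(np.exp(res.x[3:]))) if per_series_scale else None
    return FitResult(params=params, rss=rss, converged=bool(res.status > 0),
                     n_points=int(mask.sum()), n_starts=len(starts),
                     series_scales=series_scales)
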