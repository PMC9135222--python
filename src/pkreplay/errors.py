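"""Exception hierarchy.

Every error raised by the library derives from :class:`PKReplayError`, so
callers (and the CLI) can catch one base class. Errors carry enough context
to name the offending quantity.
"""

from __future__ import annotations


class PKReplayError(Exception):
    """Base class for all pkreplay errors."""


class InvalidParameterError(PKReplayError, ValueError):
    """A model or device parameter violates its invariant."""


class InsufficientDataError(PKReplayError, ValueError):
    """Too few observations to attempt a fit (< 3 distinct time points)."""


class TilingError(PKReplayError, ValueError):
    """Interval durations do not tile the cycle exactly."""


class InfeasibleTargetError(PKReplayError, ValueError):
    """A target concentration cannot be reached with the configured stock.

    ``drug`` names the limiting compound.
    """

    def __init__(self, message: str, drug: str | None = None):
        super().__init__(message)
        self.drug = drug


class QuantizationError(PKReplayError, ValueError):
    """A required dispense volume falls below the device minimum.

    ``suggested_target`` is the nearest achievable target concentration.
    """

    def __init__(self, message: str, drug: str | None = None,
                 suggested_target: float | None = None):
        super().__init__(message)
        self.drug = drug
        self.suggested_target = suggested_target


class SchedulingError(PKReplayError, ValueError):
    """The pump time budget of a step is exceeded.

    ``required_min`` / ``available_min`` report the violation in minutes.
    """

    def __init__(self, message: str, required_min: float | None = None,
                 available_min: float | None = None):
        super().__init__(message)
        self.required_min = required_min
        self.available_min = available_min


class ValidationError(PKReplayError, ValueError):
    """A schedule or trace is internally inconsistent."""


class FormatError(PKReplayError, ValueError):
    """A file is malformed (missing columns, bad header, wrong types)."""


class SchemaError(FormatError):
    """A JSON document declares an unknown schema version."""


class UnitMismatchError(PKReplayError, ValueError):
    """Two labelled quantities with different units were combined."""
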