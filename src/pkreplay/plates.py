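"""Microtiter plate layouts addressable by one 25-port valve (24 wells)."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["PlateLayout", "LAYOUTS"]


def _grid(rows: str, cols: range) -> tuple[str, ...]:
    return tuple(f"{r}{c}" for r in rows for c in cols)


@dataclass(frozen=True)
class PlateLayout:
    """Named plate layout exposing the wells one valve unit can address."""

    name: str
    wells: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.wells) > 24:
            raise InvalidParameterError(
                f"layout {self.name!r} exposes {len(self.wells)} wells; one "
                "25-port valve addresses at most 24 (plus a flush port)")

    @property
    def n_wells(self) -> int:
        return len(self.wells)


#: A full 24-well plate (rows A-D x columns 1-6), and one quadrant of a
#: 96-well plate (alternate rows/columns, 24 wells).
LAYOUTS: dict[str, PlateLayout] = {
    "24-well": PlateLayout("24-well", _grid("ABCD", range(1, 7))),
    "96-well-quadrant": PlateLayout(
        "96-well-quadrant",
        tuple(f"{r}{c}" for r in "ACEG" for c in range(1, 13, 2))),
}


def get_layout(name: str) -> PlateLayout:
    try:
        return LAYOUTS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown plate layout {name!r}; known: {sorted(LAYOUTS)}") from None
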