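"""File formats: concentration CSV, profile/schedule JSON, trace CSV, config.

All interfaces use hours for time and microlitres for volume; unit labels
are carried through but never converted. JSON documents carry a versioned
``schema`` field; unknown versions are rejected, unknown extra keys are
accepted with a logged warning (forward compatibility).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .compiler import (DeviceConfig, Schedule, StepOperation, StockSet,
                       WellSchedule)
from .errors import FormatError, SchemaError, UnitMismatchError
from .pk import ConcentrationSeries, DoseEvent, DosingRegimen, PKParameters, SeriesMeta
from .profiles import Step, StepProfile
from .twin import SimulationTrace

logger = logging.getLogger(__name__)

PROFILE_SCHEMA = "pkreplay/step-profile/1"
SCHEDULE_SCHEMA = "pkreplay/schedule/1"

SERIES_COLUMNS = ["time_h", "conc", "dose", "series_id", "unit"]

__all__ = [
    "read_series_csv", "write_series_csv",
    "read_profile_json", "write_profile_json",
    "read_schedule_json", "write_schedule_json",
    "write_trace_csv", "read_trace_csv",
    "read_params_json", "write_params_json",
    "ExperimentConfig", "load_experiment_config",
]


# ---------------------------------------------------------------------------
# Concentration series CSV


def write_series_csv(path: str | Path,
                     series: ConcentrationSeries | Sequence[ConcentrationSeries]) -> None:
    if isinstance(series, ConcentrationSeries):
        series = [series]
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "time_h": s.times, "conc": s.concentrations,
            "dose": s.meta.dose, "series_id": s.meta.series_id or "s0",
            "unit": s.meta.unit, "drug": s.meta.drug}))
    # repr keeps the shortest exact decimal so reading back is bit-exact
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))


def read_series_csv(path: str | Path) -> list[ConcentrationSeries]:
    """Read one series per ``series_id``; header with named columns required."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = []
    for sid, grp in df.groupby("series_id", sort=False):
        units = set(grp["unit"].astype(str))
        if len(units) > 1:
            raise UnitMismatchError(
                f"{path}: series {sid!r} mixes units {sorted(units)}")
        grp = grp.sort_values("time_h")
        doses = set(grp["dose"])
        drug = str(grp["drug"].iloc[0]) if "drug" in grp.columns else ""
        meta = SeriesMeta(drug=drug, dose=float(grp["dose"].iloc[0]),
                          unit=units.pop(), series_id=str(sid))
        if len(doses) > 1:
            raise FormatError(f"{path}: series {sid!r} mixes dose annotations")
        out.append(ConcentrationSeries(grp["time_h"].to_numpy(float),
                                       grp["conc"].to_numpy(float), meta))
    if not out:
        raise FormatError(f"{path}: no data rows")
    return out


# ---------------------------------------------------------------------------
# JSON documents


def _check_schema(doc: Mapping[str, Any], expected: str, path: Any) -> None:
    schema = doc.get("schema")
    if schema != expected:
        raise SchemaError(f"{path}: schema {schema!r}, expected {expected!r}")
    known_warned = doc.keys() - _KNOWN_KEYS.get(expected, set())
    if known_warned:
        logger.warning("%s: ignoring unknown key(s) %s", path, sorted(known_warned))


_KNOWN_KEYS = {
    PROFILE_SCHEMA: {"schema", "drug", "cycle_length_h", "steps"},
    SCHEDULE_SCHEMA: {"schema", "device", "stocks", "cycle_length_h",
                      "n_cycles", "wells"},
}


def write_profile_json(path: str | Path, profile: StepProfile) -> None:
    doc = {"schema": PROFILE_SCHEMA, "drug": profile.drug,
           "cycle_length_h": profile.cycle_length,
           "steps": [{"start_h": s.start, "duration_h": s.duration,
                      "target": s.target} for s in profile.steps]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_profile_json(path: str | Path) -> StepProfile:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    _check_schema(doc, PROFILE_SCHEMA, path)
    try:
        steps = tuple(Step(s["start_h"], s["duration_h"], s["target"])
                      for s in doc["steps"])
        return StepProfile(steps, doc["cycle_length_h"], drug=doc.get("drug", ""))
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc}") from exc


def write_schedule_json(path: str | Path, schedule: Schedule) -> None:
    doc = {
        "schema": SCHEDULE_SCHEMA,
        "device": asdict(schedule.device),
        "stocks": dict(schedule.stocks.concentrations),
        "cycle_length_h": schedule.cycle_length,
        "n_cycles": schedule.n_cycles,
        "wells": [{
            "well_id": ws.well_id,
            "steps": [{"start_h": op.start, "duration_h": op.duration,
                       "washouts": op.n_washouts, "blank_uL": op.blank_volume,
                       "drugs": [{"name": d, "volume_uL": v}
                                 for d, v in op.drug_volumes.items()],
                       "targets": dict(op.targets),
                       "achieved": dict(op.achieved)}
                      for op in ws.steps]} for ws in schedule.wells],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_schedule_json(path: str | Path) -> Schedule:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    _check_schema(doc, SCHEDULE_SCHEMA, path)
    try:
        device = DeviceConfig(**doc["device"])
        stocks = StockSet(doc["stocks"])
        wells = []
        for w in doc["wells"]:
            steps = tuple(StepOperation(
                start=s["start_h"], duration=s["duration_h"],
                n_washouts=s["washouts"], blank_volume=s["blank_uL"],
                drug_volumes={d["name"]: d["volume_uL"] for d in s["drugs"]},
                targets=dict(s.get("targets", {})),
                achieved=dict(s.get("achieved", {}))) for s in w["steps"])
            wells.append(WellSchedule(well_id=w["well_id"], steps=steps))
        return Schedule(device=device, stocks=stocks,
                        cycle_length=doc["cycle_length_h"],
                        n_cycles=doc["n_cycles"], wells=tuple(wells))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed schedule: {exc}") from exc


def write_params_json(path: str | Path, params: PKParameters,
                      extra: Mapping[str, Any] | None = None) -> None:
    doc = {"ka_per_h": params.ka, "ke_per_h": params.ke, "scale": params.scale}
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=1))


def read_params_json(path: str | Path) -> PKParameters:
    doc = json.loads(Path(path).read_text())
    try:
        return PKParameters(doc["ka_per_h"], doc["ke_per_h"], doc["scale"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc}") from exc


# ---------------------------------------------------------------------------
# Trace CSV


def write_trace_csv(path: str | Path, trace: SimulationTrace) -> None:
    rows = []
    for well_id, per_drug in trace.series.items():
        for drug, s in per_drug.items():
            for t, c in zip(s.times, s.concentrations):
                rows.append((well_id, drug, t, c))
    pd.DataFrame(rows, columns=["well_id", "drug", "time_h", "conc"]).to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))


def read_trace_csv(path: str | Path) -> dict[str, dict[str, ConcentrationSeries]]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("well_id", "drug", "time_h", "conc") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out: dict[str, dict[str, ConcentrationSeries]] = {}
    for (well, drug), grp in df.groupby(["well_id", "drug"], sort=False):
        grp = grp.sort_values("time_h")
        out.setdefault(str(well), {})[str(drug)] = ConcentrationSeries(
            grp["time_h"].to_numpy(float), grp["conc"].to_numpy(float),
            SeriesMeta(drug=str(drug), series_id=str(well)))
    return out


# ---------------------------------------------------------------------------
# Experiment configuration (YAML)


@dataclass
class ExperimentConfig:
    """Parsed experiment configuration tying the pipeline together."""

    device: DeviceConfig
    stocks: StockSet
    regimens: dict[str, DosingRegimen] = field(default_factory=dict)
    params: dict[str, PKParameters] = field(default_factory=dict)
    tiling: dict[str, float] = field(default_factory=lambda: {
        "fine_duration": 1.0, "fine_window": 2.0, "coarse_duration": 2.0})
    seed: int | None = None


def _regimen_from_dict(d: Mapping[str, Any]) -> DosingRegimen:
    if "schedule" in d:
        sched = str(d["schedule"]).upper()
        kw = dict(cycle_length=float(d.get("cycle_length_h", 24.0)),
                  n_cycles=int(d.get("n_cycles", 1)))
        if sched == "QD":
            return DosingRegimen.qd(float(d["dose"]), **kw)
        if sched == "BID":
            return DosingRegimen.bid(float(d["dose"]),
                                     spacing=float(d.get("spacing_h", 8.0)), **kw)
        raise FormatError(f"unknown schedule {d['schedule']!r} (use QD or BID)")
    events = tuple(DoseEvent(float(e["time_h"]), float(e["amount"]))
                   for e in d["events"])
    return DosingRegimen(events, float(d.get("cycle_length_h", 24.0)),
                         int(d.get("n_cycles", 1)))


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: config must be a mapping")
    try:
        device = DeviceConfig(**(doc.get("device") or {}))
        stocks = StockSet(doc.get("stocks") or {})
        regimens = {name: _regimen_from_dict(r)
                    for name, r in (doc.get("regimens") or {}).items()}
        params = {name: PKParameters(p["ka_per_h"], p["ke_per_h"], p["scale"])
                  for name, p in (doc.get("params") or {}).items()}
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: bad config key: {exc}") from exc
    cfg = ExperimentConfig(device=device, stocks=stocks, regimens=regimens,
                           params=params, seed=doc.get("seed"))
    if "tiling" in doc:
        cfg.tiling.update({k: float(v) for k, v in doc["tiling"].items()})
    for name in regimens:
        if stocks.drugs and name not in stocks.drugs:
            raise FormatError(
                f"{path}: regimen {name!r} has no matching stock entry "
                f"(stocks: {sorted(stocks.drugs)})")
    return cfg
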