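"""Stable file schemas: session CSV, schedule CSV, TOML configuration.

All files are RFC-4180 CSV, UTF-8, header row, fixed column order, empty
fields for missing values, reals formatted to 6 significant digits.  A file
the package writes can always be read back losslessly, and a re-write of a
read file is byte-identical.
"""

from __future__ import annotations

import csv
import dataclasses
import tomllib
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError
from .synthetic import SimulationConfig
from .types import (MODALITIES, SESSION_COLUMN_KINDS, SESSION_COLUMNS,
                    SessionData, StimParams, Trial,
                    descriptor_matches_modality)

__all__ = ["read_sessions", "write_sessions", "write_schedule",
           "read_schedule", "load_config", "SCHEDULE_COLUMNS"]

SCHEDULE_COLUMNS = (
    "experiment", "session_day", "block", "trial_index", "electrode_id",
    "amplitude_uA", "frequency_hz", "pulse_width_us", "interphase_us",
    "duration_s", "is_catch",
)


def _fmt(value, kind: str) -> str:
    if value is None or (isinstance(value, float) and value != value) or \
            value is pd.NA or value is pd.NaT:
        return ""
    if kind == "bool":
        return "1" if bool(value) else "0"
    if kind == "int":
        return str(int(value))
    if kind == "float":
        return format(float(value), ".6g")
    return str(value)


def _parse(text: str, kind: str):
    if text == "":
        return None
    if kind == "bool":
        return text == "1"
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    return text


# ---------------------------------------------------------------------------
# Session CSV
# ---------------------------------------------------------------------------


def write_sessions(data: SessionData, path) -> None:
    """Write session data with deterministic column order and formatting."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(SESSION_COLUMNS)
        for row in data.table.itertuples(index=False):
            w.writerow(_fmt(v, SESSION_COLUMN_KINDS[c])
                       for c, v in zip(SESSION_COLUMNS, row))


def validate_session_frame(df: pd.DataFrame) -> List[str]:
    """Row-level invariant checks; returns human-readable violation messages
    (row numbers are 0-based positions in the frame)."""
    problems: List[str] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        detected = bool(r["detected"]) if not pd.isna(r["detected"]) else False
        if bool(r["is_catch"]) and detected:
            problems.append(f"row {pos}: catch trial marked detected")
        if detected:
            if pd.isna(r["modality"]) or r["modality"] not in MODALITIES:
                problems.append(f"row {pos}: detected without valid modality")
            elif not pd.isna(r["descriptor"]) and not descriptor_matches_modality(
                    str(r["descriptor"]), str(r["modality"])):
                problems.append(
                    f"row {pos}: descriptor {r['descriptor']!r} inconsistent "
                    f"with modality {r['modality']!r}")
            if not pd.isna(r["intensity"]) and not 1 <= int(r["intensity"]) <= 10:
                problems.append(f"row {pos}: intensity outside 1..10")
        else:
            for col in ("modality", "descriptor", "intensity",
                        "duration_category", "region", "plane"):
                if not pd.isna(r[col]):
                    problems.append(
                        f"row {pos}: undetected trial carries {col}")
                    break
    return problems


def read_sessions(path, validate: bool = True) -> SessionData:
    """Read a session CSV, enforcing the schema and row-level invariants."""
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if tuple(header) != SESSION_COLUMNS:
            missing = set(SESSION_COLUMNS) - set(header)
            raise SchemaError(
                f"{path}: header mismatch; missing columns {sorted(missing)}"
                if missing else f"{path}: column order mismatch")
        records = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(SESSION_COLUMNS):
                raise SchemaError(f"{path}:{lineno}: wrong field count")
            records.append({c: _parse(v, SESSION_COLUMN_KINDS[c])
                            for c, v in zip(SESSION_COLUMNS, row)})
    df = pd.DataFrame(records, columns=SESSION_COLUMNS) if records else \
        pd.DataFrame(columns=SESSION_COLUMNS)
    data = SessionData(df)
    if validate and records:
        problems = validate_session_frame(data.table)
        if problems:
            raise ValidationError(
                f"{path}: {len(problems)} invariant violations: "
                + "; ".join(problems[:10]), rows=problems)
    return data


# ---------------------------------------------------------------------------
# Schedule CSV
# ---------------------------------------------------------------------------


def write_schedule(trials: Sequence[Trial], path) -> None:
    path = Path(path)
    kinds = {"experiment": "str", "session_day": "int", "block": "int",
             "trial_index": "int", "electrode_id": "int",
             "amplitude_uA": "float", "frequency_hz": "float",
             "pulse_width_us": "float", "interphase_us": "float",
             "duration_s": "float", "is_catch": "bool"}
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(SCHEDULE_COLUMNS)
        for t in trials:
            vals = {
                "experiment": t.experiment, "session_day": t.session_day,
                "block": t.block, "trial_index": t.order_index,
                "electrode_id": t.electrode_id,
                "amplitude_uA": t.stim.amplitude_uA if t.stim else None,
                "frequency_hz": t.stim.frequency_hz if t.stim else None,
                "pulse_width_us": t.stim.pulse_width_us if t.stim else None,
                "interphase_us": t.stim.interphase_us if t.stim else None,
                "duration_s": t.stim.train_duration_s if t.stim else None,
                "is_catch": t.is_catch,
            }
            w.writerow(_fmt(vals[c], kinds[c]) for c in SCHEDULE_COLUMNS)


def read_schedule(path) -> List[Trial]:
    path = Path(path)
    kinds = {"experiment": "str", "session_day": "int", "block": "int",
             "trial_index": "int", "electrode_id": "int",
             "amplitude_uA": "float", "frequency_hz": "float",
             "pulse_width_us": "float", "interphase_us": "float",
             "duration_s": "float", "is_catch": "bool"}
    trials: List[Trial] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != SCHEDULE_COLUMNS:
            raise SchemaError(f"{path}: schedule header mismatch")
        for row in reader:
            r = {c: _parse(v, kinds[c]) for c, v in zip(SCHEDULE_COLUMNS, row)}
            stim = None
            if r["amplitude_uA"] is not None:
                stim = StimParams(
                    amplitude_uA=r["amplitude_uA"],
                    frequency_hz=r["frequency_hz"],
                    pulse_width_us=r["pulse_width_us"],
                    interphase_us=r["interphase_us"],
                    train_duration_s=r["duration_s"])
            trials.append(Trial(
                experiment=r["experiment"], session_day=r["session_day"],
                block=r["block"], order_index=r["trial_index"],
                electrode_id=r["electrode_id"], stim=stim,
                is_catch=bool(r["is_catch"])))
    return trials


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path=None, seed: Optional[int] = None) -> SimulationConfig:
    """Load a SimulationConfig from a TOML file ([simulation] section keys
    map to SimulationConfig fields); *seed* overrides the file's seed."""
    cfg = SimulationConfig()
    if path is not None:
        with Path(path).open("rb") as fh:
            doc = tomllib.load(fh)
        section = doc.get("simulation", doc)
        valid = {f.name for f in dataclasses.fields(SimulationConfig)}
        for key, value in section.items():
            if key not in valid:
                from .errors import ConfigurationError
                raise ConfigurationError(f"unknown configuration key {key!r}")
            if key == "duration_weights":
                value = tuple(value)
            setattr(cfg, key, value)
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    return cfg
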