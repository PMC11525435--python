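"""File formats: event-log CSV, trigger CSV, analog traces (WAV or CSV),
and YAML/JSON plan, corruption and simulation configs.

Event log: CSV with header ``event_index,onset_s,planned_onset_s,
planned_duration_s,<factor columns>,event_class`` (and ``response_key``
for uncontrolled rows).  Trigger stream: CSV ``timestamp_s,code``.  Analog
traces: WAV (PCM or float; rate from header) or two-column CSV
``time_s,value``.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .core import AnalogTrace, EventLog, PulseSequence
from .fixtures import CorruptionSpec, ExperimentPlan

__all__ = [
    "read_event_log",
    "write_event_log",
    "read_triggers",
    "write_triggers",
    "read_trace",
    "write_trace",
    "load_plan",
    "save_plan",
    "load_corruption",
    "save_corruption",
]


def read_event_log(path: str | Path) -> EventLog:
    return EventLog.from_csv(path)


def write_event_log(log: EventLog, path: str | Path) -> None:
    log.to_csv(path)


def read_triggers(path: str | Path) -> PulseSequence:
    """Read a trigger stream CSV into a pulse sequence (codes preserved as
    an attribute on the returned object is not needed; use
    :func:`read_trigger_table` for the raw table)."""
    df = read_trigger_table(path)
    return PulseSequence(df["timestamp_s"].to_numpy(float), source="trigger")


def read_trigger_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("timestamp_s", "code"):
        if col not in df.columns:
            raise ValueError(f"trigger stream is missing column {col!r}")
    return df


def write_triggers(triggers: pd.DataFrame, path: str | Path) -> None:
    triggers.to_csv(path, index=False)


def read_trace(path: str | Path, fs: float | None = None) -> AnalogTrace:
    """Read an analog trace from WAV (rate from header) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        return AnalogTrace.from_wav(path)
    return AnalogTrace.from_csv(path)


def write_trace(trace: AnalogTrace, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        trace.to_wav(path)
    else:
        trace.to_csv(path)


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _save_structured(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_plan(path: str | Path) -> ExperimentPlan:
    d = _load_structured(path)
    if "response_plan" in d and d["response_plan"] is not None:
        d["response_plan"] = [tuple(x) for x in d["response_plan"]]
    return ExperimentPlan(**d)


def save_plan(plan: ExperimentPlan, path: str | Path) -> None:
    d = asdict(plan)
    if d.get("response_plan"):
        d["response_plan"] = [list(x) for x in d["response_plan"]]
    _save_structured(d, path)


def load_corruption(path: str | Path) -> CorruptionSpec:
    return CorruptionSpec(**_load_structured(path))


def save_corruption(spec: CorruptionSpec, path: str | Path) -> None:
    _save_structured(asdict(spec), path)
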