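"""Shared containers for event-based experiment QA.

All times are seconds (floats) internally; reports convert to milliseconds
at rendering time only. Analog signals are uniformly sampled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalogTrace",
    "PulseSequence",
    "EventLog",
    "DeltaSeries",
    "RESERVED_LOG_COLUMNS",
]

#: log-file columns that are not condition factors
RESERVED_LOG_COLUMNS = (
    "event_index",
    "onset_s",
    "planned_onset_s",
    "planned_duration_s",
    "event_class",
    "response_key",
)


@dataclass
class AnalogTrace:
    """A uniformly sampled physical signal (photodiode luminance, audio).

    Parameters
    ----------
    samples : array of float
        Signal values in arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time of every sample in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnalogTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("need at least two samples to infer sampling rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time column is not uniformly sampled")
        return cls(df["value"].to_numpy(float), fs=1.0 / dt[0], start_time=t[0])

    def to_wav(self, path: str | Path) -> None:
        from scipy.io import wavfile

        wavfile.write(path, int(round(self.fs)), self.samples.astype(np.float32))

    @classmethod
    def from_wav(cls, path: str | Path, start_time: float = 0.0) -> "AnalogTrace":
        from scipy.io import wavfile

        fs, data = wavfile.read(path)
        if data.ndim > 1:  # keep first channel of multichannel recordings
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(np.asarray(data, dtype=float), fs=float(fs), start_time=start_time)


@dataclass
class PulseSequence:
    """Physical event times extracted from a stream, in seconds.

    ``onsets`` are strictly increasing.  ``offsets`` are optional; when
    present, each offset follows the onset of the same index.  The lengths
    may differ by one when a recording ends mid-pulse.
    """

    onsets: np.ndarray
    offsets: np.ndarray | None = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if self.offsets is not None:
            self.offsets = np.asarray(self.offsets, dtype=float)
            if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) > 0):
                raise ValueError("offsets must be strictly increasing")
            k = min(len(self.onsets), len(self.offsets))
            if k and not np.all(self.offsets[:k] > self.onsets[:k]):
                raise ValueError("each offset must follow its onset")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def durations(self) -> np.ndarray:
        """Offset minus onset per event; requires offsets."""
        if self.offsets is None:
            raise ValueError("pulse sequence has no offsets")
        k = min(len(self.onsets), len(self.offsets))
        return self.offsets[:k] - self.onsets[:k]

    def shifted(self, dt: float) -> "PulseSequence":
        return PulseSequence(
            self.onsets + dt,
            None if self.offsets is None else self.offsets + dt,
            source=self.source,
        )


@dataclass
class EventLog:
    """Ordered record of experiment events as written by the software.

    Wraps a DataFrame with columns ``event_index, onset_s, planned_onset_s,
    planned_duration_s, <factor columns>, event_class`` and, for uncontrolled
    (response) rows, ``response_key``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("event_index", "onset_s"):
            if col not in df.columns:
                raise ValueError(f"event log is missing required column {col!r}")
        if df["event_index"].duplicated().any():
            dup = df.loc[df["event_index"].duplicated(), "event_index"].iloc[0]
            raise ValueError(f"duplicate event_index {dup}")
        onsets = df["onset_s"].to_numpy(float)
        if len(onsets) > 1 and np.any(np.diff(onsets) < 0):
            i = int(np.argmax(np.diff(onsets) < 0)) + 1
            raise ValueError(f"onsets decrease at row {i}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy(float)

    @property
    def planned_durations(self) -> np.ndarray:
        if "planned_duration_s" not in self.df.columns:
            raise ValueError("event log has no planned_duration_s column")
        return self.df["planned_duration_s"].to_numpy(float)

    @property
    def factor_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_LOG_COLUMNS]

    @property
    def controlled(self) -> "EventLog":
        if "event_class" not in self.df.columns:
            return self
        return EventLog(self.df[self.df["event_class"] == "controlled"])

    @property
    def uncontrolled(self) -> "EventLog":
        if "event_class" not in self.df.columns:
            raise ValueError("event log has no event_class column")
        return EventLog(self.df[self.df["event_class"] == "uncontrolled"])

    def to_pulses(self, source: str = "log") -> PulseSequence:
        """Logged onset times as a pulse sequence."""
        return PulseSequence(self.onsets, source=source)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        return cls(pd.read_csv(path))


@dataclass
class DeltaSeries:
    """Per-event timing discrepancies plus summary statistics.

    ``kind`` tags which discrepancy the values represent: ``log_timing``,
    ``duration_vs_plan``, ``trigger_jitter``, ``trigger_delay`` or
    ``response_timing``.  Interval-based kinds have one fewer value than
    events.  The sample SD uses the n-1 denominator; for a single value the
    SD is reported as 0 with ``low_n`` set.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        if self.n == 0:
            raise ValueError("empty delta series has no mean")
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if self.n == 0:
            raise ValueError("empty delta series has no sd")
        if self.n == 1:
            return 0.0
        return float(np.std(self.values, ddof=1))

    @property
    def low_n(self) -> bool:
        return self.n < 2

    @property
    def max_abs(self) -> float:
        if self.n == 0:
            raise ValueError("empty delta series has no max")
        return float(np.max(np.abs(self.values)))
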