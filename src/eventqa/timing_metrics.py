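"""Timing-discrepancy statistics between physical and logged event streams.

Sign conventions (the most likely source of implementation bugs, so stated
once and followed literally everywhere):

* log timestamping inaccuracy, trigger jitter, response inaccuracy:
  interval difference, ``(physical interval i) - (other-stream interval i)``,
  i.e. photodiode minus log / trigger.  Constant clock offsets between the
  streams cancel exactly, which is what makes the interval method robust to
  clock drift over short baselines.
* trigger delay: timestamp difference ``t_photo[i] - t_trig[i]``; requires
  both streams on the same clock.
* duration deviation: ``(observed duration i) - (planned duration i)``.
"""
from __future__ import annotations

import numpy as np

from .core import DeltaSeries, EventLog, PulseSequence

__all__ = [
    "interval_series",
    "logging_inaccuracy",
    "duration_deviation",
    "trigger_jitter",
    "trigger_delay",
    "response_inaccuracy",
    "summarize",
    "clock_drift_slope",
    "is_well_calibrated",
]

#: warn when the SD of a timing series exceeds this (seconds); a
#: well-calibrated setup keeps timestamping noise in the low-millisecond range
DEFAULT_SD_WARN_S = 0.005


def _onsets(stream: PulseSequence | EventLog | np.ndarray) -> np.ndarray:
    if isinstance(stream, EventLog):
        return stream.onsets
    if isinstance(stream, PulseSequence):
        return stream.onsets
    return np.asarray(stream, dtype=float)


def interval_series(times: PulseSequence | np.ndarray) -> np.ndarray:
    """Discrete differences between successive event timestamps."""
    t = _onsets(times)
    if len(t) < 2:
        raise ValueError(f"need at least 2 timestamps, got {len(t)}")
    return np.diff(t)


def _check_counts(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if len(a) != len(b):
        raise ValueError(
            f"event count mismatch for {what}: {len(a)} vs {len(b)} events"
        )


def _interval_difference(
    physical: PulseSequence | np.ndarray,
    other: PulseSequence | EventLog | np.ndarray,
    kind: str,
) -> DeltaSeries:
    tp, to = _onsets(physical), _onsets(other)
    _check_counts(tp, to, kind)
    return DeltaSeries(interval_series(tp) - interval_series(to), kind=kind)


def logging_inaccuracy(photo: PulseSequence, log: EventLog | PulseSequence) -> DeltaSeries:
    """Per-event log-file timestamping inaccuracy.

    Interval difference between the photodiode stream and the logged onsets;
    near zero mean with a few-ms SD for a healthy setup.
    """
    return _interval_difference(photo, log, "log_timing")


def duration_deviation(photo: PulseSequence, plan: EventLog) -> DeltaSeries:
    """Observed event duration (photodiode offset - onset) minus planned."""
    if photo.offsets is None:
        raise ValueError(
            "duration deviation needs pulse offsets; record the photodiode "
            "square with the onset_and_offset flash scheme"
        )
    planned = plan.planned_durations
    _check_counts(photo.onsets, planned, "duration deviation")
    return DeltaSeries(photo.durations - planned, kind="duration_vs_plan")


def trigger_jitter(photo: PulseSequence, trig: PulseSequence) -> DeltaSeries:
    """Peripheral trigger temporal jitter via interval differences.

    Insensitive to any constant delay between the streams; use
    :func:`trigger_delay` (same-clock recording) to measure delays.
    """
    return _interval_difference(photo, trig, "trigger_jitter")


def trigger_delay(photo: PulseSequence, trig: PulseSequence) -> DeltaSeries:
    """Per-event trigger delay ``t_photo - t_trig``.

    Both streams must be recorded on the same computer clock; this is the
    caller's responsibility and is flagged in the QA report.
    """
    tp, tt = _onsets(photo), _onsets(trig)
    _check_counts(tp, tt, "trigger delay")
    return DeltaSeries(tp - tt, kind="trigger_delay")


def response_inaccuracy(audio: PulseSequence, log: EventLog | PulseSequence) -> DeltaSeries:
    """Response timestamping inaccuracy from microphone-recorded presses.

    Same interval-difference construction as :func:`logging_inaccuracy`,
    applied to uncontrolled (response) events.
    """
    if isinstance(log, EventLog) and "event_class" in log.df.columns:
        log = log.uncontrolled
    return _interval_difference(audio, log, "response_timing")


def summarize(series: DeltaSeries) -> dict:
    """Mean, sample SD (n-1), n and max |value| of a delta series, seconds.

    For n=1 the SD is reported as 0 with ``low_n`` set.
    """
    if series.n == 0:
        raise ValueError("cannot summarize an empty delta series")
    return {
        "kind": series.kind,
        "mean_s": series.mean,
        "sd_s": series.sd,
        "n": series.n,
        "max_abs_s": series.max_abs,
        "low_n": series.low_n,
    }


def clock_drift_slope(photo: PulseSequence, other: PulseSequence | EventLog) -> float:
    """Linear drift of one clock against another (seconds per second).

    Diagnostic only: slope of the timestamp difference against time.  The
    interval-based metrics are already insensitive to drift over short
    event-to-event baselines; a large slope explains a delay estimate that
    wanders over the recording.
    """
    tp, to = _onsets(photo), _onsets(other)
    _check_counts(tp, to, "clock drift")
    if len(tp) < 2:
        raise ValueError("need at least 2 events to estimate drift")
    return float(np.polyfit(tp, tp - to, 1)[0])


def is_well_calibrated(
    series: DeltaSeries, sd_warn_s: float = DEFAULT_SD_WARN_S
) -> bool:
    """True when the series mean is within one SD of zero and the SD is
    below the warning threshold (default 5 ms)."""
    return abs(series.mean) <= max(series.sd, sd_warn_s) and series.sd <= sd_warn_s
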