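"""Turn analog traces into event timestamps.

The photodiode pipeline is threshold -> binarize -> discrete difference ->
transition localization: samples at or above threshold become 1, the discrete
difference marks off->on transitions with +1 and on->off with -1, and each
transition is stamped at the first sample on its new side, converted to
seconds through the sampling rate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import AnalogTrace, EventLog, PulseSequence

__all__ = [
    "binarize",
    "auto_threshold",
    "detect_transitions",
    "parse_photodiode",
    "extract_audio_onsets",
    "pair_pulses_to_events",
    "PulseCountMismatch",
]


def auto_threshold(samples: np.ndarray) -> float:
    """Midpoint of the 1st and 99th percentiles of a two-state trace.

    Robust to isolated outliers; fails when the trace cannot be separated
    into a low and a high state.
    """
    lo, hi = np.percentile(samples, [1.0, 99.0])
    if hi <= lo:
        raise ValueError(
            "cannot separate on/off states: 1st and 99th percentiles coincide"
        )
    return float((lo + hi) / 2.0)


def binarize(trace: AnalogTrace, threshold: float | str = "auto") -> np.ndarray:
    """Threshold a trace into a 0/1 sequence (1 = at or above threshold)."""
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        threshold = auto_threshold(trace.samples)
    return (trace.samples >= threshold).astype(np.int8)


def detect_transitions(
    binary: np.ndarray,
    fs: float,
    start_time: float = 0.0,
    refractory: float = 0.0,
) -> PulseSequence:
    """Locate state transitions of a binary sequence as pulse on/offsets.

    An off->on transition between samples n and n+1 is stamped at sample
    n+1, i.e. the first supra-threshold sample, at ``start_time + (n+1)/fs``.
    Transitions closer than ``refractory`` seconds to the previously accepted
    transition (of either polarity) are discarded as threshold chatter.
    """
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("input must be a 0/1 sequence")
    d = np.diff(binary.astype(np.int8))
    idx = np.nonzero(d != 0)[0] + 1  # first sample on the new side
    onsets: list[float] = []
    offsets: list[float] = []
    last_t = -np.inf
    for i in idx:
        t = start_time + i / fs
        if t - last_t < refractory:
            continue
        last_t = t
        (onsets if d[i - 1] > 0 else offsets).append(t)
    if offsets and (not onsets or offsets[0] < onsets[0]):
        # recording started mid-pulse: the leading offset has no onset
        offsets.pop(0)
    return PulseSequence(
        np.asarray(onsets), np.asarray(offsets) if offsets else None, source="photodiode"
    )


def parse_photodiode(
    trace: AnalogTrace,
    threshold: float | str = "auto",
    refractory: float | None = None,
) -> PulseSequence:
    """Full photodiode pipeline: binarize then localize transitions.

    Default refractory period is 2 samples, suppressing chatter at the
    threshold crossing without masking genuine pulses.
    """
    if refractory is None:
        refractory = 2.0 / trace.fs
    b = binarize(trace, threshold)
    return detect_transitions(b, trace.fs, trace.start_time, refractory)


def extract_audio_onsets(
    trace: AnalogTrace,
    envelope_window: float = 0.005,
    threshold: float | str = "auto",
    refractory: float = 0.05,
) -> PulseSequence:
    """Extract key-press onsets from a microphone recording.

    The signal is rectified and smoothed with a moving average of
    ``envelope_window`` seconds; the envelope is thresholded and transitions
    localized as for the photodiode.  Because clicks occupy a tiny fraction
    of the recording, the auto threshold here is the midpoint of the envelope
    median (noise floor) and maximum (click peak), not percentiles.
    """
    win = max(1, int(round(envelope_window * trace.fs)))
    env = uniform_filter1d(np.abs(trace.samples), size=win, mode="nearest")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        floor, peak = float(np.median(env)), float(env.max())
        if peak <= floor or peak < 10 * max(floor, 1e-12):
            # no burst stands out of the noise floor: silence
            return PulseSequence(np.asarray([]), source="microphone")
        threshold = (floor + peak) / 2.0
    b = (env >= threshold).astype(np.int8)
    pulses = detect_transitions(b, trace.fs, trace.start_time, refractory)
    return PulseSequence(pulses.onsets, source="microphone")


class PulseCountMismatch(ValueError):
    """Pulse count does not match the event log; indicates signal-quality
    problems (missed or spurious pulses) that require intervention, not
    silent repair."""

    def __init__(
        self,
        n_events: int,
        n_pulses: int,
        expected_pulses: int,
        first_divergence_event: int | None,
    ):
        self.n_events = n_events
        self.n_pulses = n_pulses
        self.expected_pulses = expected_pulses
        self.first_divergence_event = first_divergence_event
        msg = (
            f"pulse count mismatch: {n_events} logged events require "
            f"{expected_pulses} pulses but {n_pulses} were detected"
        )
        if first_divergence_event is not None:
            msg += f"; intervals first diverge at event index {first_divergence_event}"
        super().__init__(msg)


def _first_interval_divergence(
    observed: np.ndarray, expected: np.ndarray, tol: float
) -> int | None:
    k = min(len(observed), len(expected))
    if k == 0:
        return 0 if len(observed) != len(expected) else None
    dev = np.abs(observed[:k] - expected[:k]) > tol
    if dev.any():
        return int(np.argmax(dev))
    if len(observed) != len(expected):
        return k
    return None


def pair_pulses_to_events(
    pulses: PulseSequence,
    log: EventLog,
    scheme: str = "onset_and_offset",
) -> pd.DataFrame:
    """Pair detected pulses with logged events.

    Under the onset-and-offset flash scheme the photodiode square flashes
    briefly at each event onset *and* offset, so the pulse stream carries two
    pulses per event, taken pairwise in order.  A count mismatch is a hard
    error carrying both counts and the event index where the inter-pulse
    intervals first diverge from the log's expectation.
    """
    if scheme not in ("onset_only", "onset_and_offset"):
        raise ValueError(f"unknown scheme {scheme!r}")
    times = pulses.onsets
    n_events = len(log)
    per_event = 2 if scheme == "onset_and_offset" else 1
    expected_n = per_event * n_events
    if len(times) != expected_n:
        # reconstruct the expected physical time stream from the log
        if scheme == "onset_and_offset" and "planned_duration_s" in log.df.columns:
            exp = np.empty(expected_n)
            exp[0::2] = log.onsets
            exp[1::2] = log.onsets + log.planned_durations
        else:
            exp = log.onsets
        exp_int = np.diff(exp)
        obs_int = np.diff(times)
        tol = 0.25 * exp_int.min() if len(exp_int) else 0.0
        div = _first_interval_divergence(obs_int, exp_int, tol)
        # interval i diverging implicates the pulse at stream position i+1
        event_div = None if div is None else min((div + 1) // per_event, n_events - 1)
        raise PulseCountMismatch(n_events, len(times), expected_n, event_div)
    out = {"event_index": log.df["event_index"].to_numpy()}
    if scheme == "onset_and_offset":
        out["physical_onset_s"] = times[0::2]
        out["physical_offset_s"] = times[1::2]
    else:
        out["physical_onset_s"] = times
    return pd.DataFrame(out)


def paired_pulse_sequence(paired: pd.DataFrame, source: str = "photodiode") -> PulseSequence:
    """Convert a paired table back into a per-event pulse sequence."""
    offsets = (
        paired["physical_offset_s"].to_numpy(float)
        if "physical_offset_s" in paired.columns
        else None
    )
    return PulseSequence(paired["physical_onset_s"].to_numpy(float), offsets, source=source)
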