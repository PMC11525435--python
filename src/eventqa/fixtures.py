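"""Synthetic experiments with known, configurable corruptions.

Every downstream metric in this package is testable by parameter recovery:
generate an experiment with a known injected delay, jitter, label errors or
dropped events, run the pipeline, and check that the injected values are
recovered.  The generator is fully deterministic for a fixed
(plan, corruption, seed) triple.

Corruption vocabulary: a *delay* is a constant temporal shift of one stream
against another (correctable post hoc); a *jitter* is a per-event varying
shift (not correctable by a constant).  Gaussian jitter uses ``jitter_sd``;
the fixed-magnitude variant (``jitter_magnitude`` on a ``jitter_proportion``
subset, random sign) mirrors the corruption used in the impact simulator.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnalogTrace, EventLog, PulseSequence

__all__ = [
    "ExperimentPlan",
    "CorruptionSpec",
    "SyntheticExperiment",
    "generate_experiment",
    "synthesize_photodiode",
    "synthesize_keypress_audio",
    "synthesize_triggers",
]

#: default photodiode flash length: one frame at 60 Hz
DEFAULT_PULSE_WIDTH = 1.0 / 60.0

_RESPONSE_LATENCY = 0.45  # s after event onset for planned fixture presses
_REPEAT_GAP = 0.12  # s between repeated presses of a multi-press entry


@dataclass
class ExperimentPlan:
    """Blueprint of an event-based experiment.

    ``condition_factors`` maps factor names to level lists (the realized
    design is the balanced full cross, shuffled).  ``planned_durations`` and
    ``inter_event_interval`` may be scalars (applied to every event) or
    per-event sequences in seconds.  ``response_plan`` is an ordered list of
    ``(key, press_count)`` entries, one per event in order (shorter plans
    leave later events without responses).
    """

    n_events: int
    condition_factors: dict[str, list[str]] = field(
        default_factory=lambda: {"category": ["face", "object"]}
    )
    planned_durations: float | Sequence[float] = 0.5
    inter_event_interval: float | Sequence[float] = 0.5
    response_plan: list[tuple[str, int]] | None = None
    start_time: float = 10.0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for name, levels in self.condition_factors.items():
            if len(levels) < 1:
                raise ValueError(f"factor {name!r} has no levels")
        if np.any(self.durations <= 0):
            raise ValueError("planned durations must be strictly positive")
        if np.any(self.intervals < 0):
            raise ValueError("inter-event intervals must be non-negative")

    def _per_event(self, x) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(x, dtype=float), (self.n_events,))
        return arr.copy()

    @property
    def durations(self) -> np.ndarray:
        return self._per_event(self.planned_durations)

    @property
    def intervals(self) -> np.ndarray:
        return self._per_event(self.inter_event_interval)

    @property
    def total_span(self) -> float:
        """Total planned span: sum of durations and intervals."""
        return float(self.durations.sum() + self.intervals.sum())


@dataclass
class CorruptionSpec:
    """Known corruptions to inject into the logged streams.

    All magnitudes in seconds; proportions in [0, 1].  The same seed yields
    byte-identical output.
    """

    clock_delay: float = 0.0
    jitter_sd: float = 0.0
    jitter_magnitude: float = 0.0
    jitter_proportion: float = 0.0
    drop_events: int = 0
    label_errors: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter_proportion <= 1.0:
            raise ValueError("jitter_proportion must be in [0, 1]")
        for name in ("jitter_sd", "jitter_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drop_events < 0 or self.label_errors < 0:
            raise ValueError("drop_events and label_errors must be >= 0")


@dataclass
class SyntheticExperiment:
    """A generated experiment with its ground truth and corruption records.

    ``log`` is the (possibly corrupted) event log as the experimental
    software would have written it; ``truth`` holds the true physical
    stimulus onsets/offsets; ``truth_log`` is the uncorrupted log (the
    "manual annotation" oracle for content checks).  The injected-corruption
    bookkeeping (which rows were mislabelled, jittered or dropped) makes
    exact parameter-recovery tests possible.
    """

    log: EventLog
    truth: PulseSequence
    truth_log: EventLog
    response_truth: PulseSequence | None = None
    label_error_rows: np.ndarray = field(default_factory=lambda: np.asarray([], int))
    jittered_rows: np.ndarray = field(default_factory=lambda: np.asarray([], int))
    dropped_rows: np.ndarray = field(default_factory=lambda: np.asarray([], int))

    def __iter__(self):
        # allow  log, truth = generate_experiment(...)
        return iter((self.log, self.truth))


def _assign_factors(plan: ExperimentPlan, rng: np.random.Generator) -> pd.DataFrame:
    names = list(plan.condition_factors)
    combos = list(itertools.product(*(plan.condition_factors[n] for n in names)))
    reps = itertools.islice(itertools.cycle(combos), plan.n_events)
    rows = rng.permutation(np.asarray(list(reps), dtype=object))
    return pd.DataFrame(rows, columns=names)


def generate_experiment(
    plan: ExperimentPlan,
    corruption: CorruptionSpec | None = None,
    seed: int | None = None,
) -> SyntheticExperiment:
    """Generate an event log plus ground-truth physical times.

    Logged onsets equal the ground-truth onsets plus the specified constant
    delay, Gaussian jitter, and/or fixed-magnitude random-sign jitter on a
    random subset.  Label errors corrupt exactly ``label_errors`` rows;
    ``drop_events`` rows are silently missing from the log stream (the
    ground truth keeps them, as a real photodiode would).
    """
    corruption = corruption or CorruptionSpec()
    rng = np.random.default_rng(corruption.seed if seed is None else seed)
    n = plan.n_events

    durations = plan.durations
    intervals = plan.intervals
    onsets = plan.start_time + np.concatenate(
        ([0.0], np.cumsum(durations[:-1] + intervals[:-1]))
    )
    offsets = onsets + durations
    truth = PulseSequence(onsets, offsets, source="truth")

    factors = _assign_factors(plan, rng)
    logged = onsets + corruption.clock_delay
    if corruption.jitter_sd > 0:
        logged = logged + rng.normal(0.0, corruption.jitter_sd, n)
    jittered = np.asarray([], dtype=int)
    if corruption.jitter_magnitude > 0 and corruption.jitter_proportion > 0:
        k = int(round(corruption.jitter_proportion * n))
        jittered = np.sort(rng.choice(n, size=k, replace=False))
        logged = logged.copy()
        logged[jittered] += corruption.jitter_magnitude * rng.choice([-1.0, 1.0], k)
    bad = np.nonzero(np.diff(logged) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"corruption makes logged onsets non-monotonic at event {bad[0] + 1}"
        )

    base = pd.DataFrame(
        {
            "event_index": np.arange(n),
            "onset_s": logged,
            "planned_onset_s": onsets,
            "planned_duration_s": durations,
        }
    )
    base = pd.concat([base, factors], axis=1)
    base["event_class"] = "controlled"
    truth_df = base.copy()
    truth_df["onset_s"] = onsets

    # label errors: replace one factor level per chosen row with another level
    label_rows = np.asarray([], dtype=int)
    if corruption.label_errors:
        if corruption.label_errors > n:
            raise ValueError("label_errors exceeds n_events")
        label_rows = np.sort(rng.choice(n, corruption.label_errors, replace=False))
        names = list(plan.condition_factors)
        for j, row in enumerate(label_rows):
            name = names[j % len(names)]
            levels = [
                lv for lv in plan.condition_factors[name] if lv != base.at[row, name]
            ]
            if not levels:  # single-level factor cannot be mislabelled
                continue
            base.at[row, name] = levels[rng.integers(len(levels))]

    dropped = np.asarray([], dtype=int)
    if corruption.drop_events:
        if corruption.drop_events > n:
            raise ValueError("drop_events exceeds n_events")
        dropped = np.sort(rng.choice(n, corruption.drop_events, replace=False))
        base = base.drop(index=dropped)

    # planned responses ride after their events; logged response times get
    # the same delay/Gaussian-jitter treatment as stimulus timestamps
    response_truth = None
    if plan.response_plan:
        press_t, keys, idx = [], [], []
        for i, (key, count) in enumerate(plan.response_plan):
            if i >= n:
                break
            for r in range(count):
                press_t.append(onsets[i] + _RESPONSE_LATENCY + r * _REPEAT_GAP)
                keys.append(key)
                idx.append(i)
        press_t = np.asarray(press_t)
        response_truth = PulseSequence(press_t, source="truth")
        logged_press = press_t + corruption.clock_delay
        if corruption.jitter_sd > 0:
            logged_press = logged_press + rng.normal(0.0, corruption.jitter_sd, len(press_t))
        resp = pd.DataFrame(
            {
                "event_index": n + np.arange(len(press_t)),
                "onset_s": logged_press,
                "planned_onset_s": press_t,
                "planned_duration_s": np.nan,
                "event_class": "uncontrolled",
                "response_key": keys,
            }
        )
        base = pd.concat([base, resp], ignore_index=True)
        base = base.sort_values("onset_s", kind="stable").reset_index(drop=True)

    return SyntheticExperiment(
        log=EventLog(base),
        truth=truth,
        truth_log=EventLog(truth_df),
        response_truth=response_truth,
        label_error_rows=label_rows,
        jittered_rows=jittered,
        dropped_rows=dropped,
    )


def _pulse_train(
    pulse_starts: np.ndarray,
    fs: float,
    pulse_width: float,
    noise_sd: float,
    rng: np.random.Generator,
    baseline: float,
    high: float,
    pad: float,
) -> AnalogTrace:
    n_width = int(round(pulse_width * fs))
    if len(pulse_starts):
        n_total = int(round((pulse_starts[-1] + pulse_width + pad) * fs))
    else:
        n_total = int(round(max(pad, 1.0) * fs))
    samples = np.full(n_total, float(baseline))
    for t in pulse_starts:
        i = int(round(t * fs))
        samples[i : i + n_width] = high
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, n_total)
    return AnalogTrace(samples, fs=fs, start_time=0.0)


def synthesize_photodiode(
    truth: PulseSequence,
    fs: float = 1000.0,
    pulse_width: float = DEFAULT_PULSE_WIDTH,
    noise_sd: float = 0.0,
    scheme: str = "onset_and_offset",
    seed: int | None = 0,
    baseline: float = 0.0,
    high: float = 1.0,
) -> AnalogTrace:
    """Simulate the photodiode luminance trace for a pulse sequence.

    The test square flashes high for ``pulse_width`` seconds at each event
    onset (and offset under the default onset-and-offset scheme), against a
    low baseline, with optional additive Gaussian noise.
    """
    if scheme not in ("onset_only", "onset_and_offset"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not fs > 2.0 / pulse_width:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve {pulse_width * 1e3:.1f} ms pulses"
        )
    if scheme == "onset_and_offset":
        if truth.offsets is None:
            raise ValueError("onset_and_offset scheme requires pulse offsets")
        starts = np.sort(np.concatenate([truth.onsets, truth.offsets]))
    else:
        starts = truth.onsets
    gaps = np.diff(starts)
    if np.any(gaps < pulse_width):
        bad = np.nonzero(gaps < pulse_width)[0]
        events = sorted({int(b // 2) for b in bad} | {int((b + 1) // 2) for b in bad})
        raise ValueError(f"overlapping photodiode pulses at event indices {events}")
    rng = np.random.default_rng(seed)
    return _pulse_train(starts, fs, pulse_width, noise_sd, rng, baseline, high, pad=0.5)


def synthesize_keypress_audio(
    press_times: PulseSequence,
    fs: float = 44100.0,
    click_duration: float = 0.01,
    snr: float = 20.0,
    seed: int | None = 0,
) -> AnalogTrace:
    """Simulate a microphone recording of key presses.

    Each press is a broadband (white-noise) burst of unit amplitude starting
    at the press time, over a background noise floor of amplitude 1/snr.
    Only onset detectability matters, so no keyboard acoustics are modelled.
    """
    t = press_times.onsets
    if len(t) > 1 and np.any(np.diff(t) <= click_duration):
        bad = np.nonzero(np.diff(t) <= click_duration)[0]
        raise ValueError(f"key presses overlap at indices {list(bad)}")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    n_total = int(round(((t[-1] + click_duration + 0.5) if len(t) else 1.0) * fs))
    samples = rng.normal(0.0, 1.0 / snr, n_total)
    n_click = int(round(click_duration * fs))
    for tt in t:
        i = int(round(tt * fs))
        samples[i : i + n_click] += rng.normal(0.0, 1.0, n_click)
    return AnalogTrace(samples, fs=fs, start_time=0.0)


def synthesize_triggers(
    truth: PulseSequence,
    codes: Sequence | None = None,
    delay: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate a peripheral trigger stream (timestamp + code rows).

    Timestamps are the true event times plus a constant delay and optional
    per-event Gaussian jitter; codes are preserved in order.
    """
    n = len(truth)
    if codes is None:
        codes = np.arange(1, n + 1)
    if len(codes) != n:
        raise ValueError(f"need one code per event: {len(codes)} codes, {n} events")
    rng = np.random.default_rng(seed)
    ts = truth.onsets + delay
    if jitter_sd > 0:
        ts = ts + rng.normal(0.0, jitter_sd, n)
    return pd.DataFrame({"timestamp_s": ts, "code": list(codes)})
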