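"""Monte-Carlo study of how log-file corruptions destroy real effects.

Two simulated measures carry a true two-condition difference of standardized
size theta (Cohen's d of the uncorrupted *measured* variable):

* ``P1`` — single-trial visual evoked epochs: a positive component at
  100 ms (sigma 12 ms) riding next to an adjacent earlier negativity
  (C1-like, 69 ms, sigma 10 ms), plus white sensor noise.  The measured
  amplitude is the mean of the baseline-corrected signal inside the
  90-110 ms window of the epoch locked to the *logged* onset.  The
  condition difference loads on the P1 amplitude.
* ``RT`` — Gaussian reaction times; the measured RT inherits any
  logged-onset error directly.

Corruptions mirror real malfunctions: shuffling condition labels on a
random subset of trials (content errors), or a fixed-magnitude random-sign
onset jitter on a subset (timing errors).  For the P1 the jitter shifts the
epoch against the waveform, so large jitters both attenuate the condition
difference (the P1 leaves the window) and inflate variance (the adjacent
negativity enters it); for RT the jitter adds variance only.  Each grid
cell reports the mean Welch t-statistic across replicates; the boundary of
interest is the smallest corrupted proportion that drags the mean t under
the significance threshold of 1.96.

The free parameters (trial counts, waveform amplitudes, RT spread) are
calibrated once by ``scripts/calibrate_simulation.py`` and frozen below.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ErpWaveform",
    "SimulationConfig",
    "SweepResult",
    "simulate_erp_trials",
    "simulate_rt_trials",
    "shuffle_labels",
    "inject_jitter",
    "welch_t",
    "run_sweep",
    "significance_boundary",
    "corruption_boundary",
]

SIGNIFICANCE_THRESHOLD = 1.96

#: calibrated defaults (see scripts/calibrate_simulation.py); frozen
P1_N_TRIALS = 280
RT_N_TRIALS = 206
RT_SD_S = 0.0205
C1_AMPLITUDE = -12.5  # uV, adjacent pre-P1 negativity

DEFAULT_PROPORTIONS = (0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
DEFAULT_JITTERS_MS = (2.0, 8.0, 16.0, 24.0, 32.0, 40.0)
DEFAULT_THETAS = (0.1, 0.2, 0.3, 0.5, 0.8)


@dataclass(frozen=True)
class ErpWaveform:
    """Epoch grid and Gaussian-bump component model for simulated ERPs.

    All times in seconds.  Components are Gaussian bumps
    ``amp * exp(-(t - latency)^2 / (2 width^2))``; the condition difference
    loads on the component at ``effect_component`` (the P1).  ``noise_sd``
    is white per-sample sensor noise in uV.
    """

    epoch_start: float = -0.200
    epoch_stop: float = 0.500
    fs: float = 1000.0
    window: tuple[float, float] = (0.090, 0.110)
    baseline: tuple[float, float] = (-0.100, 0.0)
    latencies: tuple[float, ...] = (0.069, 0.100)
    widths: tuple[float, ...] = (0.010, 0.012)
    amplitudes: tuple[float, ...] = (C1_AMPLITUDE, 2.0)
    effect_component: int = 1
    noise_sd: float = 10.0

    def sample_indices(self) -> np.ndarray:
        k0 = int(round(self.epoch_start * self.fs))
        k1 = int(round(self.epoch_stop * self.fs))
        return np.arange(k0, k1)

    def times(self) -> np.ndarray:
        return self.sample_indices() / self.fs

    def _mask(self, lo: float, hi: float, closed: bool) -> np.ndarray:
        k = self.sample_indices()
        klo, khi = int(round(lo * self.fs)), int(round(hi * self.fs))
        return (k >= klo) & ((k <= khi) if closed else (k < khi))

    @property
    def window_mask(self) -> np.ndarray:
        m = self._mask(*self.window, closed=True)
        if not m.any():
            raise ValueError("measurement window lies outside the epoch")
        return m

    @property
    def baseline_mask(self) -> np.ndarray:
        m = self._mask(*self.baseline, closed=False)
        if not m.any():
            raise ValueError("baseline window lies outside the epoch")
        return m

    def template(self, t: np.ndarray, condition_delta: float = 0.0) -> np.ndarray:
        """Noise-free waveform at times ``t`` for a given condition's extra
        amplitude on the effect component."""
        out = np.zeros_like(t, dtype=float)
        for i, (lat, wid, amp) in enumerate(
            zip(self.latencies, self.widths, self.amplitudes)
        ):
            if i == self.effect_component:
                amp = amp + condition_delta
            out += amp * np.exp(-((t - lat) ** 2) / (2.0 * wid**2))
        return out

    def measured_template(self, onset_error: float, condition_delta: float = 0.0) -> float:
        """Window-mean minus baseline-mean of the noise-free waveform when
        the epoch is locked to an onset mislogged by ``onset_error``.

        A logged onset that is wrong by ``e`` makes epoch time ``tau``
        correspond to true post-stimulus time ``tau + e``.
        """
        t = self.times() + onset_error
        w = self.template(t, condition_delta)
        return float(w[self.window_mask].mean() - w[self.baseline_mask].mean())

    @property
    def measurement_noise_sd(self) -> float:
        """SD of the measured amplitude from white sensor noise alone."""
        n_win = int(self.window_mask.sum())
        n_base = int(self.baseline_mask.sum())
        return self.noise_sd * np.sqrt(1.0 / n_win + 1.0 / n_base)

    def effect_amplitude(self, theta: float) -> float:
        """Condition amplitude difference giving measured Cohen's d = theta."""
        unit = replace(self, amplitudes=tuple(0.0 for _ in self.amplitudes))
        gain = unit.measured_template(0.0, condition_delta=1.0)
        return theta * self.measurement_noise_sd / gain


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one corruption sweep.

    ``theta`` is the standardized effect size of the uncorrupted measured
    variable; grids default to the studied ranges (proportions 2-40%,
    jitter 2-40 ms).  ``n_trials_per_condition`` defaults to the calibrated
    per-measure value.  ``waveform_fidelity`` switches the P1 sampler from
    the exact reduced form (window/baseline noise means drawn directly) to
    full epoch synthesis; both sample the identical distribution because the
    measurement is linear in the white noise.
    """

    measure: str = "P1"
    theta: float = 0.2
    n_trials_per_condition: int | None = None
    reps: int = 500
    corruption: str = "shuffle"
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    jitter_ms: tuple[float, ...] = DEFAULT_JITTERS_MS
    thetas: tuple[float, ...] | None = None
    seed: int = 0
    waveform: ErpWaveform = field(default_factory=ErpWaveform)
    rt_mean_s: float = 0.450
    rt_sd_s: float = RT_SD_S
    waveform_fidelity: bool = False

    def __post_init__(self) -> None:
        if self.measure not in ("P1", "RT"):
            raise ValueError(f"measure must be 'P1' or 'RT', got {self.measure!r}")
        if self.corruption not in ("shuffle", "jitter"):
            raise ValueError(f"corruption must be 'shuffle' or 'jitter'")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(not 0.0 <= p <= 1.0 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        if self.n_trials_per_condition is not None:
            return self.n_trials_per_condition
        return P1_N_TRIALS if self.measure == "P1" else RT_N_TRIALS

    @property
    def theta_grid(self) -> tuple[float, ...]:
        return self.thetas if self.thetas is not None else (self.theta,)


def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Welch's unequal-variance two-sample t-statistic (x minus y).

    Degenerate inputs (zero variance in both groups and equal means) return
    0 by convention.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    num = x.mean() - y.mean()
    den = np.sqrt(vx / len(x) + vy / len(y))
    if den == 0.0:
        return 0.0 if num == 0.0 else np.sign(num) * np.inf
    return float(num / den)


def shuffle_labels(
    labels: np.ndarray, proportion: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Randomly permute condition labels within a random subset of trials.

    The subset has size ``round(proportion * n)``; the overall label
    multiset is preserved exactly.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    labels = np.asarray(labels).copy()
    k = int(round(proportion * len(labels)))
    if k >= 2:
        idx = rng.choice(len(labels), size=k, replace=False)
        labels[idx] = labels[idx][rng.permutation(k)]
    return labels


def inject_jitter(
    n_trials: int,
    proportion: float,
    magnitude_s: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Per-trial logged-onset errors: +/-magnitude (random sign) on a random
    subset of size ``round(proportion * n)``, zero elsewhere."""
    if magnitude_s < 0:
        raise ValueError("magnitude must be >= 0")
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    errors = np.zeros(n_trials)
    k = int(round(proportion * n_trials))
    if k and magnitude_s > 0:
        idx = rng.choice(n_trials, size=k, replace=False)
        errors[idx] = magnitude_s * rng.choice([-1.0, 1.0], size=k)
    return errors


def simulate_erp_trials(
    config: SimulationConfig,
    rng: np.random.Generator | int = 0,
    onset_errors: np.ndarray | None = None,
    return_epochs: bool = False,
):
    """Simulate single-trial P1 amplitudes (full waveform synthesis).

    Each trial is a sum of Gaussian-bump components plus white noise,
    epoch-locked to the logged onset (true onset plus that trial's
    ``onset_error``).  The measured amplitude is the mean of the
    baseline-corrected signal in the measurement window.  Returns
    ``(amplitudes, labels)`` (labels 0/1), plus the epochs matrix when
    ``return_epochs`` is set.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    wf = config.waveform
    n = config.n_trials
    n_total = 2 * n
    labels = np.repeat([0, 1], n)
    if onset_errors is None:
        onset_errors = np.zeros(n_total)
    onset_errors = np.asarray(onset_errors, float)
    d_amp = wf.effect_amplitude(config.theta)
    tau = wf.times()
    # condition deltas: label 0 -> -d/2, label 1 -> +d/2
    deltas = (labels - 0.5) * d_amp
    epochs = np.empty((n_total, len(tau)))
    for i in range(n_total):
        epochs[i] = wf.template(tau + onset_errors[i], deltas[i])
    epochs += rng.normal(0.0, wf.noise_sd, epochs.shape)
    measured = (
        epochs[:, wf.window_mask].mean(axis=1) - epochs[:, wf.baseline_mask].mean(axis=1)
    )
    if return_epochs:
        return measured, labels, epochs
    return measured, labels


def _erp_measured_reduced(
    config: SimulationConfig,
    rng: np.random.Generator,
    onset_errors: np.ndarray,
    labels: np.ndarray,
    det_table: np.ndarray,
) -> np.ndarray:
    """Exact reduced P1 sampler: deterministic window/baseline means per
    (condition, onset-error sign) plus a single Gaussian measurement-noise
    draw per trial.

    Identical in distribution to full epoch synthesis because the
    measurement (window mean minus baseline mean) is linear in the white
    noise.  ``det_table[label, code]`` holds the noise-free measured values
    for error codes 0: -magnitude, 1: none, 2: +magnitude.
    """
    wf = config.waveform
    codes = (np.sign(onset_errors) + 1).astype(int)
    det = det_table[labels, codes]
    return det + rng.normal(0.0, wf.measurement_noise_sd, len(labels))


def _erp_det_table(config: SimulationConfig, magnitude_s: float) -> np.ndarray:
    wf = config.waveform
    d_amp = wf.effect_amplitude(config.theta)
    table = np.empty((2, 3))
    for lab in (0, 1):
        for code, e in enumerate((-magnitude_s, 0.0, magnitude_s)):
            table[lab, code] = wf.measured_template(e, (lab - 0.5) * d_amp)
    return table


def simulate_rt_trials(
    config: SimulationConfig,
    rng: np.random.Generator | int = 0,
    onset_errors: np.ndarray | None = None,
):
    """Simulate reaction times with standardized condition difference theta.

    The measured RT is the true RT plus the logged-onset error of that trial
    (a mislogged stimulus onset shifts the computed RT one-for-one).
    Returns ``(measured_rt, labels)``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = config.n_trials
    labels = np.repeat([0, 1], n)
    means = config.rt_mean_s + (labels - 0.5) * config.theta * config.rt_sd_s
    rt = rng.normal(means, config.rt_sd_s)
    if onset_errors is not None:
        rt = rt + np.asarray(onset_errors, float)
    return rt, labels


def _cell_ts(
    config: SimulationConfig,
    theta: float,
    proportion: float,
    magnitude_s: float,
    rng: np.random.Generator,
    reps: int,
) -> np.ndarray:
    """t-statistics of ``reps`` independent corrupted datasets for one cell."""
    cfg = replace(config, theta=theta)
    n_total = 2 * cfg.n_trials
    ts = np.empty(reps)
    det_table = (
        _erp_det_table(cfg, magnitude_s) if cfg.measure == "P1" and not cfg.waveform_fidelity
        else None
    )
    for r in range(reps):
        labels = np.repeat([0, 1], cfg.n_trials)
        if cfg.corruption == "jitter":
            errors = inject_jitter(n_total, proportion, magnitude_s, rng)
        else:
            errors = None
        if cfg.measure == "RT":
            x, labels = simulate_rt_trials(cfg, rng, errors)
        elif cfg.waveform_fidelity:
            x, labels = simulate_erp_trials(
                cfg, rng, errors if errors is not None else None
            )
        else:
            if errors is None:
                errors = np.zeros(n_total)
            x = _erp_measured_reduced(cfg, rng, errors, labels, det_table)
        if cfg.corruption == "shuffle":
            labels = shuffle_labels(labels, proportion, rng)
        ts[r] = welch_t(x[labels == 1], x[labels == 0])
    return ts


@dataclass
class SweepResult:
    """Grid of mean t-statistics over (theta, magnitude, proportion).

    ``table`` is long-format with columns ``theta, magnitude_ms, proportion,
    mean_t, sd_t, reps``; ``magnitude_ms`` is 0 for label-shuffle sweeps.
    """

    table: pd.DataFrame
    threshold: float
    config: SimulationConfig

    def cell(self, theta: float, proportion: float, magnitude_ms: float = 0.0) -> pd.Series:
        t = self.table
        m = (
            np.isclose(t["theta"], theta)
            & np.isclose(t["proportion"], proportion)
            & np.isclose(t["magnitude_ms"], magnitude_ms)
        )
        if not m.any():
            raise KeyError(
                f"no cell at theta={theta}, proportion={proportion}, "
                f"magnitude={magnitude_ms}"
            )
        return t[m].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def heatmap(self, theta: float, magnitude_ms: float = 0.0, ax=None):
        """Proportion-resolved mean-t heat strip for one theta/magnitude,
        colored divergently around the significance threshold."""
        import matplotlib.pyplot as plt

        t = self.table
        m = np.isclose(t["theta"], theta) & np.isclose(t["magnitude_ms"], magnitude_ms)
        sub = t[m].sort_values("proportion")
        if sub.empty:
            raise KeyError(f"no cells at theta={theta}, magnitude={magnitude_ms}")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 1.8))
        vals = sub["mean_t"].to_numpy()[None, :]
        span = max(abs(vals - self.threshold).max(), 0.5)
        im = ax.imshow(
            vals, aspect="auto", cmap="coolwarm_r",
            vmin=self.threshold - span, vmax=self.threshold + span,
        )
        ax.set_xticks(range(len(sub)), [f"{p:.0%}" for p in sub["proportion"]])
        ax.set_yticks([])
        ax.set_xlabel("corrupted proportion of trials")
        title = f"mean t, theta={theta}"
        if magnitude_ms:
            title += f", jitter {magnitude_ms:.0f} ms"
        ax.set_title(title)
        plt.colorbar(im, ax=ax, label="mean t")
        return ax


def run_sweep(config: SimulationConfig) -> SweepResult:
    """Simulate the full corruption grid.

    For every (theta, magnitude, proportion) cell, ``config.reps``
    independent corrupted datasets are generated and tested; the cell value
    is the mean Welch t across replicates.  Deterministic for a fixed seed.
    """
    magnitudes = (
        [m / 1000.0 for m in config.jitter_ms] if config.corruption == "jitter" else [0.0]
    )
    rows = []
    for i_t, theta in enumerate(config.theta_grid):
        for i_m, mag in enumerate(magnitudes):
            for i_p, p in enumerate(config.proportions):
                rng = np.random.default_rng([config.seed, i_t, i_m, i_p])
                ts = _cell_ts(config, theta, p, mag, rng, config.reps)
                rows.append(
                    {
                        "theta": theta,
                        "magnitude_ms": mag * 1000.0,
                        "proportion": p,
                        "mean_t": ts.mean(),
                        "sd_t": ts.std(ddof=1) if len(ts) > 1 else 0.0,
                        "reps": config.reps,
                    }
                )
    return SweepResult(pd.DataFrame(rows), SIGNIFICANCE_THRESHOLD, config)


def significance_boundary(
    sweep: SweepResult,
    theta: float,
    magnitude_ms: float = 0.0,
    threshold: float | None = None,
) -> float | None:
    """Smallest grid proportion whose mean t falls below the threshold.

    Returns None when the effect survives the whole grid.
    """
    threshold = sweep.threshold if threshold is None else threshold
    t = sweep.table
    m = np.isclose(t["theta"], theta) & np.isclose(t["magnitude_ms"], magnitude_ms)
    sub = t[m].sort_values("proportion")
    below = sub[sub["mean_t"] < threshold]
    if below.empty:
        return None
    return float(below["proportion"].iloc[0])


def corruption_boundary(
    config: SimulationConfig,
    magnitude_ms: float = 0.0,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> float | None:
    """Scan proportions in ascending order, returning the first whose mean t
    drops below the threshold (None if the effect survives the whole grid).

    Equivalent to running the full sweep and applying
    :func:`significance_boundary`, but stops at the boundary.
    """
    mag = magnitude_ms / 1000.0
    for i_p, p in enumerate(sorted(config.proportions)):
        rng = np.random.default_rng([config.seed, 0, 0, i_p])
        ts = _cell_ts(config, config.theta, p, mag, rng, config.reps)
        if ts.mean() < threshold:
            return float(p)
    return None
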