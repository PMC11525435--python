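"""Corruption-impact simulator: statistics, corruption models, sweeps."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eventqa import (
    ErpWaveform,
    SimulationConfig,
    SweepResult,
    inject_jitter,
    run_sweep,
    shuffle_labels,
    significance_boundary,
    simulate_erp_trials,
    simulate_rt_trials,
    welch_t,
)
from eventqa.impact_simulation import _cell_ts


class TestWelchT:
    def test_hand_evaluated_example(self):
        assert welch_t([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.2247, abs=1e-4)

    def test_identical_samples_zero(self):
        x = [1.0, 2.0, 5.0]
        assert welch_t(x, x) == 0.0

    def test_degenerate_zero_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 2, 45)
        expected = stats.ttest_ind(x, y, equal_var=False).statistic
        assert welch_t(x, y) == pytest.approx(expected, abs=1e-12)

    def test_equal_variance_matches_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        pooled = stats.ttest_ind(x, y, equal_var=True).statistic
        assert welch_t(x, y) == pytest.approx(pooled, abs=1e-9)


class TestShuffleLabels:
    def test_zero_proportion_identity(self, rng):
        labels = np.repeat([0, 1], 50)
        np.testing.assert_array_equal(shuffle_labels(labels, 0.0, rng), labels)

    def test_full_shuffle_preserves_multiset(self, rng):
        labels = np.repeat([0, 1], 100)
        out = shuffle_labels(labels, 1.0, rng)
        assert out.sum() == labels.sum()
        assert not np.array_equal(out, labels)  # association randomized

    def test_attenuation_tracks_one_minus_p(self):
        # signal-carrying data: x equals its true label; after shuffling a
        # proportion p, the group mean difference shrinks to ~(1-p)
        rng = np.random.default_rng(5)
        n = 10_000
        labels = np.repeat([0, 1], n)
        x = labels.astype(float)
        for p in (0.2, 0.5):
            lab = shuffle_labels(labels, p, rng)
            diff = x[lab == 1].mean() - x[lab == 0].mean()
            assert diff == pytest.approx(1.0 - p, abs=0.02)


class TestInjectJitter:
    def test_zero_cases(self, rng):
        np.testing.assert_array_equal(inject_jitter(100, 0.0, 0.016, rng), 0.0)
        np.testing.assert_array_equal(inject_jitter(100, 0.5, 0.0, rng), 0.0)

    def test_magnitude_and_count(self, rng):
        e = inject_jitter(200, 0.25, 0.032, rng)
        hit = e != 0
        assert hit.sum() == 50
        np.testing.assert_allclose(np.abs(e[hit]), 0.032)

    def test_rt_variance_inflation(self):
        cfg = SimulationConfig(measure="RT", theta=0.0, n_trials_per_condition=20000)
        rng = np.random.default_rng(7)
        errors = inject_jitter(2 * cfg.n_trials, 1.0, 0.032, rng)
        rt, _ = simulate_rt_trials(cfg, rng, errors)
        expected = cfg.rt_sd_s**2 + 0.032**2
        assert rt.var(ddof=1) == pytest.approx(expected, rel=0.05)


class TestErpTrials:
    def test_zero_noise_matches_analytic_window_mean(self):
        wf = replace(ErpWaveform(), noise_sd=0.0)
        cfg = SimulationConfig(measure="P1", theta=0.4, n_trials_per_condition=3, waveform=wf)
        measured, labels = simulate_erp_trials(cfg, rng=0)
        d_amp = wf.effect_amplitude(0.4)
        for lab in (0, 1):
            expected = wf.measured_template(0.0, (lab - 0.5) * d_amp)
            np.testing.assert_allclose(measured[labels == lab], expected, atol=1e-12)

    def test_jitter_shifts_template_out_of_window(self):
        wf = replace(ErpWaveform(), noise_sd=0.0)
        cfg = SimulationConfig(measure="P1", theta=0.0, n_trials_per_condition=2, waveform=wf)
        errors = np.full(4, 0.050)  # P1 leaves the 90-110 ms window entirely
        measured, _ = simulate_erp_trials(cfg, rng=0, onset_errors=errors)
        clean, _ = simulate_erp_trials(cfg, rng=0)
        assert np.all(np.abs(measured) < np.abs(clean))

    def test_window_outside_epoch_rejected(self):
        wf = replace(ErpWaveform(), window=(0.6, 0.7))
        with pytest.raises(ValueError, match="outside the epoch"):
            SimulationConfig(measure="P1", waveform=wf).waveform.window_mask

    def test_reduced_sampler_matches_full_waveform_path(self):
        # same cell simulated via full epochs and via the exact reduced
        # form; the mean t must agree within combined Monte-Carlo error
        kw = dict(
            measure="P1", theta=0.5, corruption="jitter",
            n_trials_per_condition=40, reps=400,
        )
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        fast = _cell_ts(SimulationConfig(**kw), 0.5, 0.3, 0.016, rng1, 400)
        full = _cell_ts(
            SimulationConfig(waveform_fidelity=True, **kw), 0.5, 0.3, 0.016, rng2, 400
        )
        se = np.hypot(fast.std(ddof=1), full.std(ddof=1)) / np.sqrt(400)
        assert abs(fast.mean() - full.mean()) < 3.5 * se


class TestRtTrials:
    def test_null_theta_centers_on_zero(self):
        cfg = SimulationConfig(measure="RT", theta=0.0, reps=300)
        rng = np.random.default_rng(3)
        ts = _cell_ts(cfg, 0.0, 0.0, 0.0, rng, 300)
        assert abs(ts.mean()) < 3.0 / np.sqrt(300)
        assert ts.std(ddof=1) == pytest.approx(1.0, abs=0.15)

    def test_uncorrupted_t_matches_analytic_expectation(self):
        # theta=0.2 at n=210/condition -> E[t] ~ 0.2*sqrt(105) = 2.05
        cfg = SimulationConfig(
            measure="RT", theta=0.2, n_trials_per_condition=210, reps=600
        )
        rng = np.random.default_rng(4)
        ts = _cell_ts(cfg, 0.2, 0.0, 0.0, rng, 600)
        assert ts.mean() == pytest.approx(0.2 * np.sqrt(105), rel=0.05)

    def test_large_effect_matches_analytic_expectation(self):
        # theta=0.5 at n=500/condition -> E[t] ~ 0.5*sqrt(250) = 7.91
        cfg = SimulationConfig(
            measure="RT", theta=0.5, n_trials_per_condition=500, reps=200
        )
        rng = np.random.default_rng(5)
        ts = _cell_ts(cfg, 0.5, 0.0, 0.0, rng, 200)
        assert ts.mean() == pytest.approx(0.5 * np.sqrt(250), rel=0.05)


class TestSweep:
    def _small_config(self, **kw):
        defaults = dict(
            measure="RT", corruption="shuffle", theta=0.3,
            n_trials_per_condition=60, reps=40,
            proportions=(0.0, 0.2, 0.5), seed=99,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_deterministic_under_fixed_seed(self):
        a = run_sweep(self._small_config()).table
        b = run_sweep(self._small_config()).table
        pd.testing.assert_frame_equal(a, b)

    def test_mean_t_non_increasing_in_shuffle_proportion(self):
        cfg = self._small_config(
            theta=0.5, n_trials_per_condition=200, reps=300,
            proportions=(0.0, 0.2, 0.4, 0.8),
        )
        tab = run_sweep(cfg).table.sort_values("proportion")
        se = (tab["sd_t"] / np.sqrt(tab["reps"])).to_numpy()
        mt = tab["mean_t"].to_numpy()
        assert np.all(np.diff(mt) <= 2 * np.hypot(se[:-1], se[1:]))

    def test_null_theta_row_centers_on_zero(self):
        cfg = self._small_config(theta=0.0, reps=200, proportions=(0.0, 0.3))
        tab = run_sweep(cfg).table
        assert np.all(np.abs(tab["mean_t"]) < 3.0 / np.sqrt(200))

    def test_boundary_rules(self):
        cfg = self._small_config()
        tbl = pd.DataFrame(
            {
                "theta": 0.2,
                "magnitude_ms": 0.0,
                "proportion": [0.02, 0.05, 0.10, 0.15],
                "mean_t": [2.4, 2.1, 1.99, 1.7],
                "sd_t": 1.0,
                "reps": 100,
            }
        )
        sweep = SweepResult(tbl, 1.96, cfg)
        assert significance_boundary(sweep, 0.2) == 0.15
        # brute-force oracle over the column
        col = tbl.sort_values("proportion")
        oracle = next(
            (p for p, t in zip(col["proportion"], col["mean_t"]) if t < 1.96), None
        )
        assert significance_boundary(sweep, 0.2) == oracle
        tbl_high = tbl.assign(mean_t=[3.0, 2.9, 2.8, 2.7])
        assert significance_boundary(SweepResult(tbl_high, 1.96, cfg), 0.2) is None
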