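"""Generator tests: learner closed forms, schedule structure, noise spectrum,
injected beta effects, and the cat trial stream."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import signal as sps

from betaadapt.behavior import assign_epochs
from betaadapt.containers import PipelineError, PreMovementWindowSpec
from betaadapt.preprocess import (
    extract_windows,
    filter_chain,
    hjorth_laplacian,
)
from betaadapt.spectral import premovement_beta, transform_windows
from betaadapt.synth import (
    AdaptationParams,
    CatTaskConfig,
    TaskConfig,
    default_human_neural_config,
    simulate_behavior,
    simulate_cat_stream,
    simulate_recording,
)


def adaptation_errors(df: pd.DataFrame) -> np.ndarray:
    return df.loc[df["phase"] == "adaptation", "endpoint_error_deg"].to_numpy()


class TestLearner:
    def test_geometric_decay_when_full_retention(self, noise_free_params):
        # with A=1 the perceived error follows e_{n+1} = (1-B) e_n
        task = TaskConfig(rotation_deg=30.0)
        p = AdaptationParams(
            retention=1.0, learning_rate=0.2, motor_noise_sd_deg=0.0
        )
        df, _ = simulate_behavior(task, p, 0)
        err = adaptation_errors(df)
        np.testing.assert_allclose(err[:3], [-30.0, -24.0, -19.2], atol=1e-10)

    def test_no_learning_keeps_error_constant(self):
        task = TaskConfig(rotation_deg=30.0)
        p = AdaptationParams(
            retention=1.0, learning_rate=0.0, motor_noise_sd_deg=0.0
        )
        df, _ = simulate_behavior(task, p, 0)
        np.testing.assert_allclose(adaptation_errors(df), -30.0, atol=1e-12)

    def test_asymptote_matches_fixed_point_and_brute_force(self):
        # closed form r (1-A)/(1-A+B) vs iterating the recursion directly
        A, B, r = 0.98, 0.2, 30.0
        fixed_point = r * (1 - A) / (1 - A + B)
        e = r
        for _ in range(10_000):
            x = r - e
            x = A * x + B * e
            e = r - x
        assert abs(e - fixed_point) < 1e-10

        task = TaskConfig(n_adaptation=10_000, rotation_deg=r)
        p = AdaptationParams(
            retention=A, learning_rate=B, motor_noise_sd_deg=0.0
        )
        df, _ = simulate_behavior(task, p, 0)
        assert abs(adaptation_errors(df)[-1] + fixed_point) < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        A=st.floats(0.9, 1.0),
        B=st.floats(0.05, 1.0),
    )
    def test_monotone_decay_and_negative_aftereffect(self, A, B):
        # B <= A keeps the learner in the non-oscillatory regime; with
        # B > A the state overshoots the rotation and |error| can rebound
        assume(B <= A)
        task = TaskConfig(n_baseline=20, n_adaptation=100, n_washout=20)
        p = AdaptationParams(retention=A, learning_rate=B, motor_noise_sd_deg=0.0)
        df, _ = simulate_behavior(task, p, 0)
        err = np.abs(adaptation_errors(df))
        assert np.all(np.diff(err) <= 1e-12)
        first_adapt = adaptation_errors(df)[0]
        first_wash = df.loc[df["phase"] == "washout", "endpoint_error_deg"].iloc[0]
        if B < 1.0:  # B=1 adapts fully in one trial, leaving no aftereffect
            assert np.sign(first_wash) == -np.sign(first_adapt)

    def test_state_trajectory_returned(self, small_task, noise_free_params):
        df, truth = simulate_behavior(small_task, noise_free_params, 0)
        assert truth.state_deg.shape == (len(df),)
        assert truth.state_deg[0] == 0.0


class TestSchedule:
    def test_target_blocks_balanced(self, session_600):
        df, _ = session_600
        task = TaskConfig()
        n_per = task.block_size // len(task.target_angles_deg)
        for b in range(len(df) // task.block_size):
            block = df["target_deg"].iloc[
                b * task.block_size : (b + 1) * task.block_size
            ]
            assert block.value_counts().eq(n_per).all()

    def test_same_seed_bit_identical(self, small_task):
        p = AdaptationParams()
        df1, _ = simulate_behavior(small_task, p, 42)
        df2, _ = simulate_behavior(small_task, p, 42)
        pd.testing.assert_frame_equal(df1, df2)

    def test_bad_block_size_rejected(self):
        with pytest.raises(PipelineError):
            TaskConfig(block_size=18)


class TestRecording:
    def test_same_seed_bit_identical(self, small_task, fast_neural):
        df, _ = simulate_behavior(small_task, AdaptationParams(), 1)
        r1, g1 = simulate_recording(df, fast_neural, 7)
        r2, g2 = simulate_recording(df, fast_neural, 7)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        pd.testing.assert_frame_equal(r1.events, r2.events)
        np.testing.assert_array_equal(g1.beta_multiplier, g2.beta_multiplier)

    def test_event_markers_centre_their_windows(self, small_task, fast_neural):
        df, _ = simulate_behavior(small_task, AdaptationParams(), 1)
        rec, _ = simulate_recording(df, fast_neural, 7)
        filt, fs = filter_chain(hjorth_laplacian(rec, "C3"), rec.fs)
        windows = extract_windows(filt, fs, rec.events, 1.0)
        assert len(windows) == len(df)
        n = windows[0].samples.size
        for w in windows:
            assert w.samples.size == n
            assert w.t0_s == (n // 2) / fs

    def test_overlapping_trials_rejected(self, small_task):
        df, _ = simulate_behavior(small_task, AdaptationParams(), 1)
        cfg = default_human_neural_config(fs_raw=1000.0, iti_s=0.5)
        with pytest.raises(PipelineError, match="overlap"):
            simulate_recording(df, cfg, 7)

    def test_noise_spectral_slope_matches_exponent(self):
        # periodogram log-log regression over 1-100 Hz, beta disabled
        cfg = default_human_neural_config(
            fs_raw=1000.0, beta_rms=0.0, noise_exponent=1.0
        )
        df = pd.DataFrame(
            {
                "trial_index": np.arange(1, 41),
                "epoch": "none",
                "rt_ms": 300.0,
                "duration_ms": 350.0,
            }
        )
        rec, _ = simulate_recording(df, cfg, 3)
        f, pxx = sps.welch(rec.channel("C3"), fs=rec.fs, nperseg=4096)
        sel = (f >= 1.0) & (f <= 100.0)
        slope = np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)[0]
        assert abs(-slope - 1.0) < 0.2

    def _premovement_stat(self, trials, cfg, seed, zscore=False):
        from betaadapt.preprocess import zscore_window

        rec, _ = simulate_recording(trials, cfg, seed)
        filt, fs = filter_chain(hjorth_laplacian(rec, "C3"), rec.fs)
        wins = extract_windows(filt, fs, rec.events, 1.0)
        if zscore:
            wins = [zscore_window(w) for w in wins]
        tf = transform_windows(wins)
        return premovement_beta(tf, trials, PreMovementWindowSpec())

    def test_epoch_gain_appears_as_log_power_shift(self, noise_free_params):
        # amplitude gain g on a noise-free recording shifts the band-mean
        # log power by 2 ln g (small slack for envelope-transition smearing)
        task = TaskConfig(n_baseline=80, n_adaptation=80, n_washout=80)
        trials, _ = simulate_behavior(task, noise_free_params, 5)
        trials, _ = assign_epochs(trials, epoch_len=36)
        cfg = default_human_neural_config(
            fs_raw=1000.0,
            noise_rms=0.0,
            beta_epoch_gain={"EA": 0.75},
        )
        beta = self._premovement_stat(trials, cfg, 6)
        trials = trials.assign(b=trials["trial_index"].map(beta))
        m = trials.groupby("epoch")["b"].mean()
        diff = m["EA"] - m["Baseline"]
        assert abs(diff - 2.0 * np.log(0.75)) < 0.08

    def test_zero_beta_amplitude_sits_at_noise_floor(self, small_task):
        # beta off vs pure noise: pre-movement band power indistinguishable
        from scipy.stats import ttest_ind

        task = TaskConfig(n_baseline=40, n_adaptation=40, n_washout=40)
        trials, _ = simulate_behavior(task, AdaptationParams(), 8)
        trials, _ = assign_epochs(trials, epoch_len=20)
        cfg = default_human_neural_config(fs_raw=1000.0, beta_rms=0.0)
        a = self._premovement_stat(trials, cfg, 9).dropna()
        b = self._premovement_stat(trials, cfg, 10).dropna()
        assert len(a) >= 100
        assert ttest_ind(a, b).pvalue > 0.05


class TestCatStream:
    def test_zero_miss_rate_ends_prism_at_streak(self):
        cfg = CatTaskConfig(
            miss_rate_by_phase={"baseline": 0.0, "prism": 0.0, "post": 0.0}
        )
        df = simulate_cat_stream(cfg, 0)
        prism = df[df["phase"] == "prism"]
        assert len(prism) == cfg.streak_to_remove
        assert df["converged"].all()

    def test_certain_miss_hits_cap_and_flags_non_convergence(self):
        cfg = CatTaskConfig(
            miss_rate_by_phase={"baseline": 0.0, "prism": 1.0, "post": 0.0},
            prism_adaptation_tau=None,
            max_prism_trials=50,
        )
        df = simulate_cat_stream(cfg, 0)
        assert (df["phase"] == "prism").sum() == 50
        assert not df["converged"].any()

    def test_long_run_miss_fraction_matches_probability(self):
        p = 0.3
        cfg = CatTaskConfig(
            n_baseline=10_000,
            n_post=0,
            miss_rate_by_phase={"baseline": p, "prism": 1.0},
            prism_adaptation_tau=None,
            max_prism_trials=1,
        )
        df = simulate_cat_stream(cfg, 11)
        base = df[df["phase"] == "baseline"]
        frac = (base["category"] == "miss").mean()
        se = np.sqrt(p * (1 - p) / len(base))
        assert abs(frac - p) < 3 * se

    def test_epoch_mapping_follows_hit_miss_rules(self):
        df = simulate_cat_stream(CatTaskConfig(), 4)
        assert (
            df.loc[df["epoch"] == "EA", "category"].eq("miss").all()
        )
        assert (
            df.loc[df["epoch"] == "LA", "phase"].eq("prism").all()
        )
        assert (
            df.loc[df["epoch"] == "Baseline", "phase"].eq("baseline").all()
        )
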