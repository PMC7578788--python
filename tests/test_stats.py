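"""Inferential battery: rank correlations, error regression, covariate-
adjusted epoch contrasts, and the balanced bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from betaadapt.containers import PipelineError
from betaadapt.stats import (
    bootstrap_balanced,
    correlate_beta_kinematics,
    epoch_contrast,
    regress_beta_error,
)


class TestSpearman:
    def test_perfect_monotone_gives_unit_rho(self):
        beta = np.array([1.0, 2.5, 3.0, 7.0, 9.0, 12.0])
        rt = beta**3 + 5.0  # monotone transform
        dur = -beta
        out = correlate_beta_kinematics(beta, rt, dur)
        assert out["reaction_time"].rho == pytest.approx(1.0)
        assert out["duration"].rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        beta = np.round(rng.normal(size=40), 1)  # force ties
        rt = np.round(rng.normal(size=40), 1)
        out = correlate_beta_kinematics(beta, rt, np.arange(40.0))
        ranks_b = sps.rankdata(beta)  # average-rank tie handling
        ranks_r = sps.rankdata(rt)
        expected = np.corrcoef(ranks_b, ranks_r)[0, 1]
        assert out["reaction_time"].rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_flagged(self):
        out = correlate_beta_kinematics(
            np.ones(10), np.arange(10.0), np.arange(10.0)
        )
        assert not out["reaction_time"].ok
        assert np.isnan(out["reaction_time"].rho)

    def test_too_few_trials_rejected(self):
        with pytest.raises(PipelineError):
            correlate_beta_kinematics(
                np.arange(4.0), np.arange(4.0), np.arange(4.0)
            )


class TestErrorRegression:
    def test_exact_linear_relation(self):
        beta = np.arange(10.0)
        out = regress_beta_error(beta, 2.0 * beta + 1.0)
        assert out.r_squared == pytest.approx(1.0)
        assert out.p < 1e-10
        assert out.df == (1, 8)

    def test_orthogonal_residuals_give_zero_f(self):
        beta = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        err = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # orthogonal to beta
        out = regress_beta_error(beta, err)
        assert out.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        beta = rng.normal(size=30)
        err = 0.3 * beta + rng.normal(size=30)
        out = regress_beta_error(beta, err)
        r = np.corrcoef(beta, err)[0, 1]
        expected_f = (r**2 / (1 - r**2)) * (30 - 2)
        assert out.F == pytest.approx(expected_f, rel=1e-10)
        assert out.p == pytest.approx(
            sps.f.sf(expected_f, 1, 28), rel=1e-10
        )

    def test_zero_variance_predictor_flagged(self):
        out = regress_beta_error(np.ones(10), np.arange(10.0))
        assert not out.ok


def build_table(rng, n_per=20, offsets=(0.0, -0.4, 0.1), noise=0.0,
                rt_coef=0.0, dur_coef=0.0):
    rows = []
    for epoch, off in zip(("Baseline", "EA", "LA"), offsets):
        rt = rng.uniform(250, 400, n_per)
        dur = rng.uniform(300, 450, n_per)
        beta = (
            2.0 + off + rt_coef * rt + dur_coef * dur
            + noise * rng.normal(size=n_per)
        )
        for i in range(n_per):
            rows.append(
                {"epoch": epoch, "beta_logpower": beta[i],
                 "rt_ms": rt[i], "duration_ms": dur[i]}
            )
    return pd.DataFrame(rows)


class TestEpochContrast:
    def test_noise_free_offsets_recovered_exactly(self):
        rng = np.random.default_rng(0)
        df = build_table(rng, offsets=(0.0, -0.5, 0.2),
                         rt_coef=0.001, dur_coef=-0.002)
        res = epoch_contrast(df, epoch_order=["Baseline", "EA", "LA"])
        pc = res.pair("EA", "Baseline")
        est = pc.estimate if pc.epoch_a == "EA" else -pc.estimate
        assert est == pytest.approx(-0.5, abs=1e-8)
        pc = res.pair("LA", "Baseline")
        est = pc.estimate if pc.epoch_a == "LA" else -pc.estimate
        assert est == pytest.approx(0.2, abs=1e-8)
        # covariate slopes recovered too
        cov = dict((name, coef) for name, coef, _ in res.covariates)
        assert cov["rt_ms"] == pytest.approx(0.001, abs=1e-8)
        assert cov["duration_ms"] == pytest.approx(-0.002, abs=1e-8)

    def test_equal_adjusted_means_give_zero_f(self):
        # both epochs contain byte-identical observations, so the epoch
        # dummy is orthogonal to the response and its partial F vanishes
        rng = np.random.default_rng(1)
        rt = rng.uniform(250, 400, 15)
        dur = rng.uniform(300, 450, 15)
        beta = rng.normal(size=15)
        df = pd.DataFrame(
            {
                "epoch": ["A"] * 15 + ["B"] * 15,
                "beta_logpower": np.tile(beta, 2),
                "rt_ms": np.tile(rt, 2),
                "duration_ms": np.tile(dur, 2),
            }
        )
        res = epoch_contrast(df, epoch_order=["A", "B"])
        assert res.omnibus_F == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        df = build_table(rng, n_per=12, noise=0.3)
        res = epoch_contrast(df, epoch_order=["Baseline", "EA", "LA"])
        # explicit Gram-matrix solve of the same design
        d_ea = (df["epoch"] == "EA").to_numpy(float)
        d_la = (df["epoch"] == "LA").to_numpy(float)
        X = np.column_stack(
            [np.ones(len(df)), d_ea, d_la, df["rt_ms"], df["duration_ms"]]
        )
        y = df["beta_logpower"].to_numpy()
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        pc = res.pair("EA", "Baseline")
        est = pc.estimate if pc.epoch_a == "EA" else -pc.estimate
        assert est == pytest.approx(coef[1], abs=1e-8)
        cov = dict((name, c) for name, c, _ in res.covariates)
        assert cov["rt_ms"] == pytest.approx(coef[3], abs=1e-8)

    def test_bonferroni_over_all_pairs(self):
        rng = np.random.default_rng(3)
        df = build_table(rng, noise=0.5)
        res = epoch_contrast(df, epoch_order=["Baseline", "EA", "LA"])
        assert len(res.pairwise) == 3
        for pc in res.pairwise:
            assert pc.p_bonferroni == pytest.approx(
                min(1.0, pc.p_raw * 3), abs=1e-12
            )

    def test_five_epochs_give_ten_pairs(self):
        rng = np.random.default_rng(4)
        frames = []
        for e in ("Baseline", "EA", "LA", "EAft", "LAft"):
            d = build_table(rng, n_per=8, noise=0.5)
            d["epoch"] = e
            frames.append(d)
        res = epoch_contrast(pd.concat(frames, ignore_index=True))
        assert len(res.pairwise) == 10

    def test_rank_deficient_design_names_alias(self):
        rng = np.random.default_rng(5)
        df = build_table(rng, noise=0.2)
        df["duration_ms"] = 2.0 * df["rt_ms"]  # aliased covariate
        with pytest.raises(PipelineError, match="aliased"):
            epoch_contrast(df, epoch_order=["Baseline", "EA", "LA"])

    def test_small_epoch_rejected(self):
        df = build_table(np.random.default_rng(6), n_per=2)
        with pytest.raises(PipelineError, match="3 trials"):
            epoch_contrast(df, epoch_order=["Baseline", "EA", "LA"])

    def test_subject_factor_absorbs_between_subject_shifts(self):
        rng = np.random.default_rng(7)
        frames = []
        for s, shift in enumerate((0.0, 1.0, -2.0)):
            d = build_table(rng, n_per=10, offsets=(0.0, -0.5, 0.0), noise=0.0)
            d["beta_logpower"] += shift
            d["subject"] = f"s{s}"
            frames.append(d)
        df = pd.concat(frames, ignore_index=True)
        res = epoch_contrast(
            df, subject_col="subject", epoch_order=["Baseline", "EA", "LA"]
        )
        pc = res.pair("EA", "Baseline")
        est = pc.estimate if pc.epoch_a == "EA" else -pc.estimate
        assert est == pytest.approx(-0.5, abs=1e-8)


class TestBootstrap:
    def test_identical_observations_give_degenerate_ci(self):
        data = {"a": np.full(10, 2.0), "b": np.full(6, 2.0)}
        res = bootstrap_balanced(data, n_boot=200, seed=0)
        pc = res.pairwise[0]
        assert pc.ci_low == pc.ci_high == 0.0
        assert pc.p_bonferroni == 1.0
        assert res.m_per_condition == 6

    def test_bootstrap_mean_consistent_with_sample_mean(self):
        rng = np.random.default_rng(1)
        data = {"a": rng.normal(1.0, 1.0, 80), "b": rng.normal(0.0, 1.0, 40)}
        res = bootstrap_balanced(data, n_boot=1000, seed=2)
        for name, arr in data.items():
            mean, se = res.conditions[name]
            assert abs(mean - arr.mean()) < 3 * se

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(3)
        data = {"a": rng.normal(size=30), "b": rng.normal(size=20)}
        r1 = bootstrap_balanced(data, n_boot=500, seed=9)
        r2 = bootstrap_balanced(data, n_boot=500, seed=9)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)

    def test_clear_separation_is_detected(self):
        rng = np.random.default_rng(4)
        data = {
            "lo": rng.normal(0.0, 0.5, 50),
            "hi": rng.normal(3.0, 0.5, 50),
        }
        res = bootstrap_balanced(data, n_boot=1000, seed=5)
        pc = res.pairwise[0]
        assert pc.p_bonferroni < 0.01
        assert not (pc.ci_low <= 0.0 <= pc.ci_high)

    def test_single_trial_condition_flagged_not_fatal(self):
        data = {"a": np.arange(10.0), "b": np.array([1.0])}
        res = bootstrap_balanced(data, n_boot=100, seed=6)
        assert any("degenerate" in f for f in res.flags)

    def test_empty_condition_rejected(self):
        with pytest.raises(PipelineError, match="empty"):
            bootstrap_balanced({"a": np.arange(3.0), "b": np.array([])})
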