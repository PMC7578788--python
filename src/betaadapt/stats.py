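"""Inferential battery on per-trial beta-power tables.

Four analyses mirror the study design around epoch-wise beta power:

* Spearman rank correlations between the pre-movement beta statistic and
  the upcoming reach kinematics (reaction time, reach duration);
* a simple regression of beta power on subsequent endpoint-error magnitude;
* a covariate-adjusted fixed-effects linear model (ANCOVA)
  ``beta ~ epoch + rt + duration (+ subject)`` with an omnibus partial F for
  the epoch factor and Bonferroni-corrected pairwise contrasts of adjusted
  epoch means;
* a balanced bootstrap that resamples every condition down to the smallest
  group size, for unbalanced designs such as the cat hit/miss epochs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .containers import (
    BootstrapResult,
    ContrastResult,
    PairwiseBootstrap,
    PairwiseContrast,
    PipelineError,
)

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "correlate_beta_kinematics",
    "regress_beta_error",
    "epoch_contrast",
    "bootstrap_balanced",
]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    ok: bool = True
    note: str | None = None


@dataclass
class RegressionResult:
    F: float
    df: tuple[int, int]
    p: float
    slope: float
    r_squared: float
    ok: bool = True
    note: str | None = None


def _spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            rho=float("nan"), p=float("nan"), n=x.size, ok=False,
            note="constant input, correlation undefined",
        )
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=x.size)


def correlate_beta_kinematics(
    beta: np.ndarray, rt_ms: np.ndarray, duration_ms: np.ndarray
) -> dict[str, CorrelationResult]:
    """Spearman correlation of beta power with reaction time and duration.

    Average ranks handle ties; p-values come from the t-approximation.
    Only trials complete on all three measures enter.
    """
    beta = np.asarray(beta, dtype=float)
    rt = np.asarray(rt_ms, dtype=float)
    dur = np.asarray(duration_ms, dtype=float)
    keep = np.isfinite(beta) & np.isfinite(rt) & np.isfinite(dur)
    if keep.sum() < 5:
        raise PipelineError("need at least 5 complete trials")
    return {
        "reaction_time": _spearman(beta[keep], rt[keep]),
        "duration": _spearman(beta[keep], dur[keep]),
    }


def regress_beta_error(
    beta: np.ndarray, abs_error_deg: np.ndarray
) -> RegressionResult:
    """F-test of the slope in ``|error| ~ beta`` (simple linear regression)."""
    beta = np.asarray(beta, dtype=float)
    err = np.asarray(abs_error_deg, dtype=float)
    keep = np.isfinite(beta) & np.isfinite(err)
    beta, err = beta[keep], err[keep]
    n = beta.size
    if n < 3:
        raise PipelineError("need at least 3 complete trials")
    if np.ptp(beta) == 0:
        return RegressionResult(
            F=float("nan"), df=(1, n - 2), p=float("nan"), slope=float("nan"),
            r_squared=float("nan"), ok=False, note="zero-variance predictor",
        )
    res = sps.linregress(beta, err)
    r2 = res.rvalue**2
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (r2 / (1.0 - r2)) * (n - 2)
        p = float(sps.f.sf(f_stat, 1, n - 2))
    return RegressionResult(
        F=float(f_stat), df=(1, n - 2), p=p, slope=float(res.slope),
        r_squared=float(r2),
    )


def _aliased_columns(exog: np.ndarray, names: Sequence[str]) -> list[str]:
    _, r = np.linalg.qr(exog)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(exog.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def epoch_contrast(
    trials: pd.DataFrame,
    value_col: str = "beta_logpower",
    epoch_col: str = "epoch",
    covariate_cols: Sequence[str] = ("rt_ms", "duration_ms"),
    subject_col: str | None = None,
    epoch_order: Sequence[str] | None = None,
) -> ContrastResult:
    """Covariate-adjusted epoch contrast.

    Fits ``value ~ C(epoch) + covariates (+ C(subject))`` by least squares,
    reports the partial F for the epoch factor and all pairwise differences
    of covariate-adjusted epoch means with Bonferroni correction over the
    number of pairs.  Estimates are ``epoch_a - epoch_b`` on the value scale
    (log-power units for the beta statistic).
    """
    needed = [value_col, epoch_col, *covariate_cols]
    if subject_col:
        needed.append(subject_col)
    if missing := set(needed) - set(trials.columns):
        raise PipelineError(f"missing columns: {sorted(missing)}")
    data = trials.loc[trials[epoch_col] != "none", needed].dropna().copy()

    levels = [
        e for e in (epoch_order or pd.unique(data[epoch_col]))
        if e in set(data[epoch_col])
    ]
    counts = data[epoch_col].value_counts()
    small = [e for e in levels if counts.get(e, 0) < 3]
    if len(levels) < 2 or small:
        raise PipelineError(
            f"need >= 2 epochs with >= 3 trials each (too small: {small})"
        )
    data[epoch_col] = pd.Categorical(data[epoch_col], categories=levels)

    terms = [f"C({epoch_col})"] + list(covariate_cols)
    if subject_col:
        terms.append(f"C({subject_col})")
    formula = f"Q('{value_col}') ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        aliased = _aliased_columns(model.exog, model.exog_names)
        raise PipelineError(f"rank-deficient design; aliased: {aliased}")
    fit = model.fit()

    table = anova_lm(fit, typ=2)
    row = table.loc[f"C({epoch_col})"]
    omnibus_f = float(row["F"])
    df_num = float(row["df"])
    df_den = float(table.loc["Residual", "df"])
    p_omni = float(row["PR(>F)"])

    dummy_idx = {
        lvl: i
        for i, name in enumerate(model.exog_names)
        for lvl in levels
        if name == f"C({epoch_col})[T.{lvl}]"
    }
    pairs = list(itertools.combinations(levels, 2))
    pairwise = []
    for a, b in pairs:
        vec = np.zeros(len(model.exog_names))
        if a in dummy_idx:
            vec[dummy_idx[a]] += 1.0
        if b in dummy_idx:
            vec[dummy_idx[b]] -= 1.0
        tt = fit.t_test(vec)
        p_raw = float(np.squeeze(tt.pvalue))
        pairwise.append(
            PairwiseContrast(
                epoch_a=a,
                epoch_b=b,
                estimate=float(np.squeeze(tt.effect)),
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * len(pairs)),
            )
        )

    covariates = [
        (c, float(fit.params[c]), float(fit.pvalues[c]))
        for c in covariate_cols
    ]
    return ContrastResult(
        omnibus_F=omnibus_f,
        df=(df_num, df_den),
        p=p_omni,
        pairwise=pairwise,
        covariates=covariates,
        n_obs=int(fit.nobs),
    )


def bootstrap_balanced(
    data: Mapping[str, np.ndarray],
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> BootstrapResult:
    """Balanced bootstrap of condition means.

    Every replicate draws ``m = min(group sizes)`` observations with
    replacement from each condition, so comparisons are balanced regardless
    of the raw group sizes.  Reports per-condition bootstrap mean and SE,
    2.5/97.5 percentile CIs of pairwise mean differences, and two-sided
    empirical p-values with Bonferroni correction over the pairs.
    """
    if len(data) < 2:
        raise PipelineError("need at least 2 conditions")
    arrays = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    arrays = {k: v[np.isfinite(v)] for k, v in arrays.items()}
    if any(v.size == 0 for v in arrays.values()):
        empty = [k for k, v in arrays.items() if v.size == 0]
        raise PipelineError(f"empty condition(s): {empty}")
    flags = [
        f"degenerate resampling: condition {k!r} has a single trial"
        for k, v in arrays.items()
        if v.size == 1
    ]
    m = min(v.size for v in arrays.values())
    rng = np.random.default_rng(seed)

    boot_means = {}
    for name, arr in arrays.items():
        idx = rng.integers(0, arr.size, size=(n_boot, m))
        boot_means[name] = arr[idx].mean(axis=1)

    conditions = {
        name: (float(bm.mean()), float(bm.std(ddof=1)))
        for name, bm in boot_means.items()
    }
    pairs = list(itertools.combinations(arrays, 2))
    pairwise = []
    for a, b in pairs:
        d = boot_means[a] - boot_means[b]
        lo, hi = np.percentile(d, [2.5, 97.5])
        p_raw = min(1.0, 2.0 * min(np.mean(d <= 0), np.mean(d >= 0)))
        pairwise.append(
            PairwiseBootstrap(
                cond_a=a,
                cond_b=b,
                diff_mean=float(d.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                p_raw=float(p_raw),
                p_bonferroni=min(1.0, float(p_raw) * len(pairs)),
            )
        )
    return BootstrapResult(
        n_boot=n_boot,
        m_per_condition=int(m),
        conditions=conditions,
        pairwise=pairwise,
        flags=flags,
    )
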