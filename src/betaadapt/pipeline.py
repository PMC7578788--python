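"""End-to-end orchestration: simulate -> preprocess -> spectral -> stats.

A :class:`RunConfig` (usually loaded from YAML) fully determines a run; the
single seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence`` spawning, so any stage can be re-run on its
own yet the whole pipeline is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import classify_trial_cat, extract_epochs
from .containers import (
    CAT_EPOCHS,
    HUMAN_EPOCHS,
    PipelineError,
    PreMovementWindowSpec,
    Recording,
)
from .io import save_recording, write_json, write_trials
from .preprocess import (
    bipolar_rereference,
    extract_windows,
    filter_chain,
    hjorth_laplacian,
    zscore_window,
)
from .spectral import DEFAULT_FREQ_GRID, premovement_beta, transform_windows
from .stats import (
    bootstrap_balanced,
    correlate_beta_kinematics,
    epoch_contrast,
    regress_beta_error,
)
from .synth import (
    AdaptationParams,
    CatTaskConfig,
    NeuralConfig,
    TaskConfig,
    default_cat_neural_config,
    default_human_neural_config,
    simulate_behavior,
    simulate_cat_stream,
    simulate_recording,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "simulate_session_table",
    "load_config",
]

logger = logging.getLogger(__name__)

# stage order for seed spawning: behaviour, recording, bootstrap
_N_STAGE_SEEDS = 3


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    mode: str = "human"
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    cat_task: CatTaskConfig = field(default_factory=CatTaskConfig)
    neural: NeuralConfig | None = None
    window: PreMovementWindowSpec | None = None
    n_boot: int = 1000
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("human", "cat"):
            raise PipelineError(f"mode must be 'human' or 'cat', got {self.mode!r}")
        if self.neural is None:
            self.neural = (
                default_human_neural_config()
                if self.mode == "human"
                else default_cat_neural_config()
            )
        if self.window is None:
            self.window = PreMovementWindowSpec(
                mode="reaction_time" if self.mode == "human" else "fixed"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(str(type(o)))


def _build_section(cls, values: dict, section: str):
    try:
        return cls(**values)
    except TypeError as exc:
        raise PipelineError(f"invalid field in config section {section!r}: {exc}")


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from a YAML file; ``seed`` overrides the file's."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    mode = raw.get("mode", "human")
    neural = raw.get("neural")
    if neural is not None:
        maker = (
            default_human_neural_config
            if mode == "human"
            else default_cat_neural_config
        )
        try:
            neural = maker(**neural)
        except TypeError as exc:
            raise PipelineError(f"invalid field in config section 'neural': {exc}")
    window = raw.get("window")
    if window is not None:
        window = _build_section(PreMovementWindowSpec, window, "window")
    cfg = RunConfig(
        mode=mode,
        seed=int(raw.get("seed", 0)) if seed is None else int(seed),
        task=_build_section(TaskConfig, raw.get("task", {}), "task"),
        adaptation=_build_section(
            AdaptationParams, raw.get("adaptation", {}), "adaptation"
        ),
        cat_task=_build_section(CatTaskConfig, raw.get("cat_task", {}), "cat_task"),
        neural=neural,
        window=window,
        n_boot=int(raw.get("n_boot", 1000)),
        output_dir=raw.get("output_dir"),
    )
    unknown = set(raw) - {
        "mode", "seed", "task", "adaptation", "cat_task", "neural",
        "window", "n_boot", "output_dir",
    }
    if unknown:
        raise PipelineError(f"unknown config field(s): {sorted(unknown)}")
    return cfg


def _simulate_trials(cfg: RunConfig, seed) -> pd.DataFrame:
    if cfg.mode == "human":
        trials, _ = simulate_behavior(cfg.task, cfg.adaptation, seed)
        return trials
    trials = simulate_cat_stream(cfg.cat_task, seed)
    # session-level rejection rules, then epochs only for retained reaches
    scored = trials[trials["category"].isin(["hit", "miss"])]
    dur_mean = float(scored["duration_ms"].mean())
    dur_sd = float(scored["duration_ms"].std(ddof=1))
    cats, reasons = [], []
    for row in trials.itertuples():
        cat, reason = classify_trial_cat(
            row.rt_ms, row.duration_ms, row.category, dur_mean, dur_sd
        )
        cats.append(cat)
        reasons.append(reason or "")
    trials = trials.assign(category=cats, reject_reason=reasons)
    trials.loc[trials["category"] == "rejected", "epoch"] = "none"
    return trials


def _derive(cfg: RunConfig, rec: Recording) -> np.ndarray:
    if cfg.mode == "human":
        return hjorth_laplacian(rec, cfg.neural.beta_channel)
    a, b = rec.channel_names[0], rec.channel_names[1]
    return bipolar_rereference(rec, a, b)


def derive_and_window(cfg: RunConfig, rec: Recording):
    """Spatial derivation -> filter chain -> z-scored 2 s windows."""
    series = _derive(cfg, rec)
    filtered, fs = filter_chain(series, rec.fs)
    events = rec.events.copy()
    windows = extract_windows(
        filtered, fs, events, cfg.neural.window_halfwidth_s
    )
    return [zscore_window(w) for w in windows]


def compute_beta_statistic(
    cfg: RunConfig, windows, trials: pd.DataFrame
) -> pd.DataFrame:
    """Morlet band log-power -> per-trial pre-movement statistic column."""
    tf = transform_windows(windows, DEFAULT_FREQ_GRID, time_decim=4)
    beta = premovement_beta(tf, trials, cfg.window)
    out = trials.copy()
    out["beta_logpower"] = out["trial_index"].map(beta)
    return out


def run_stats(cfg: RunConfig, trials: pd.DataFrame, seed) -> dict:
    """The inferential battery on a finished trial table."""
    epoch_order = HUMAN_EPOCHS if cfg.mode == "human" else CAT_EPOCHS
    in_epoch = trials[trials["epoch"] != "none"]
    results: dict = {}
    results["correlations"] = correlate_beta_kinematics(
        in_epoch["beta_logpower"].to_numpy(),
        in_epoch["rt_ms"].to_numpy(),
        in_epoch["duration_ms"].to_numpy(),
    )
    if cfg.mode == "human":
        results["error_regression"] = regress_beta_error(
            in_epoch["beta_logpower"].to_numpy(),
            in_epoch["endpoint_error_deg"].abs().to_numpy(),
        )
    results["contrast"] = epoch_contrast(
        trials, epoch_order=list(epoch_order)
    )
    groups = {
        e: in_epoch.loc[in_epoch["epoch"] == e, "beta_logpower"]
        .dropna()
        .to_numpy()
        for e in epoch_order
        if e in set(in_epoch["epoch"])
    }
    results["bootstrap"] = bootstrap_balanced(groups, cfg.n_boot, seed)
    return results


def _provenance(cfg: RunConfig) -> dict:
    cfg_dict = cfg.to_dict()
    cfg_dict.pop("output_dir", None)  # artifact location, not run identity
    blob = json.dumps(cfg_dict, sort_keys=True)
    return {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "betaadapt": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def _report_text(cfg: RunConfig, results: dict) -> str:
    lines = [f"betaadapt run (mode={cfg.mode}, seed={cfg.seed})"]
    c = results["contrast"]
    lines.append(
        f"epoch omnibus: F({c.df[0]:.0f},{c.df[1]:.0f}) = {c.omnibus_F:.2f}, "
        f"p = {c.p:.4g} (n = {c.n_obs})"
    )
    for pc in c.pairwise:
        lines.append(
            f"  {pc.epoch_a} - {pc.epoch_b}: {pc.estimate:+.4f} log-power, "
            f"p_bonf = {pc.p_bonferroni:.4g}"
        )
    for name, coef, p in c.covariates:
        lines.append(f"  covariate {name}: coef = {coef:+.3g}, p = {p:.4g}")
    for key, corr in results["correlations"].items():
        lines.append(
            f"spearman beta vs {key}: rho = {corr.rho:+.3f}, p = {corr.p:.4g}"
        )
    if "error_regression" in results:
        r = results["error_regression"]
        lines.append(
            f"beta vs |error|: F({r.df[0]},{r.df[1]}) = {r.F:.2f}, "
            f"p = {r.p:.4g}"
        )
    b = results["bootstrap"]
    lines.append(
        f"balanced bootstrap (n_boot={b.n_boot}, m={b.m_per_condition}):"
    )
    for name, (mean, se) in b.conditions.items():
        lines.append(f"  {name}: {mean:.4f} +/- {se:.4f}")
    return "\n".join(lines) + "\n"


def simulate_session_table(cfg: RunConfig) -> dict:
    """Simulate -> preprocess -> spectral, without the stats stage.

    Returns the finished trial table (``beta_logpower`` included), epoch
    definitions (human mode), the recording and ground truth.  Useful for
    pooling several sessions before a single inferential pass — e.g. small
    cat sessions whose miss counts are individually too low to model.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seed_behaviour, seed_recording, _ = ss.spawn(_N_STAGE_SEEDS)

    trials = _simulate_trials(cfg, seed_behaviour)
    epochs = None
    if cfg.mode == "human":
        t = cfg.task
        epoch_len = min(
            t.epoch_len, t.n_baseline, t.n_adaptation, t.n_washout
        )
        epochs = extract_epochs(trials, epoch_len)
    rec, truth = simulate_recording(trials, cfg.neural, seed_recording)
    windows = derive_and_window(cfg, rec)
    trials = compute_beta_statistic(cfg, windows, trials)
    return {
        "trials": trials,
        "epochs": epochs,
        "recording": rec,
        "ground_truth": truth,
    }


def run_pipeline(cfg: RunConfig, save_recording_artifact: bool = False) -> dict:
    """Run the full chain and (optionally) write artifacts to output_dir.

    Returns a dict with the finished trial table (``beta_logpower`` column
    included), the epoch definitions (human mode), the stats results, and a
    provenance record.  Re-running with an identical config reproduces
    identical outputs.
    """
    ss = np.random.SeedSequence(cfg.seed)
    _, _, seed_boot = ss.spawn(_N_STAGE_SEEDS)

    session = simulate_session_table(cfg)
    trials, epochs = session["trials"], session["epochs"]
    rec, truth = session["recording"], session["ground_truth"]
    results = run_stats(cfg, trials, seed_boot)

    artifacts = {
        "trials": trials,
        "epochs": epochs,
        "recording": rec,
        "ground_truth": truth,
        "provenance": _provenance(cfg),
        **results,
    }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(trials, out / "trials.csv")
        if epochs is not None:
            write_json(
                {
                    e.name: {
                        "trial_indices": e.trial_indices,
                        "qc_fraction_beyond_2sd": e.qc_fraction_beyond_2sd,
                    }
                    for e in epochs
                },
                out / "epochs.json",
            )
        write_json(
            {k: results[k] for k in results},
            out / "stats.json",
        )
        (out / "report.txt").write_text(_report_text(cfg, results))
        write_json(artifacts["provenance"], out / "provenance.json")
        if save_recording_artifact:
            save_recording(rec, out / "recording")
        logger.info("artifacts written to %s", out)
    return artifacts
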