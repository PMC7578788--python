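"""Synthetic visuomotor-adaptation sessions with coupled neural recordings.

Two task models are emulated:

* a human joystick centre-out task: three blocks (baseline / rotation /
  washout), four targets presented pseudorandomly in balanced blocks, a
  single-rate state-space learner producing exponential error decay under the
  rotation and a negative aftereffect when it is removed;
* a cat prism reach task: a short baseline, a prism block that ends after a
  criterion run of consecutive accurate reaches, and a brief post-prism block.

Behavioural sessions can be coupled to a continuous multichannel recording in
which a narrowband beta-range (15-25 Hz) process rides on 1/f background
noise.  The beta envelope carries the experimental effect: during each
trial's pre-movement preparatory span its amplitude is multiplied by an
epoch-specific gain, it is suppressed from shortly after movement initiation
(event-related desynchronization) and rebounds after movement end.  The
injected per-trial gain is returned as ground truth so downstream estimates
have a recoverable target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft
from scipy.ndimage import uniform_filter1d

from .behavior import assign_epochs
from .containers import GroundTruth, PipelineError, Recording

__all__ = [
    "TaskConfig",
    "AdaptationParams",
    "NeuralConfig",
    "CatTaskConfig",
    "simulate_behavior",
    "simulate_recording",
    "simulate_cat_stream",
    "default_human_neural_config",
    "default_cat_neural_config",
]


@dataclass
class TaskConfig:
    """Geometry and schedule of the human joystick task."""

    n_baseline: int = 200
    n_adaptation: int = 200
    n_washout: int = 200
    rotation_deg: float = 30.0
    target_angles_deg: Sequence[float] = (45.0, 135.0, 225.0, 315.0)
    boundary_radius_px: float = 300.0
    init_threshold_px: float = 5.0
    max_trial_ms: float = 750.0
    block_size: int = 20
    epoch_len: int = 72

    def __post_init__(self) -> None:
        for name in ("n_baseline", "n_adaptation", "n_washout"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be a positive trial count")
        if not math.isfinite(self.rotation_deg):
            raise PipelineError("rotation_deg must be finite")
        if self.init_threshold_px <= 0:
            raise PipelineError("init_threshold_px must be positive")
        if not self.target_angles_deg:
            raise PipelineError("need at least one target")
        if self.block_size % len(self.target_angles_deg):
            raise PipelineError(
                "block_size must be divisible by the number of targets"
            )

    @property
    def n_trials(self) -> int:
        return self.n_baseline + self.n_adaptation + self.n_washout


@dataclass
class AdaptationParams:
    """Single-rate state-space learner plus kinematic distributions.

    The internal estimate x of the perturbation evolves as
    ``x <- A*x + B*(r - x)`` with retention A and learning rate B; the
    noise-free perceived error on a trial is ``r - x``.  Reaction times and
    reach durations are Gaussian with additive per-epoch shifts (the human
    data show slower reaction times but shorter reaches in early adaptation).
    """

    retention: float = 0.98
    learning_rate: float = 0.10
    motor_noise_sd_deg: float = 4.0
    rt_base_ms: float = 300.0
    rt_sd_ms: float = 40.0
    dur_base_ms: float = 350.0
    dur_sd_ms: float = 40.0
    rt_epoch_offsets_ms: Mapping[str, float] = field(
        default_factory=lambda: {"EA": 15.0, "LA": 5.0, "EAft": 10.0}
    )
    dur_epoch_offsets_ms: Mapping[str, float] = field(
        default_factory=lambda: {"EA": -8.0, "LA": -4.0, "EAft": -5.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention <= 1.0:
            raise PipelineError("retention must lie in [0, 1]")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise PipelineError("learning_rate must lie in [0, 1]")
        for name in ("motor_noise_sd_deg", "rt_sd_ms", "dur_sd_ms"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be non-negative")


@dataclass
class NeuralConfig:
    """Generative model of the coupled recording.

    The beta component is a narrowband Gaussian process spanning
    ``beta_centre_hz +/- beta_bandwidth_hz/2`` so its power is spread evenly
    across the 15-25 Hz analysis band.  Its amplitude envelope per trial:

    * tonic level 1 between trials (idle sensorimotor rhythm);
    * ``beta_epoch_gain[epoch]`` from ``premove_lead_ms`` before target onset
      until ``desync_onset_ms`` after movement initiation (the preparatory
      span read out by the pre-movement statistic);
    * ``1 - desync_depth`` during the movement (event-related
      desynchronization, epoch-independent);
    * ``rebound_gain`` for ``rebound_len_ms`` starting ``rebound_delay_ms``
      after movement end (post-movement rebound, epoch-independent).
    """

    fs_raw: float = 2500.0
    channel_names: Sequence[str] = ("C3", "FC1", "FC5", "CP1", "CP5")
    neighbour_map: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"C3": ("FC1", "FC5", "CP1", "CP5")}
    )
    beta_channel: str = "C3"
    neighbour_leak: float = 0.3
    beta_centre_hz: float = 20.0
    beta_bandwidth_hz: float = 10.0
    beta_line_spacing_hz: float = 2.0
    beta_rms: float = 1.4
    noise_rms: float = 1.0
    noise_exponent: float = 1.0
    beta_epoch_gain: Mapping[str, float] = field(
        default_factory=lambda: {"EA": 0.8}
    )
    desync_depth: float = 0.6
    desync_onset_ms: float = 50.0
    premove_lead_ms: float = 150.0
    rebound_gain: float = 1.5
    rebound_delay_ms: float = 300.0
    rebound_len_ms: float = 600.0
    window_halfwidth_s: float = 1.0
    iti_s: float = 2.5

    def __post_init__(self) -> None:
        if self.fs_raw < 4.0 * self.beta_centre_hz:
            raise PipelineError("fs_raw must be at least 4x the beta centre")
        if not 0.0 <= self.desync_depth <= 1.0:
            raise PipelineError("desync_depth must lie in [0, 1]")
        if any(g <= 0 for g in self.beta_epoch_gain.values()):
            raise PipelineError("epoch gains must be positive")
        for name in ("beta_rms", "noise_rms", "neighbour_leak"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be non-negative")
        if self.beta_channel not in self.channel_names:
            raise PipelineError(
                f"beta_channel {self.beta_channel!r} not in channel_names"
            )

    def gain_for(self, epoch: str) -> float:
        return float(self.beta_epoch_gain.get(epoch, 1.0))


@dataclass
class CatTaskConfig:
    """Schedule of the cat prism reach task.

    ``miss_rate_by_phase`` gives the miss probability per phase; during the
    prism phase the rate decays as ``exp(-k/prism_adaptation_tau)`` over
    prism trials k, emulating adaptation (set ``prism_adaptation_tau`` to
    None for a constant rate).  The prism phase ends after
    ``streak_to_remove`` consecutive hits or at ``max_prism_trials``
    (flagged as non-converged).
    """

    n_baseline: int = 20
    n_post: int = 10
    miss_rate_by_phase: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 0.05, "prism": 0.9, "post": 0.5}
    )
    prism_adaptation_tau: float | None = 5.0
    streak_to_remove: int = 20
    max_prism_trials: int = 300
    rt_base_ms: float = 350.0
    rt_sd_ms: float = 60.0
    dur_base_ms: float = 400.0
    dur_sd_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.n_baseline <= 0 or self.n_post < 0:
            raise PipelineError("invalid cat phase schedule")
        for phase, p in self.miss_rate_by_phase.items():
            if not 0.0 <= p <= 1.0:
                raise PipelineError(f"miss rate for {phase!r} not in [0, 1]")
        if self.streak_to_remove <= 0 or self.max_prism_trials <= 0:
            raise PipelineError("invalid prism termination rule")


def default_human_neural_config(**overrides) -> NeuralConfig:
    """Human EEG-like configuration (2500 Hz, C3 Laplacian montage)."""
    return NeuralConfig(**overrides)


def default_cat_neural_config(**overrides) -> NeuralConfig:
    """Cat LFP-like configuration: 30 kHz two-site probe, bipolar montage."""
    defaults = dict(
        fs_raw=30000.0,
        channel_names=("probe_deep", "probe_superficial"),
        neighbour_map={},
        beta_channel="probe_deep",
        neighbour_leak=0.2,
    )
    defaults.update(overrides)
    return NeuralConfig(**defaults)


def _pseudorandom_targets(task: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Balanced pseudorandom target schedule: each target appears
    block_size / n_targets times per block, order permuted within block."""
    targets = np.asarray(task.target_angles_deg, dtype=float)
    reps = task.block_size // targets.size
    block = np.repeat(targets, reps)
    n_blocks = math.ceil(task.n_trials / task.block_size)
    out = np.concatenate([rng.permutation(block) for _ in range(n_blocks)])
    return out[: task.n_trials]


def simulate_behavior(
    task: TaskConfig,
    params: AdaptationParams,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one baseline/rotation/washout session.

    Returns a trial table (1-based ``trial_index``, epoch labels already
    assigned) and the learner's internal state trajectory as ground truth.
    The sign convention is negative = clockwise: under a clockwise rotation
    the reported endpoint error starts near ``-rotation_deg`` and decays; the
    first washout trials show the opposite (positive) sign, the negative
    aftereffect.
    """
    rng = np.random.default_rng(seed)
    n = task.n_trials
    phases = (
        ["baseline"] * task.n_baseline
        + ["adaptation"] * task.n_adaptation
        + ["washout"] * task.n_washout
    )
    rotation = np.where(
        np.array(phases) == "adaptation", task.rotation_deg, 0.0
    )
    targets = _pseudorandom_targets(task, rng)

    x = 0.0
    state = np.empty(n)
    err = np.empty(n)
    A, B = params.retention, params.learning_rate
    noise = rng.normal(0.0, params.motor_noise_sd_deg, size=n)
    for i in range(n):
        state[i] = x
        e_true = rotation[i] - x
        err[i] = -e_true - noise[i]
        x = A * x + B * e_true

    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "phase": phases,
            "epoch": "none",
            "target_deg": targets,
            "endpoint_error_deg": err,
            "rt_ms": 0.0,
            "duration_ms": 0.0,
            "category": "n/a",
        }
    )
    # epochs shrink with the shortest phase so reduced test sessions still
    # carry the five labels; full sessions use the standard 72-trial epochs
    epoch_len = min(
        task.epoch_len, task.n_baseline, task.n_adaptation, task.n_washout
    )
    df, _ = assign_epochs(df, epoch_len)

    rt = params.rt_base_ms + rng.normal(0.0, params.rt_sd_ms, size=n)
    dur = params.dur_base_ms + rng.normal(0.0, params.dur_sd_ms, size=n)
    rt += df["epoch"].map(
        lambda e: params.rt_epoch_offsets_ms.get(e, 0.0)
    ).to_numpy()
    dur += df["epoch"].map(
        lambda e: params.dur_epoch_offsets_ms.get(e, 0.0)
    ).to_numpy()
    df["rt_ms"] = np.maximum(rt, 50.0)
    df["duration_ms"] = np.maximum(dur, 100.0)
    df["slow"] = (df["rt_ms"] + df["duration_ms"]) > task.max_trial_ms

    truth = GroundTruth(state_deg=state)
    return df, truth


def simulate_cat_stream(
    cfg: CatTaskConfig, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Simulate a cat hit/miss/reject trial stream.

    Phases: ``baseline`` (fixed length), ``prism`` (until
    ``streak_to_remove`` consecutive hits or the cap, in which case the
    session carries ``converged=False``) and ``post``.  Epochs follow the
    hit/miss mapping: Baseline = pre-prism hits, EA = prism misses,
    LA = prism hits.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def add_trial(phase: str, miss_p: float) -> bool:
        miss = rng.random() < miss_p
        rows.append(
            {
                "phase": phase,
                "category": "miss" if miss else "hit",
                "rt_ms": max(50.0, cfg.rt_base_ms + rng.normal(0, cfg.rt_sd_ms)),
                "duration_ms": max(
                    100.0, cfg.dur_base_ms + rng.normal(0, cfg.dur_sd_ms)
                ),
            }
        )
        return miss

    for _ in range(cfg.n_baseline):
        add_trial("baseline", cfg.miss_rate_by_phase.get("baseline", 0.0))

    base_p = cfg.miss_rate_by_phase.get("prism", 0.0)
    streak = 0
    converged = False
    for k in range(cfg.max_prism_trials):
        p = base_p
        if cfg.prism_adaptation_tau is not None:
            p = base_p * math.exp(-k / cfg.prism_adaptation_tau)
        miss = add_trial("prism", p)
        streak = 0 if miss else streak + 1
        if streak >= cfg.streak_to_remove:
            converged = True
            break

    for _ in range(cfg.n_post):
        add_trial("post", cfg.miss_rate_by_phase.get("post", 0.0))

    df = pd.DataFrame(rows)
    df.insert(0, "trial_index", np.arange(1, len(df) + 1))
    df["endpoint_error_deg"] = np.nan
    df["target_deg"] = np.nan
    epoch = np.full(len(df), "none", dtype=object)
    epoch[(df["phase"] == "baseline") & (df["category"] == "hit")] = "Baseline"
    epoch[(df["phase"] == "prism") & (df["category"] == "miss")] = "EA"
    epoch[(df["phase"] == "prism") & (df["category"] == "hit")] = "LA"
    df["epoch"] = epoch
    df["converged"] = converged
    return df


def _powerlaw_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian 1/f^alpha noise via spectral shaping, scaled to a target RMS."""
    m = next_fast_len(n)  # pad to an FFT-friendly length, then truncate
    white = rng.standard_normal(m)
    spec = rfft(white)
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = irfft(spec * shape, n=m)[:n]
    # scale by the analytic expected SD, not the realized one: the realized
    # record variance is dominated by a few low-frequency components, and
    # dividing by it would give every record a random broadband gain
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if m % 2 == 0:
        weights[-1] = 1.0
    expected_sd = math.sqrt(float(np.sum(weights * shape**2)) / m)
    if expected_sd > 0 and rms > 0:
        x *= rms / expected_sd
    else:
        x[:] = 0.0
    return x


def _beta_process(
    n: int,
    fs: float,
    cfg: NeuralConfig,
    rng: np.random.Generator,
    slot_bounds: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-RMS beta-band rhythm: a comb of equal-amplitude sinusoids
    spanning the band interior, phases re-randomized per trial slot.

    A line comb (rather than band-limited noise) gives the rhythm a
    deterministic band power per trial, so the epoch amplitude gain the
    generator injects is a recoverable target for the band-mean log-power
    statistic; see the methods note for what this simplification leaves out.
    """
    lo = cfg.beta_centre_hz - cfg.beta_bandwidth_hz / 2.0
    hi = cfg.beta_centre_hz + cfg.beta_bandwidth_hz / 2.0
    lines = np.arange(lo + 1.0, hi, cfg.beta_line_spacing_hz)
    t = np.arange(n) / fs
    x = np.zeros(n)
    bounds = [0, n] if slot_bounds is None else [0, *slot_bounds, n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        phases = rng.uniform(0.0, 2.0 * math.pi, size=lines.size)
        seg = t[a:b, None] * lines[None, :] * (2.0 * math.pi) + phases
        x[a:b] = np.cos(seg).sum(axis=1)
    x /= math.sqrt(lines.size / 2.0)  # unit RMS for random-phase lines
    return x


def simulate_recording(
    trials: pd.DataFrame,
    cfg: NeuralConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[Recording, GroundTruth]:
    """Couple a behavioural session to a continuous multichannel recording.

    Movement-initiation markers are laid out every ``iti_s`` seconds;
    each trial's target onset precedes its marker by that trial's reaction
    time and movement end follows it by the reach duration.  The beta
    component is injected on ``beta_channel`` with attenuated copies
    (``neighbour_leak``) on all other channels, so a spatial derivation
    retains most of the beta signal while suppressing common-mode artifacts.
    """
    required = {"trial_index", "epoch", "rt_ms", "duration_ms"}
    if missing := required - set(trials.columns):
        raise PipelineError(f"trial table lacks columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    fs = cfg.fs_raw
    n_tr = len(trials)
    pad = cfg.window_halfwidth_s + 0.5

    move_init = pad + np.arange(n_tr) * cfg.iti_s
    rt_s = trials["rt_ms"].to_numpy() / 1000.0
    dur_s = trials["duration_ms"].to_numpy() / 1000.0
    target_on = move_init - rt_s
    move_end = move_init + dur_s

    lead = cfg.premove_lead_ms / 1000.0
    if np.any(target_on[1:] - lead <= move_end[:-1]):
        raise PipelineError(
            "inter-trial interval too short: trial event spans overlap"
        )
    n_samp = int(math.ceil((move_init[-1] + pad) * fs))

    envelope = np.ones(n_samp)
    gains = np.array([cfg.gain_for(e) for e in trials["epoch"]])
    desync_on = cfg.desync_onset_ms / 1000.0
    reb_delay = cfg.rebound_delay_ms / 1000.0
    reb_len = cfg.rebound_len_ms / 1000.0
    for i in range(n_tr):
        a = int((target_on[i] - lead) * fs)
        b = int((move_init[i] + desync_on) * fs)
        c = int((move_end[i] + reb_delay) * fs)
        d = int((move_end[i] + reb_delay + reb_len) * fs)
        envelope[a:b] = gains[i]
        envelope[b:c] = 1.0 - cfg.desync_depth
        envelope[c:d] = cfg.rebound_gain
    # ~10 ms smoothing so envelope steps do not inject broadband clicks
    k = max(1, int(0.01 * fs))
    envelope = uniform_filter1d(uniform_filter1d(envelope, k), k)

    # comb phases re-drawn at slot boundaries midway between trials, well
    # outside every analysis window
    slot_bounds = (
        ((move_init[:-1] + move_init[1:]) / 2.0 * fs).astype(int)
        if n_tr > 1
        else None
    )
    beta = cfg.beta_rms * envelope * _beta_process(
        n_samp, fs, cfg, rng, slot_bounds
    )

    channels = np.empty((len(cfg.channel_names), n_samp))
    for j, name in enumerate(cfg.channel_names):
        channels[j] = _powerlaw_noise(
            n_samp, fs, cfg.noise_exponent, cfg.noise_rms, rng
        )
        scale = 1.0 if name == cfg.beta_channel else cfg.neighbour_leak
        channels[j] += scale * beta

    events = pd.DataFrame(
        {
            "trial_index": trials["trial_index"].to_numpy(),
            "target_on_s": target_on,
            "move_init_s": move_init,
            "move_end_s": move_end,
        }
    )
    rec = Recording(
        samples=channels,
        fs=fs,
        channel_names=tuple(cfg.channel_names),
        events=events,
        neighbour_map=dict(cfg.neighbour_map),
    )
    truth = GroundTruth(
        beta_multiplier=gains,
        target_on_s=target_on,
        move_init_s=move_init,
        move_end_s=move_end,
    )
    return rec, truth
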