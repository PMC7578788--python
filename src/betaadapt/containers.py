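"""Shared data containers for the adaptation/beta-power pipeline.

Conventions used throughout the package:

* angles in degrees, signed, negative = clockwise;
* times in milliseconds in trial tables, seconds in signal metadata;
* trial tables are :class:`pandas.DataFrame` objects with the column schema in
  :data:`TRIAL_COLUMNS`; ``trial_index`` is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of a behavioural trial table.
TRIAL_COLUMNS = (
    "trial_index",
    "phase",
    "epoch",
    "target_deg",
    "endpoint_error_deg",
    "rt_ms",
    "duration_ms",
    "category",
)

#: Human analysis epochs, in task order.
HUMAN_EPOCHS = ("Baseline", "EA", "LA", "EAft", "LAft")

#: Cat analysis epochs (aftereffect trials are too few to analyse).
CAT_EPOCHS = ("Baseline", "EA", "LA")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage receives invalid input or configuration."""


@dataclass
class Recording:
    """Continuous multichannel time-series with event markers.

    ``samples`` has shape ``(n_channels, n_samples)``.  ``events`` is a
    DataFrame with one row per trial and columns ``trial_index``,
    ``target_on_s``, ``move_init_s``, ``move_end_s`` (seconds from record
    start).
    """

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str]
    events: pd.DataFrame
    neighbour_map: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise PipelineError("samples must be a (channels x time) array")
        if self.fs <= 0:
            raise PipelineError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.channel_names):
            raise PipelineError(
                f"{self.samples.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        names = set(self.channel_names)
        for centre, neighbours in self.neighbour_map.items():
            missing = [n for n in {centre, *neighbours} if n not in names]
            if missing:
                raise PipelineError(
                    f"neighbour map references absent channels: {missing}"
                )
        if len(self.events):
            t_max = self.samples.shape[1] / self.fs
            times = self.events[["target_on_s", "move_init_s", "move_end_s"]]
            if (times.to_numpy() < 0).any() or (times.to_numpy() > t_max).any():
                raise PipelineError("event timestamps fall outside the record")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = list(self.channel_names).index(name)
        except ValueError:
            raise PipelineError(f"no channel named {name!r}") from None
        return self.samples[idx]


@dataclass
class TrialWindow:
    """A single event-locked analysis window.

    ``t0_s`` is the position of movement initiation within the window (always
    the centre for the 2 s windows produced by ``extract_windows``).
    """

    samples: np.ndarray
    fs: float
    t0_s: float
    trial_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        """Sample times relative to movement initiation."""
        return np.arange(self.samples.size) / self.fs - self.t0_s


@dataclass
class TimeFreqMap:
    """Per-trial log-power over a frequency x time grid.

    ``logpower`` has shape ``(n_trials, n_freqs, n_times)``; samples inside
    the cone of influence are NaN.  ``time_grid_s`` is relative to movement
    initiation.
    """

    logpower: np.ndarray
    freq_grid_hz: np.ndarray
    time_grid_s: np.ndarray
    trial_indices: np.ndarray
    band: tuple[float, float] = (15.0, 25.0)

    def __post_init__(self) -> None:
        self.logpower = np.asarray(self.logpower, dtype=float)
        self.freq_grid_hz = np.asarray(self.freq_grid_hz, dtype=float)
        self.time_grid_s = np.asarray(self.time_grid_s, dtype=float)
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        for grid, label in ((self.freq_grid_hz, "frequency"),
                            (self.time_grid_s, "time")):
            if np.any(np.diff(grid) <= 0):
                raise PipelineError(f"{label} grid must be strictly increasing")

    def band_rows(self) -> np.ndarray:
        lo, hi = self.band
        return np.flatnonzero(
            (self.freq_grid_hz >= lo) & (self.freq_grid_hz <= hi)
        )


@dataclass
class EpochDefinition:
    """A named analysis epoch and its member trials (1-based trial indices)."""

    name: str
    trial_indices: np.ndarray
    qc_fraction_beyond_2sd: float | None = None

    def __post_init__(self) -> None:
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    state_deg: np.ndarray | None = None
    beta_multiplier: np.ndarray | None = None
    target_on_s: np.ndarray | None = None
    move_init_s: np.ndarray | None = None
    move_end_s: np.ndarray | None = None


@dataclass
class PreMovementWindowSpec:
    """Where the pre-movement beta statistic is read out.

    ``reaction_time`` mode averages over each trial's own reaction-time
    interval [-rt, 0); ``fixed`` mode uses [fixed_start_ms, fixed_end_ms)
    relative to movement initiation (negative = before).
    """

    mode: str = "reaction_time"
    fixed_start_ms: float = -400.0
    fixed_end_ms: float = -200.0

    def __post_init__(self) -> None:
        if self.mode not in ("reaction_time", "fixed"):
            raise PipelineError(f"unknown window mode {self.mode!r}")
        if self.mode == "fixed":
            if not (self.fixed_start_ms < self.fixed_end_ms <= 0):
                raise PipelineError(
                    "fixed window must be entirely pre-movement with "
                    "positive duration"
                )


@dataclass
class PairwiseContrast:
    epoch_a: str
    epoch_b: str
    estimate: float
    p_raw: float
    p_bonferroni: float


@dataclass
class ContrastResult:
    """Covariate-adjusted epoch contrast: omnibus F plus pairwise contrasts."""

    omnibus_F: float
    df: tuple[float, float]
    p: float
    pairwise: list[PairwiseContrast]
    covariates: list[tuple[str, float, float]]
    n_obs: int

    def pair(self, a: str, b: str) -> PairwiseContrast:
        for c in self.pairwise:
            if {c.epoch_a, c.epoch_b} == {a, b}:
                return c
        raise KeyError(f"no contrast between {a!r} and {b!r}")


@dataclass
class PairwiseBootstrap:
    cond_a: str
    cond_b: str
    diff_mean: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonferroni: float


@dataclass
class BootstrapResult:
    """Balanced bootstrap over condition means."""

    n_boot: int
    m_per_condition: int
    conditions: dict[str, tuple[float, float]]  # name -> (mean, se)
    pairwise: list[PairwiseBootstrap]
    flags: list[str] = field(default_factory=list)
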