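"""Spatial derivations, the band-limiting filter chain, and event-locked
windowing.

The filter chain reproduces a standard beta-band pre-processing recipe:
zero-phase 4th-order Butterworth low-pass at 30 Hz at the native rate (which
doubles as the anti-alias filter), resampling to 500 Hz, then a zero-phase
4th-order Butterworth high-pass at 10 Hz.  Zero-phase (forward-backward)
filtering is used throughout so event alignment is preserved; the effective
order is therefore doubled and the first/last ``EDGE_EXCLUDE_S`` seconds of
any filtered record should be excluded from statistics.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import PipelineError, Recording, TrialWindow

__all__ = [
    "hjorth_laplacian",
    "bipolar_rereference",
    "filter_chain",
    "extract_windows",
    "zscore_window",
    "TARGET_FS",
    "EDGE_EXCLUDE_S",
]

logger = logging.getLogger(__name__)

#: Analysis sampling rate after the filter chain (Hz).
TARGET_FS = 500.0

#: Filtered-record edge span excluded from downstream statistics (s).
EDGE_EXCLUDE_S = 0.25


def hjorth_laplacian(rec: Recording, centre: str) -> np.ndarray:
    """Hjorth approximation of the surface Laplacian at ``centre``.

    Output is the centre channel minus the mean of its four mapped
    nearest-neighbour channels, sample-wise — a spatial high-pass that
    suppresses signal components common to the local montage.
    """
    if centre not in rec.neighbour_map:
        raise PipelineError(f"no neighbour map entry for channel {centre!r}")
    neighbours = list(rec.neighbour_map[centre])
    if len(neighbours) != 4:
        raise PipelineError(
            f"Hjorth derivation at {centre!r} needs exactly 4 neighbours, "
            f"got {len(neighbours)}"
        )
    missing = [n for n in neighbours if n not in rec.channel_names]
    if missing:
        raise PipelineError(f"missing neighbour channel(s): {missing}")
    neigh = np.stack([rec.channel(n) for n in neighbours])
    return rec.channel(centre) - neigh.mean(axis=0)


def bipolar_rereference(rec: Recording, ch_a: str, ch_b: str) -> np.ndarray:
    """Bipolar derivation ``a - b`` (e.g. two sites at opposite probe ends)."""
    if ch_a == ch_b:
        raise PipelineError("bipolar channels must differ")
    return rec.channel(ch_a) - rec.channel(ch_b)


def filter_chain(series: np.ndarray, fs_in: float) -> tuple[np.ndarray, float]:
    """Low-pass 30 Hz -> resample to 500 Hz -> high-pass 10 Hz.

    Returns the 10-30 Hz band-limited series and its new sampling rate.
    Integer rate ratios are decimated directly (the 30 Hz low-pass already
    served as the anti-alias filter); non-integer ratios use polyphase
    resampling.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise PipelineError("filter_chain expects a single channel")
    if fs_in < 1000.0:
        raise PipelineError(f"fs_in={fs_in} Hz too low; need >= 1000 Hz")

    sos_lp = signal.butter(4, 30.0, btype="lowpass", fs=fs_in, output="sos")
    x = signal.sosfiltfilt(sos_lp, series)

    ratio = fs_in / TARGET_FS
    if abs(ratio - round(ratio)) < 1e-9:
        x = x[:: int(round(ratio))]
    else:
        frac = Fraction(TARGET_FS / fs_in).limit_denominator(10000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)

    sos_hp = signal.butter(4, 10.0, btype="highpass", fs=TARGET_FS, output="sos")
    return signal.sosfiltfilt(sos_hp, x), TARGET_FS


def extract_windows(
    series: np.ndarray,
    fs: float,
    events: pd.DataFrame | np.ndarray,
    halfwidth_s: float = 1.0,
) -> list[TrialWindow]:
    """Extract one window per movement-initiation marker.

    ``events`` is either an event table with ``move_init_s`` (and optionally
    ``trial_index``) columns, or a plain array of times in seconds.  Each
    window spans ``2 * halfwidth_s`` with the marker at the centre sample.
    Markers too close to the record edges are skipped with a logged reason.
    """
    series = np.asarray(series, dtype=float)
    if isinstance(events, pd.DataFrame):
        times = events["move_init_s"].to_numpy(dtype=float)
        trial_idx = (
            events["trial_index"].to_numpy(dtype=int)
            if "trial_index" in events
            else np.arange(1, times.size + 1)
        )
    else:
        times = np.asarray(events, dtype=float)
        trial_idx = np.arange(1, times.size + 1)

    n_win = int(round(2.0 * halfwidth_s * fs))
    t0_idx = n_win // 2
    windows = []
    for ti, t in zip(trial_idx, times):
        start = int(round((t - halfwidth_s) * fs))
        if start < 0 or start + n_win > series.size:
            logger.info(
                "trial %d skipped: window [%.3f, %.3f] s exceeds record "
                "bounds", ti, t - halfwidth_s, t + halfwidth_s
            )
            continue
        windows.append(
            TrialWindow(
                samples=series[start : start + n_win].copy(),
                fs=fs,
                t0_s=t0_idx / fs,
                trial_index=int(ti),
            )
        )
    return windows


def zscore_window(w: TrialWindow) -> TrialWindow:
    """Normalize a window to zero mean and unit SD over its own samples."""
    sd = w.samples.std()
    if sd == 0 or not math.isfinite(sd):
        raise PipelineError(
            f"trial {w.trial_index}: window has zero variance, cannot z-score"
        )
    return TrialWindow(
        samples=(w.samples - w.samples.mean()) / sd,
        fs=w.fs,
        t0_s=w.t0_s,
        trial_index=w.trial_index,
    )
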