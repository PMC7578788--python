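"""Morlet time-frequency decomposition and the pre-movement beta statistic.

The wavelet is the analytic Morlet with nondimensional frequency
``omega0 = 6`` in the Torrence & Compo convention: at scale ``s`` the
frequency-domain wavelet is

    Psi_hat(s * w) = pi**(-1/4) * sqrt(2 * pi * s * fs) * exp(-(s*w - omega0)**2 / 2)

for positive angular frequencies ``w`` (zero otherwise), which is
unit-energy normalized so coefficient magnitudes are comparable across
scales.  A grid frequency ``f`` maps to the scale whose Fourier period is
``1/f``: ``s = (omega0 + sqrt(2 + omega0**2)) / (4 * pi * f)``.

Power is the natural log of the squared coefficient magnitude (with a small
floor), so an amplitude ratio ``g`` between two signals appears as a
log-power difference of exactly ``2 * ln(g)``.  Coefficients inside the cone
of influence (within one e-folding time ``sqrt(2) * s`` of either window
edge) are excluded as NaN.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .containers import (
    PipelineError,
    PreMovementWindowSpec,
    TimeFreqMap,
    TrialWindow,
)

__all__ = [
    "OMEGA0",
    "LOG_FLOOR",
    "DEFAULT_FREQ_GRID",
    "morlet_scale",
    "morlet_transform",
    "log_power",
    "transform_windows",
    "premovement_beta",
]

logger = logging.getLogger(__name__)

#: Morlet nondimensional frequency.
OMEGA0 = 6.0

#: Floor added to squared magnitudes before taking the log.
LOG_FLOOR = 1e-12

#: Default analysis grid: the 15-25 Hz beta band in 1 Hz steps.
DEFAULT_FREQ_GRID = np.arange(15.0, 26.0, 1.0)

_FOURIER_FACTOR = 4.0 * math.pi / (OMEGA0 + math.sqrt(2.0 + OMEGA0**2))


def morlet_scale(freq_hz: float) -> float:
    """Wavelet scale (s) whose Fourier period equals ``1 / freq_hz``."""
    return 1.0 / (freq_hz * _FOURIER_FACTOR)


def _check_grid(freq_grid_hz: np.ndarray, fs: float) -> np.ndarray:
    grid = np.atleast_1d(np.asarray(freq_grid_hz, dtype=float))
    if np.any(grid <= 0) or np.any(grid >= fs / 2.0):
        raise PipelineError(
            f"grid frequencies must lie in (0, {fs / 2:g}) Hz"
        )
    return grid


def _wavelet_bank(
    freq_grid_hz: np.ndarray, fs: float, n_fft: int
) -> np.ndarray:
    """Frequency-domain Morlet bank, shape (n_freqs, n_fft)."""
    w = 2.0 * math.pi * np.fft.fftfreq(n_fft, d=1.0 / fs)
    bank = np.zeros((freq_grid_hz.size, n_fft))
    pos = w > 0
    for i, f in enumerate(freq_grid_hz):
        s = morlet_scale(f)
        bank[i, pos] = (
            math.pi**-0.25
            * math.sqrt(2.0 * math.pi * s * fs)
            * np.exp(-0.5 * (s * w[pos] - OMEGA0) ** 2)
        )
    return bank


def _pad_length(n: int, fs: float, freq_grid_hz: np.ndarray) -> int:
    # zero-pad beyond the widest wavelet's support so the circular FFT
    # product equals a linear convolution over the original samples
    s_max = morlet_scale(float(np.min(freq_grid_hz)))
    return next_fast_len(n + int(math.ceil(12.0 * s_max * fs)))


def _coi_valid(
    n_times: int, fs: float, freq_grid_hz: np.ndarray
) -> np.ndarray:
    """True where a coefficient is outside the cone of influence."""
    t = np.arange(n_times) / fs
    t_end = (n_times - 1) / fs
    valid = np.empty((freq_grid_hz.size, n_times), dtype=bool)
    for i, f in enumerate(freq_grid_hz):
        efold = math.sqrt(2.0) * morlet_scale(f)
        valid[i] = (t >= efold) & (t <= t_end - efold)
    return valid


def morlet_transform(
    window: TrialWindow,
    freq_grid_hz: np.ndarray = DEFAULT_FREQ_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous Morlet transform of one window.

    Returns complex coefficients of shape ``(n_freqs, n_times)`` together
    with a boolean mask that is True outside the cone of influence.
    """
    grid = _check_grid(freq_grid_hz, window.fs)
    x = np.asarray(window.samples, dtype=float)
    n = x.size
    n_fft = _pad_length(n, window.fs, grid)
    bank = _wavelet_bank(grid, window.fs, n_fft)
    spec = fft(x, n=n_fft)
    coefs = ifft(spec[None, :] * bank, axis=1)[:, :n]
    return coefs, _coi_valid(n, window.fs, grid)


def log_power(coefs: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Natural-log squared magnitude; COI-excluded cells become NaN."""
    if not np.all(np.isfinite(coefs)):
        raise PipelineError("non-finite wavelet coefficients")
    lp = np.log(np.abs(coefs) ** 2 + LOG_FLOOR)
    if valid is not None:
        lp = np.where(valid, lp, np.nan)
    return lp


def transform_windows(
    windows: list[TrialWindow],
    freq_grid_hz: np.ndarray = DEFAULT_FREQ_GRID,
    band: tuple[float, float] = (15.0, 25.0),
    time_decim: int = 1,
) -> TimeFreqMap:
    """Morlet log-power for a stack of equally sized windows.

    All windows must share length, sampling rate and ``t0_s``; the result's
    time grid is relative to movement initiation.  ``time_decim`` keeps
    every k-th power sample: the wavelet's temporal envelope (tens of ms in
    the beta band) makes the full-rate power grid redundant, so modest
    decimation leaves band-mean statistics essentially unchanged.
    """
    if not windows:
        raise PipelineError("no windows to transform")
    fs = windows[0].fs
    n = windows[0].samples.size
    t0 = windows[0].t0_s
    if any(
        w.fs != fs or w.samples.size != n or w.t0_s != t0 for w in windows
    ):
        raise PipelineError("windows differ in length, rate or alignment")

    grid = _check_grid(freq_grid_hz, fs)
    n_fft = _pad_length(n, fs, grid)
    bank = _wavelet_bank(grid, fs, n_fft)
    x = np.stack([w.samples for w in windows])
    spec = fft(x, n=n_fft, axis=1)
    tsel = slice(0, n, int(time_decim))
    valid = _coi_valid(n, fs, grid)[:, tsel]
    n_t = valid.shape[1]

    lp = np.empty((len(windows), grid.size, n_t), dtype=float)
    for i in range(grid.size):
        coefs = ifft(spec * bank[i][None, :], axis=1)[:, tsel]
        lp[:, i, :] = np.log(
            coefs.real**2 + coefs.imag**2 + LOG_FLOOR
        )
    lp[:, ~valid] = np.nan

    return TimeFreqMap(
        logpower=lp,
        freq_grid_hz=grid,
        time_grid_s=(np.arange(n) / fs - t0)[tsel],
        trial_indices=np.array([w.trial_index for w in windows]),
        band=band,
    )


def premovement_beta(
    tf: TimeFreqMap,
    trials: pd.DataFrame,
    spec: PreMovementWindowSpec = PreMovementWindowSpec(),
) -> pd.Series:
    """Per-trial mean beta log-power over the pre-movement interval.

    In ``reaction_time`` mode the interval is ``[-rt, 0)`` for each trial's
    own reaction time; in ``fixed`` mode it is the configured span for every
    trial.  The mean runs over the 15-25 Hz band rows and the in-interval
    time bins, ignoring COI-excluded cells; trials whose interval contains
    no valid cell get NaN (flagged missing, never zero).  Intervals
    extending beyond the extracted window are truncated with a logged note.
    """
    rows = tf.band_rows()
    if rows.size == 0:
        raise PipelineError("frequency grid does not cover the beta band")
    rt = trials.set_index("trial_index")["rt_ms"]
    out = {}
    for k, ti in enumerate(tf.trial_indices):
        if spec.mode == "reaction_time":
            if ti not in rt.index:
                raise PipelineError(f"trial {ti} missing from trial table")
            start_s, end_s = -rt.loc[ti] / 1000.0, 0.0
        else:
            start_s = spec.fixed_start_ms / 1000.0
            end_s = spec.fixed_end_ms / 1000.0
        if start_s < tf.time_grid_s[0]:
            logger.info(
                "trial %d: pre-movement interval truncated to window start",
                ti,
            )
            start_s = tf.time_grid_s[0]
        tsel = (tf.time_grid_s >= start_s) & (tf.time_grid_s < end_s)
        block = tf.logpower[k][np.ix_(rows, tsel)]
        if block.size == 0 or np.all(np.isnan(block)):
            logger.info("trial %d: no valid pre-movement cells, flagged", ti)
            out[int(ti)] = np.nan
        else:
            out[int(ti)] = float(np.nanmean(block))
    return pd.Series(out, name="beta_logpower")
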