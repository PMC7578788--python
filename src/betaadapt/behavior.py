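"""Behavioural measures, trial classification and adaptation-epoch assignment.

Angle convention: angles are measured in degrees counterclockwise from
vertical (the 12 o'clock direction), so a clockwise displacement of the reach
endpoint relative to its target yields a *negative* endpoint error.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import EpochDefinition, PipelineError

__all__ = [
    "detect_movement_init",
    "compute_endpoint_error",
    "classify_trial_cat",
    "extract_epochs",
    "assign_epochs",
    "point_angle_deg",
    "wrap_angle_deg",
]

#: Reaction-time floor for cat trials (ms); faster reaches are anticipatory.
CAT_RT_FLOOR_MS = 150.0


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (deg) to the interval (-180, 180]."""
    wrapped = angle - 360.0 * np.floor((np.asarray(angle) + 180.0) / 360.0)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.isscalar(angle) else wrapped


def point_angle_deg(x: float, y: float) -> float:
    """Angle of the point (x, y), degrees counterclockwise from vertical."""
    return math.degrees(math.atan2(-x, y))


def detect_movement_init(
    times: np.ndarray, xy: np.ndarray, threshold_px: float
) -> float | None:
    """First timestamp at which the cursor leaves the start zone.

    Movement initiation is the first sample whose Euclidean distance from
    the trajectory's starting position *strictly exceeds* ``threshold_px``.
    Returns None if the trajectory never leaves the zone.
    """
    times = np.asarray(times, dtype=float)
    xy = np.asarray(xy, dtype=float)
    if xy.size == 0:
        raise PipelineError("empty trajectory")
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] != times.size:
        raise PipelineError("trajectory must be (n, 2) with matching times")
    dist = np.hypot(xy[:, 0] - xy[0, 0], xy[:, 1] - xy[0, 1])
    beyond = np.flatnonzero(dist > threshold_px)
    return float(times[beyond[0]]) if beyond.size else None


def compute_endpoint_error(
    xy: np.ndarray, target_deg: float, boundary_radius_px: float
) -> float:
    """Signed angular endpoint error (deg) at the first boundary crossing.

    The crossing point is found by linear interpolation between the last
    sample inside and the first sample strictly outside the boundary circle
    (centred on the origin).  The error is the wrapped difference
    ``endpoint_angle - target_deg``; clockwise displacement is negative.
    Returns NaN for trajectories that never cross (incomplete trial).
    """
    xy = np.asarray(xy, dtype=float)
    if xy.size == 0:
        raise PipelineError("empty trajectory")
    r = np.hypot(xy[:, 0], xy[:, 1])
    outside = np.flatnonzero(r > boundary_radius_px)
    if outside.size == 0:
        return float("nan")
    i = int(outside[0])
    if i == 0:
        px, py = xy[0]
    else:
        p = xy[i - 1]
        d = xy[i] - xy[i - 1]
        # smallest t in (0, 1] with |p + t d| = R (outward root)
        a = float(d @ d)
        b = 2.0 * float(p @ d)
        c = float(p @ p) - boundary_radius_px**2
        t = (-b + math.sqrt(max(b * b - 4 * a * c, 0.0))) / (2 * a)
        px, py = p + t * d
    return wrap_angle_deg(point_angle_deg(px, py) - target_deg)


def classify_trial_cat(
    rt_ms: float,
    duration_ms: float,
    outcome: str,
    duration_mean_ms: float,
    duration_sd_ms: float,
    late_correction: bool = False,
    noise_artifact: bool = False,
) -> tuple[str, str | None]:
    """Classify one cat reach as hit / miss / rejected.

    Rejection rules (any one suffices): reaction time shorter than 150 ms,
    reach duration more than 2 SD above that animal's session mean, a late
    corrective adjustment, or a neural noise artifact.  Returns the category
    and, for rejections, the reason.
    """
    if duration_ms is None or (
        isinstance(duration_ms, float) and math.isnan(duration_ms)
    ):
        return "rejected", "incomplete"
    if rt_ms < CAT_RT_FLOOR_MS:
        return "rejected", "reaction_time"
    if duration_ms > duration_mean_ms + 2.0 * duration_sd_ms:
        return "rejected", "duration"
    if late_correction:
        return "rejected", "late_correction"
    if noise_artifact:
        return "rejected", "noise_artifact"
    if outcome not in ("hit", "miss"):
        raise PipelineError(f"outcome must be 'hit' or 'miss', got {outcome!r}")
    return outcome, None


def _qc_fraction(errors: np.ndarray, base_mean: float, base_sd: float) -> float:
    """Fraction of trials whose endpoint error lies strictly beyond the
    baseline mean +/- 2 SD band."""
    beyond = np.abs(errors - base_mean) > 2.0 * base_sd
    return float(np.mean(beyond))


def extract_epochs(
    trials: pd.DataFrame, epoch_len: int = 72
) -> list[EpochDefinition]:
    """The five human analysis epochs as consecutive trial-index sets.

    Baseline = last ``epoch_len`` baseline trials; EA / EAft = first
    ``epoch_len`` trials after the rotation is applied / removed;
    LA / LAft = final ``epoch_len`` trials of those blocks.  The early
    epochs additionally report the fraction of their trials whose endpoint
    error exceeds the Baseline mean +/- 2 SD (a QC check that the epoch
    indeed captures large errors, not a selection filter).
    """
    idx = {
        phase: trials.loc[trials["phase"] == phase, "trial_index"].to_numpy()
        for phase in ("baseline", "adaptation", "washout")
    }
    for phase, indices in idx.items():
        if indices.size < epoch_len:
            raise PipelineError(
                f"phase {phase!r} has {indices.size} trials; "
                f"needs >= {epoch_len}"
            )
    members = {
        "Baseline": idx["baseline"][-epoch_len:],
        "EA": idx["adaptation"][:epoch_len],
        "LA": idx["adaptation"][-epoch_len:],
        "EAft": idx["washout"][:epoch_len],
        "LAft": idx["washout"][-epoch_len:],
    }

    err = trials.set_index("trial_index")["endpoint_error_deg"]
    base = err.loc[members["Baseline"]].to_numpy()
    base_mean, base_sd = float(np.mean(base)), float(np.std(base, ddof=1))

    epochs = []
    for name, indices in members.items():
        qc = None
        if name in ("EA", "EAft"):
            qc = _qc_fraction(err.loc[indices].to_numpy(), base_mean, base_sd)
        epochs.append(EpochDefinition(name, indices, qc))
    return epochs


def assign_epochs(
    trials: pd.DataFrame, epoch_len: int = 72
) -> tuple[pd.DataFrame, list[EpochDefinition]]:
    """Attach an ``epoch`` column to a human trial table.

    Trials outside every epoch are labelled ``"none"``.  Returns the table
    (copy) and the epoch definitions.
    """
    epochs = extract_epochs(trials, epoch_len)
    out = trials.copy()
    label = pd.Series("none", index=out["trial_index"].to_numpy(), dtype=object)
    # later assignments win; task order means overlaps only occur in
    # degenerate short phases, where the late epoch takes precedence
    for ep in epochs:
        label.loc[ep.trial_indices] = ep.name
    out["epoch"] = label.loc[out["trial_index"].to_numpy()].to_numpy()
    return out, epochs
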