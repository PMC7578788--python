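"""Artifact I/O: trial tables (CSV), recordings (npy + JSON sidecar),
window stacks (npz) and JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PipelineError, Recording, TrialWindow

__all__ = [
    "write_trials",
    "read_trials",
    "save_recording",
    "load_recording",
    "save_windows",
    "load_windows",
    "write_json",
    "read_recording_edf",
]


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, cls=_Encoder, indent=2, sort_keys=True) + "\n"
    )


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_recording(rec: Recording, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "recording.npy", rec.samples)
    rec.events.to_csv(directory / "events.csv", index=False)
    write_json(
        {
            "fs": rec.fs,
            "channel_names": list(rec.channel_names),
            "neighbour_map": {
                k: list(v) for k, v in rec.neighbour_map.items()
            },
        },
        directory / "recording.json",
    )


def load_recording(directory: str | Path) -> Recording:
    directory = Path(directory)
    meta = json.loads((directory / "recording.json").read_text())
    return Recording(
        samples=np.load(directory / "recording.npy"),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        events=pd.read_csv(directory / "events.csv"),
        neighbour_map=meta["neighbour_map"],
    )


def save_windows(windows: list[TrialWindow], path: str | Path) -> None:
    if not windows:
        raise PipelineError("no windows to save")
    np.savez(
        path,
        samples=np.stack([w.samples for w in windows]),
        fs=windows[0].fs,
        t0_s=windows[0].t0_s,
        trial_index=np.array([w.trial_index for w in windows]),
    )


def load_windows(path: str | Path) -> list[TrialWindow]:
    with np.load(path) as z:
        return [
            TrialWindow(
                samples=row,
                fs=float(z["fs"]),
                t0_s=float(z["t0_s"]),
                trial_index=int(ti),
            )
            for row, ti in zip(z["samples"], z["trial_index"])
        ]


def read_recording_edf(
    path: str | Path,
    neighbour_map: dict[str, list[str]] | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (requires mne).

    Event markers are taken from the EDF annotations where present; the
    caller is expected to build the trial event table separately.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise PipelineError(
            "EDF reading requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    events = pd.DataFrame(
        columns=["trial_index", "target_on_s", "move_init_s", "move_end_s"]
    )
    return Recording(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
        neighbour_map=neighbour_map or {},
    )
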