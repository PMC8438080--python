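"""Shared data containers and their on-disk formats.

The pipeline exchanges three kinds of objects between stages:

* :class:`DisplaySpec` — per-frame AOI rectangles for one stimulus video,
  plus its event times (display onset, movement onset, grasp, hammering,
  end) and a depth-order history used to resolve overlapping AOIs.
  Serialized as JSON.
* :class:`GazeRecording` — one participant x trial gaze/pupil time series
  from a remote eye tracker.  Serialized as tidy CSV.
* :class:`EEGEpochSet` — epoched multichannel EEG around movement onset.
  Serialized as an HDF5 container.

Coordinates are display pixels, origin at the top-left corner, x to the
right, y downward.  Times are seconds from display onset unless a field
says otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

AOI_NAMES = ("hammer", "peg", "dominant_hand", "non_dominant_hand", "face")

CONDITIONS = ("efficient", "inefficient", "localizer_a", "localizer_b")


@dataclass
class DisplaySpec:
    """Per-frame AOI geometry and event times for one stimulus video.

    ``aoi_tracks[name]`` is an ``(n_frames, 4)`` float array of rectangles
    ``[x0, y0, x1, y1]`` (inclusive bounds, pixels).  ``depth_history`` is a
    time-ordered list of ``(t_s, mover, target)`` entries recording each
    moment an AOI moved into the space of another AOI; the most recent
    mover is treated as front-most when a gaze point falls in an overlap.
    ``depth_order`` is the resting front-to-back order used before any
    history entry applies.
    """

    resolution: tuple[int, int]  # (width, height) px
    fps: float
    events: dict[str, float]  # onset, movement, grasp, hammer, end (s)
    condition: str
    aoi_tracks: dict[str, np.ndarray]
    depth_history: list[tuple[float, str, str]] = field(default_factory=list)
    depth_order: tuple[str, ...] = AOI_NAMES

    @property
    def n_frames(self) -> int:
        return next(iter(self.aoi_tracks.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.events["end"]

    def frame_at(self, t_s: float) -> int:
        """Nearest frame index for a sample time (no extrapolation)."""
        if t_s < 0 or t_s > self.duration_s:
            raise ValueError(f"time {t_s:.3f}s outside display [0, {self.duration_s:.3f}]s")
        return int(min(round(t_s * self.fps), self.n_frames - 1))

    def rect_at(self, name: str, t_s: float) -> np.ndarray:
        return self.aoi_tracks[name][self.frame_at(t_s)]

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "resolution": list(self.resolution),
            "fps": self.fps,
            "events": self.events,
            "condition": self.condition,
            "aoi_tracks": {k: v.tolist() for k, v in self.aoi_tracks.items()},
            "depth_history": [[t, a, b] for t, a, b in self.depth_history],
            "depth_order": list(self.depth_order),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "DisplaySpec":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            resolution=tuple(obj["resolution"]),
            fps=obj["fps"],
            events=obj["events"],
            condition=obj["condition"],
            aoi_tracks={k: np.asarray(v, float) for k, v in obj["aoi_tracks"].items()},
            depth_history=[(t, a, b) for t, a, b in obj["depth_history"]],
            depth_order=tuple(obj["depth_order"]),
        )


@dataclass
class GazeRecording:
    """One trial of tracker samples: gaze position, validity, pupil size.

    Invalid samples (blinks, track loss) carry NaN positions and pupil 0.
    ``t`` is strictly increasing, seconds from display onset.
    """

    participant_id: str
    trial_id: int
    condition: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray  # bool

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.pupil = np.asarray(self.pupil, float)
        self.valid = np.asarray(self.valid, bool)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def sampling_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "trial": self.trial_id,
                "condition": self.condition,
                "t_s": self.t,
                "x_px": self.x,
                "y_px": self.y,
                "pupil": self.pupil,
                "valid": self.valid.astype(int),
            }
        )


def write_gaze_csv(recordings: list[GazeRecording], path) -> None:
    pd.concat([r.to_frame() for r in recordings], ignore_index=True).to_csv(path, index=False)


def read_gaze_csv(path) -> list[GazeRecording]:
    df = pd.read_csv(path)
    out = []
    for (pid, trial, cond), g in df.groupby(["participant", "trial", "condition"], sort=True):
        out.append(
            GazeRecording(
                participant_id=str(pid),
                trial_id=int(trial),
                condition=str(cond),
                t=g["t_s"].to_numpy(),
                x=g["x_px"].to_numpy(),
                y=g["y_px"].to_numpy(),
                pupil=g["pupil"].to_numpy(),
                valid=g["valid"].to_numpy().astype(bool),
            )
        )
    return out


@dataclass
class EEGEpochSet:
    """Epoched EEG: ``data`` is (n_epochs, n_channels, n_samples) in µV.

    ``times`` is seconds relative to movement onset and must span a
    negative (baseline) and positive (post-onset) interval.  ``labels``
    holds the per-epoch condition string.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    channel_names: list[str]
    labels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length mismatch")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length mismatch")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def pick(self, channels: list[str]) -> "EEGEpochSet":
        idx = [self.channel_names.index(c) for c in channels]
        return EEGEpochSet(self.data[:, idx, :], self.sfreq, self.times, list(channels), list(self.labels))

    def select_epochs(self, mask: np.ndarray) -> "EEGEpochSet":
        mask = np.asarray(mask, bool)
        labels = [l for l, m in zip(self.labels, mask) if m]
        return EEGEpochSet(self.data[mask], self.sfreq, self.times, list(self.channel_names), labels)

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.create_dataset("times", data=self.times)
            fh.create_dataset(
                "channel_names", data=np.array(self.channel_names, dtype=h5py.string_dtype())
            )
            fh.create_dataset("labels", data=np.array(self.labels, dtype=h5py.string_dtype()))
            fh.attrs["sfreq"] = self.sfreq

    @classmethod
    def from_hdf5(cls, path) -> "EEGEpochSet":
        with h5py.File(path, "r") as fh:
            return cls(
                data=fh["data"][()],
                sfreq=float(fh.attrs["sfreq"]),
                times=fh["times"][()],
                channel_names=[s.decode() for s in fh["channel_names"][()]],
                labels=[s.decode() for s in fh["labels"][()]],
            )
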