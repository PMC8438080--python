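"""Gaze-masked "looking videos" and their per-participant classification.

A looking video represents the visual information an observer actually
sampled: each display frame is black except within a 75 px radius of the
observer's gaze at that frame.  Frame-feature sequences are extracted
with a pluggable extractor (default: 8x8x3 grid of region means, no
pretrained weights needed) and classified per participant with the shared
repeated leave-one-out LS-SVM protocol and label-shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import h5py
import numpy as np

from .classify import ClassificationResult, classify_trials
from .containers import DisplaySpec, GazeRecording
from .probmaps import _gaze_at_frames
from .synthetic import render_frame


@dataclass
class LookingVideo:
    """Masked frames plus trial metadata."""

    frames: np.ndarray  # (n_frames, H, W, 3), float in [0, 1]
    participant_id: str
    trial_id: int
    condition: str
    radius_px: float

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=self.frames, compression="gzip")
            fh.attrs.update(participant=self.participant_id, trial=self.trial_id,
                            condition=self.condition, radius_px=self.radius_px)


def gaze_disk_mask(shape_hw: tuple[int, int], gx: float, gy: float,
                   radius_px: float) -> np.ndarray:
    """Boolean mask of pixels within ``radius_px`` (inclusive) of (gx, gy)."""
    h, w = shape_hw
    mask = np.zeros((h, w), bool)
    ri = int(np.ceil(radius_px))
    y0, y1 = max(int(gy) - ri - 1, 0), min(int(gy) + ri + 2, h)
    x0, x1 = max(int(gx) - ri - 1, 0), min(int(gx) + ri + 2, w)
    if y1 <= y0 or x1 <= x0:
        return mask
    ys, xs = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (xs - gx) ** 2 + (ys - gy) ** 2 <= radius_px**2
    return mask


def make_looking_video(
    display_frames: np.ndarray,
    recording: GazeRecording,
    display: DisplaySpec,
    radius_px: float = 75.0,
    scale: int = 1,
) -> LookingVideo:
    """Mask each display frame to the gaze disk.

    Gaze is taken as the nearest valid sample within half a frame of the
    frame time; frames with no such sample are entirely black.  With
    ``scale`` > 1 the frames are at a reduced resolution and gaze
    coordinates and radius are scaled to match.
    """
    display_frames = np.asarray(display_frames)
    h, w = display_frames.shape[1:3]
    if (w * scale, h * scale) != display.resolution:
        raise ValueError("frame resolution does not match recording coordinates")
    frames_idx = np.arange(display_frames.shape[0])
    gaze = _gaze_at_frames(recording, display, frames_idx) / scale
    r = radius_px / scale
    out = np.zeros_like(display_frames, dtype=np.float32)
    for k in range(display_frames.shape[0]):
        gx, gy = gaze[k]
        if np.isnan(gx):
            continue
        m = gaze_disk_mask((h, w), gx, gy, r)
        out[k][m] = display_frames[k][m]
    return LookingVideo(out, recording.participant_id, recording.trial_id,
                        recording.condition, radius_px)


# ---------------------------------------------------------------------------
# feature extraction

def _grid8_mean(frames: np.ndarray) -> np.ndarray:
    """Default extractor: 8x8 grid of per-channel region means -> 192-dim.

    Rows/columns are split into 8 near-equal bands (uneven by at most one
    pixel when the size is not divisible by 8).
    """
    n, h, w, c = frames.shape
    if h < 8 or w < 8:
        raise ValueError("frames must be at least 8x8")
    if h % 8 == 0 and w % 8 == 0:
        pooled = frames.reshape(n, 8, h // 8, 8, w // 8, c).mean(axis=(2, 4))
        return pooled.reshape(n, 8 * 8 * c)
    out = np.empty((n, 8, 8, c), frames.dtype)
    rows = np.array_split(np.arange(h), 8)
    cols = np.array_split(np.arange(w), 8)
    for i, rs in enumerate(rows):
        band = frames[:, rs[0]:rs[-1] + 1]
        for j, cs in enumerate(cols):
            out[:, i, j] = band[:, :, cs[0]:cs[-1] + 1].mean(axis=(1, 2))
    return out.reshape(n, 8 * 8 * c)


EXTRACTORS: dict[str, Callable[[np.ndarray], np.ndarray]] = {"grid8_mean": _grid8_mean}


def register_extractor(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a frame-sequence feature extractor (e.g. a pretrained CNN hook)."""
    EXTRACTORS[name] = fn


def extract_features(video: LookingVideo, extractor_id: str = "grid8_mean") -> np.ndarray:
    """Per-frame feature vectors: (n_frames, dim)."""
    if extractor_id not in EXTRACTORS:
        raise KeyError(f"unknown extractor {extractor_id!r}")
    feats = EXTRACTORS[extractor_id](np.asarray(video.frames, np.float32))
    if not np.all(np.isfinite(feats)):
        raise ValueError("extractor produced non-finite features")
    return feats


def pool_sequence(features: np.ndarray) -> np.ndarray:
    """Deterministic temporal pooling: concatenated mean and max over frames."""
    return np.concatenate([features.mean(axis=0), features.max(axis=0)])


def render_video(display: DisplaySpec, scale: int = 10) -> np.ndarray:
    """All display frames as one (n_frames, H, W, 3) array.

    Render once per display and pass to :func:`trial_features` for every
    trial sharing the stimulus.
    """
    return np.stack([render_frame(display, k, scale=scale)
                     for k in range(display.n_frames)])


def trial_features(
    recording: GazeRecording,
    display: DisplaySpec,
    radius_px: float = 75.0,
    scale: int = 10,
    extractor_id: str = "grid8_mean",
    frames: np.ndarray | None = None,
) -> np.ndarray:
    """Render + mask + extract + pool one trial without storing the video."""
    if frames is None:
        frames = render_video(display, scale=scale)
    video = make_looking_video(frames, recording, display,
                               radius_px=radius_px, scale=scale)
    return pool_sequence(extract_features(video, extractor_id))


# ---------------------------------------------------------------------------
# classification

def classify_participant(
    trial_feats: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 500,
    n_shuffles: int = 1000,
    n_reps_per_shuffle: int = 50,
    seed: int = 0,
) -> ClassificationResult:
    """Repeated leave-one-out (one held-out trial per condition) LS-SVM
    accuracy with a label-shuffle null; see :mod:`observa.classify`."""
    return classify_trials(
        trial_feats, labels, n_reps=n_reps, n_shuffles=n_shuffles,
        n_reps_per_shuffle=n_reps_per_shuffle, C=1.0, seed=seed,
    )


def shuffle_null(
    trial_feats: np.ndarray,
    labels: np.ndarray,
    observed_accuracy: float,
    n_shuffles: int = 1000,
    n_reps_per_shuffle: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Label-shuffle null for an already-computed observed accuracy.

    Returns the null accuracy distribution (%) and the +1-corrected
    p-value P(null >= observed).
    """
    res = classify_trials(
        trial_feats, labels, n_reps=1, n_shuffles=n_shuffles,
        n_reps_per_shuffle=n_reps_per_shuffle, C=1.0, seed=seed,
    )
    null = res.null_distribution
    p = float((1 + np.sum(null >= observed_accuracy)) / (1 + n_shuffles))
    return null, p
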