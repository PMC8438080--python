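"""Temporal fixation-probability maps and pixel-wise group comparison.

For each participant, the probability map over a frame range (movement
onset to grasp) gives, per pixel, the fraction of frames on which the
pixel lay within 75 px of the gaze point ("the gaze disk"); frames with
no valid gaze cover no pixels but still count in the denominator.  Group
maps average participant maps; groups are compared with a pixel-wise
unequal-variance t-test and a Benjamini–Hochberg FDR mask at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .containers import DisplaySpec, GazeRecording
from .stats import bh_fdr, welch_t_grid


@dataclass
class ProbabilityMap:
    grid: np.ndarray  # (height, width), values in [0, 1]
    frame_range: tuple[int, int]  # [start, end) display-frame indices
    owner: str
    downsample: int = 1

    def __post_init__(self):
        if np.any((self.grid < 0) | (self.grid > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("grid", data=self.grid)
            fh.attrs["frame_range"] = self.frame_range
            fh.attrs["owner"] = self.owner
            fh.attrs["downsample"] = self.downsample

    @classmethod
    def from_hdf5(cls, path) -> "ProbabilityMap":
        with h5py.File(path, "r") as fh:
            return cls(fh["grid"][()], tuple(fh.attrs["frame_range"]),
                       str(fh.attrs["owner"]), int(fh.attrs["downsample"]))


def _gaze_at_frames(recording: GazeRecording, display: DisplaySpec,
                    frames: np.ndarray) -> np.ndarray:
    """Nearest valid gaze sample within half a frame of each frame time.

    Returns (n_frames, 2) of x, y; NaN rows where no valid sample is close
    enough.
    """
    out = np.full((frames.size, 2), np.nan)
    tv = recording.t[recording.valid]
    if tv.size == 0:
        return out
    xv = recording.x[recording.valid]
    yv = recording.y[recording.valid]
    half = 0.5 / display.fps
    ft = frames / display.fps
    pos = np.searchsorted(tv, ft)
    for k, (p, tf) in enumerate(zip(pos, ft)):
        best, bd = -1, np.inf
        for j in (p - 1, p):
            if 0 <= j < tv.size and abs(tv[j] - tf) < bd:
                best, bd = j, abs(tv[j] - tf)
        if best >= 0 and bd <= half:
            out[k] = xv[best], yv[best]
    return out


def participant_map(
    recording: GazeRecording,
    display: DisplaySpec,
    frame_range: tuple[int, int] | None = None,
    radius_px: float = 75.0,
    downsample: int = 1,
) -> ProbabilityMap:
    """Per-pixel fraction of frames covered by the gaze disk.

    ``frame_range`` is [start, end) in display frames; default is movement
    onset to grasp.  A pixel is covered when its center lies within
    ``radius_px`` (inclusive) of the frame's gaze point.  With
    ``downsample`` > 1 the grid holds every ``downsample``-th pixel and the
    radius is scaled accordingly.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    if frame_range is None:
        frame_range = (display.frame_at(display.events["movement"]),
                       display.frame_at(display.events["grasp"]))
    f0, f1 = frame_range
    if f1 <= f0:
        raise ValueError("empty frame_range")
    if f0 < 0 or f1 > display.n_frames:
        raise ValueError("frame_range outside display")
    w, h = display.resolution
    W, H = w // downsample, h // downsample
    r = radius_px / downsample
    frames = np.arange(f0, f1)
    gaze = _gaze_at_frames(recording, display, frames) / downsample

    count = np.zeros((H, W))
    ri = int(np.ceil(r))
    dy, dx = np.mgrid[-ri:ri + 1, -ri:ri + 1]
    for gx, gy in gaze:
        if np.isnan(gx):
            continue
        cx, cy = int(round(gx)), int(round(gy))
        disk = (dx + cx - gx) ** 2 + (dy + cy - gy) ** 2 <= r**2
        ys, xs = dy[disk] + cy, dx[disk] + cx
        ok = (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
        count[ys[ok], xs[ok]] += 1
    return ProbabilityMap(count / frames.size, (f0, f1),
                          owner=recording.participant_id, downsample=downsample)


def group_map(maps: list[ProbabilityMap]) -> ProbabilityMap:
    """Element-wise mean across participants."""
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].grid.shape
    if any(m.grid.shape != shape for m in maps):
        raise ValueError("maps must share a grid shape")
    grid = np.mean([m.grid for m in maps], axis=0)
    return ProbabilityMap(grid, maps[0].frame_range, owner="group",
                          downsample=maps[0].downsample)


@dataclass
class MapComparison:
    t_grid: np.ndarray
    p_grid: np.ndarray
    mask: np.ndarray  # BH-FDR rejections at q
    q: float


def compare_maps(group_a: list[ProbabilityMap], group_b: list[ProbabilityMap],
                 q: float = 0.05) -> MapComparison:
    """Pixel-wise Welch t between two groups of participant maps, with a
    BH-FDR mask over all pixels of the grid.

    Pixels constant across participants in both groups get p = 1 (no
    variance, no evidence).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 maps per group")
    a = np.stack([m.grid for m in group_a])
    b = np.stack([m.grid for m in group_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("grid shape mismatch between groups")
    t, p = welch_t_grid(a, b)
    mask = bh_fdr(p.ravel(), q=q).reshape(p.shape)
    return MapComparison(t, p, mask, q)


def render_map_png(pmap: ProbabilityMap, path, background: np.ndarray | None = None) -> None:
    """Save the map as a PNG with opacity encoding fixation probability."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if background is not None:
        ax.imshow(background)
        ax.imshow(np.zeros_like(pmap.grid), cmap="gray",
                  alpha=1.0 - pmap.grid, vmin=0, vmax=1)
    else:
        ax.imshow(pmap.grid, cmap="magma", vmin=0, vmax=1)
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
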