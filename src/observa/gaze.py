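"""Dynamic AOI gaze analysis.

Implements the per-trial looking measures: gaze samples are scored against
five time-varying rectangular AOIs (hammer, peg, dominant hand,
non-dominant hand, face), with overlaps resolved by attributing gaze to
the front-most AOI — the AOI that most recently moved into the space of
another AOI.  From the scored samples we derive

* percent dwell time — AOI sample time / total tracked time,
* fixations (dispersion-based I-DT, minimum duration 100 ms) and percent
  fixation time — AOI fixation time / total fixation time,
* revisits — entries of gaze into an AOI from outside it (the first entry
  counts), and
* gaze shifts — consecutive fixations on two different AOIs within
  100 ms, pooled over direction into the 10 unordered AOI pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import AOI_NAMES, DisplaySpec, GazeRecording

AOI_PAIRS = tuple(combinations(AOI_NAMES, 2))  # 10 unordered pairs


@dataclass
class Fixation:
    start_s: float
    end_s: float
    centroid_px: tuple[float, float]
    aoi: str | None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class LookingMeasures:
    """Per-trial looking measures keyed by AOI name."""

    pct_dwell: dict[str, float]
    pct_fixation: dict[str, float]
    revisits: dict[str, int]
    tracked_time_s: float
    fixation_time_s: float


def assign_aoi(x: float, y: float, t_s: float, display: DisplaySpec) -> str | None:
    """AOI containing the point, front-most AOI when several contain it.

    Front-most = the candidate with the most recent depth-history entry at
    or before ``t_s`` (it last moved into another AOI's space); with no
    applicable history, the display's resting depth order decides.
    Returns ``None`` outside all AOIs.
    """
    frame = display.frame_at(t_s)  # raises out-of-range
    candidates = [
        name for name in AOI_NAMES
        if (r := display.aoi_tracks[name][frame])[0] <= x <= r[2] and r[1] <= y <= r[3]
    ]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    best, best_t = None, -np.inf
    for i, (te, mover, _target) in enumerate(display.depth_history):
        if te <= t_s and mover in candidates and (te, i) >= (best_t, -1):
            best, best_t = mover, te
    if best is not None:
        return best
    for name in display.depth_order:
        if name in candidates:
            return name
    return candidates[0]


def assign_aoi_series(recording: GazeRecording, display: DisplaySpec) -> np.ndarray:
    """Per-sample AOI labels (object array; None for invalid/off-AOI samples)."""
    out = np.full(recording.t.size, None, object)
    for i in range(recording.t.size):
        if recording.valid[i]:
            out[i] = assign_aoi(recording.x[i], recording.y[i], recording.t[i], display)
    return out


def detect_fixations(
    recording: GazeRecording,
    display: DisplaySpec | None = None,
    min_dur_s: float = 0.100,
    dispersion_px: float = 50.0,
) -> list[Fixation]:
    """Dispersion-based (I-DT) fixation detection.

    A window of samples is a fixation candidate while its dispersion
    (x-range + y-range) stays within ``dispersion_px``; candidates
    shorter than ``min_dur_s`` are discarded.  Runs are split at invalid
    samples.  When a display is given, each fixation is labeled with the
    majority AOI of its samples' per-sample assignments (ties broken by
    the earliest-assigned AOI).
    """
    fixations: list[Fixation] = []
    v = recording.valid
    if not v.any():
        return fixations
    # contiguous valid runs
    idx = np.flatnonzero(v)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    dt = float(np.median(np.diff(recording.t)))

    for run in runs:
        x, y, t = recording.x[run], recording.y[run], recording.t[run]
        n = run.size
        start = 0
        while start < n:
            end = start + 1
            xmin = xmax = x[start]
            ymin = ymax = y[start]
            while end < n:
                xm, xM = min(xmin, x[end]), max(xmax, x[end])
                ym, yM = min(ymin, y[end]), max(ymax, y[end])
                if (xM - xm) + (yM - ym) > dispersion_px:
                    break
                xmin, xmax, ymin, ymax = xm, xM, ym, yM
                end += 1
            dur = t[end - 1] - t[start] + dt  # include the final sample's span
            if dur >= min_dur_s and end - start >= 2:
                cx, cy = float(np.mean(x[start:end])), float(np.mean(y[start:end]))
                aoi = None
                if display is not None:
                    labels = [assign_aoi(x[i], y[i], t[i], display) for i in range(start, end)]
                    aoi = _majority_label(labels)
                fixations.append(Fixation(float(t[start]), float(t[end - 1] + dt),
                                          (cx, cy), aoi))
                start = end
            else:
                start += 1
    return fixations


def _majority_label(labels: list[str | None]) -> str | None:
    counts: dict[str | None, int] = {}
    first_seen: dict[str | None, int] = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        first_seen.setdefault(lab, i)
    best = max(counts.items(), key=lambda kv: (kv[1], -first_seen[kv[0]]))
    return best[0]


def looking_measures(
    recording: GazeRecording,
    display: DisplaySpec,
    fixations: list[Fixation] | None = None,
) -> LookingMeasures:
    """Percent dwell, percent fixation time, and revisit counts per AOI.

    Dwell uses only valid samples in both numerator and denominator
    ("total tracking time"); fixation time is normalized by the summed
    duration of all fixations.  A revisit is an entry into the AOI from
    outside it, including the first entry.
    """
    if fixations is None:
        fixations = detect_fixations(recording, display)
    labels = assign_aoi_series(recording, display)
    tracked = int(recording.valid.sum())
    if tracked == 0:
        raise ValueError("zero tracked time: no valid samples")
    dt = float(np.median(np.diff(recording.t)))

    pct_dwell = {
        a: 100.0 * np.sum(labels[recording.valid] == a) / tracked for a in AOI_NAMES
    }

    fix_total = sum(f.duration_s for f in fixations)
    pct_fix = {a: 0.0 for a in AOI_NAMES}
    if fix_total > 0:
        for f in fixations:
            if f.aoi is not None:
                pct_fix[f.aoi] += 100.0 * f.duration_s / fix_total

    revisits = {a: 0 for a in AOI_NAMES}
    prev = None
    for lab in labels[recording.valid]:
        if lab is not None and lab != prev:
            revisits[lab] += 1
        prev = lab

    return LookingMeasures(pct_dwell, pct_fix, revisits,
                           tracked_time_s=tracked * dt, fixation_time_s=fix_total)


@dataclass
class TransitionMatrix:
    """Gaze-shift counts over the 10 unordered AOI pairs (directions pooled)."""

    counts: dict[tuple[str, str], int]

    @classmethod
    def empty(cls) -> "TransitionMatrix":
        return cls({p: 0 for p in AOI_PAIRS})

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"aoi_a": a, "aoi_b": b, "count": c} for (a, b), c in self.counts.items()]
        )


def gaze_shifts(fixations: list[Fixation], max_gap_s: float = 0.100) -> TransitionMatrix:
    """Count shifts between consecutive AOI-labeled fixations on different
    AOIs separated by at most ``max_gap_s``."""
    tm = TransitionMatrix.empty()
    labeled = [f for f in fixations if f.aoi is not None]
    labeled.sort(key=lambda f: f.start_s)
    for f1, f2 in zip(labeled, labeled[1:]):
        if f2.aoi != f1.aoi and (f2.start_s - f1.end_s) <= max_gap_s:
            pair = (f1.aoi, f2.aoi) if (f1.aoi, f2.aoi) in tm.counts else (f2.aoi, f1.aoi)
            tm.counts[pair] += 1
    return tm


def measures_table(per_trial: list[tuple[str, int, str, LookingMeasures]]) -> pd.DataFrame:
    """Tidy frame: one row per participant x trial x AOI."""
    rows = []
    for pid, trial, cond, m in per_trial:
        for a in AOI_NAMES:
            rows.append({
                "participant": pid, "trial": trial, "condition": cond, "aoi": a,
                "pct_dwell": m.pct_dwell[a], "pct_fixation": m.pct_fixation[a],
                "revisits": m.revisits[a],
            })
    return pd.DataFrame(rows)
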