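"""Pupillometry: artifact cleaning, baseline normalization, and
time-resolved condition comparison.

Pupil size is expressed as a percentage of each trial's baseline (the
mean over the first 1250 ms of the display, before movement begins),
down-sampled to 30 Hz and aligned to movement onset.  Conditions are
compared timepoint-by-timepoint on participant-mean traces with an
unequal-variance t-test, FDR-corrected across timepoints, and contiguous
significant windows reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GazeRecording
from .stats import bh_fdr, welch_t, welch_t_grid


@dataclass
class CleanedPupil:
    """Artifact-cleaned pupil series on the original time base."""

    t: np.ndarray
    value: np.ndarray  # NaN where missing
    usable: bool
    missing_fraction: float


@dataclass
class PupilTrace:
    """Trial trace in percent of baseline, 30 Hz, aligned to movement onset."""

    t: np.ndarray  # s relative to movement onset
    value: np.ndarray  # percent of baseline; NaN in unrecoverable gaps
    baseline_mean: float
    participant_id: str = ""
    trial_id: int = 0
    condition: str = ""


def preprocess_pupil(
    recording: GazeRecording,
    mad_criterion: float = 5.0,
    margin_s: float = 0.050,
    max_gap_s: float = 0.300,
    max_missing: float = 0.5,
) -> CleanedPupil:
    """Remove blinks/implausible samples and interpolate short gaps.

    Samples are flagged when invalid, non-positive, or when their
    deviation from a 500 ms rolling median exceeds ``mad_criterion``
    (scaled) MADs of that residual — blinks and saccadic spikes are fast,
    whereas physiological dilation is slow and rides inside the rolling
    median, so it is never censored.  Flags grow by a ``margin_s`` margin
    on each side.  Gaps up to ``max_gap_s`` are linearly interpolated;
    longer gaps stay missing.  Trials with more than ``max_missing``
    missing after cleaning are marked unusable.
    """
    from scipy.ndimage import median_filter

    t = recording.t
    v = recording.pupil.astype(float).copy()
    bad = (~recording.valid) | (v <= 0) | ~np.isfinite(v)
    if (~bad).any():
        dt = float(np.median(np.diff(t)))
        k = max(int(round(0.5 / dt)) | 1, 3)  # odd window, ~500 ms
        med = np.median(v[~bad])
        smooth = median_filter(np.where(bad, med, v), size=k, mode="nearest")
        resid = v - smooth
        mad = np.median(np.abs(resid[~bad] - np.median(resid[~bad])))
        if mad > 0:
            bad |= np.abs(resid) > mad_criterion * 1.4826 * mad
    # dilate the bad mask by the margin
    if bad.any() and margin_s > 0:
        dt = float(np.median(np.diff(t)))
        k = int(round(margin_s / dt))
        if k > 0:
            idx = np.flatnonzero(bad)
            grown = np.zeros_like(bad)
            for i in idx:
                grown[max(i - k, 0):i + k + 1] = True
            bad = grown
    v[bad] = np.nan

    # interpolate gaps shorter than max_gap_s
    good = ~np.isnan(v)
    if good.any() and (~good).any():
        gap_idx = np.flatnonzero(~good)
        runs = np.split(gap_idx, np.flatnonzero(np.diff(gap_idx) > 1) + 1)
        for run in runs:
            if run.size == 0:
                continue
            left, right = run[0] - 1, run[-1] + 1
            if left < 0 or right >= v.size:
                continue  # edge gaps stay missing
            if t[right] - t[left] <= max_gap_s:
                v[run] = np.interp(t[run], [t[left], t[right]], [v[left], v[right]])
    missing = float(np.mean(np.isnan(v)))
    return CleanedPupil(t=t, value=v, usable=missing <= max_missing,
                        missing_fraction=missing)


def normalize_trace(
    cleaned: CleanedPupil,
    events: dict[str, float],
    out_hz: float = 30.0,
    baseline_window_s: float = 1.250,
    recording: GazeRecording | None = None,
) -> PupilTrace:
    """Percent-of-baseline trace at ``out_hz``, aligned to movement onset.

    Baseline is the mean over the first ``baseline_window_s`` of the
    display (before movement); down-sampling is mean-per-bin.
    """
    t, v = cleaned.t, cleaned.value
    base_sel = (t >= 0) & (t < baseline_window_s) & ~np.isnan(v)
    if not base_sel.any():
        raise ValueError("empty baseline window")
    baseline = float(v[base_sel].mean())

    onset = events["movement"]
    dur = events["end"]
    edges = np.arange(0.0, dur + 0.5 / out_hz, 1.0 / out_hz)
    centers = (edges[:-1] + edges[1:]) / 2
    binned = np.full(centers.size, np.nan)
    which = np.digitize(t, edges) - 1
    for b in range(centers.size):
        sel = (which == b) & ~np.isnan(v)
        if sel.any():
            binned[b] = v[sel].mean()
    meta = {}
    if recording is not None:
        meta = dict(participant_id=recording.participant_id,
                    trial_id=recording.trial_id, condition=recording.condition)
    return PupilTrace(t=centers - onset, value=100.0 * binned / baseline,
                      baseline_mean=baseline, **meta)


@dataclass
class PupilComparison:
    t: np.ndarray  # timepoints (s relative to movement onset) tested
    t_stat: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    windows: list[tuple[float, float]]  # contiguous significant windows
    q: float


def participant_mean_traces(traces: list[PupilTrace]) -> dict[str, dict[str, np.ndarray]]:
    """participant -> condition -> mean trace (NaN-aware)."""
    out: dict[str, dict[str, list[np.ndarray]]] = {}
    for tr in traces:
        out.setdefault(tr.participant_id, {}).setdefault(tr.condition, []).append(tr.value)
    return {
        pid: {c: np.nanmean(np.stack(vs), axis=0) for c, vs in byc.items()}
        for pid, byc in out.items()
    }


def compare_conditions(
    traces_by_condition: dict[str, np.ndarray],
    times: np.ndarray,
    q: float = 0.05,
    from_t: float = 0.0,
) -> PupilComparison:
    """Timepoint-wise Welch t between two conditions on participant-mean
    traces, BH-FDR across timepoints from movement onset to video end.

    ``traces_by_condition`` maps each of two condition names to an
    (n_participants, n_timepoints) array on the common ``times`` base.
    """
    conds = sorted(traces_by_condition)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    a, b = (np.asarray(traces_by_condition[c], float) for c in conds)
    if a.shape[1] != times.size or b.shape[1] != times.size:
        raise ValueError("unequal time bases")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 participants per condition")

    sel = times >= from_t
    asel, bsel = a[:, sel], b[:, sel]
    if np.isnan(asel).any() or np.isnan(bsel).any():
        # NaN-robust per-timepoint Welch (participants with unrecoverable
        # gaps at a timepoint are dropped there; < 2 per group -> p = 1)
        nt = asel.shape[1]
        tt = np.zeros(nt)
        pp = np.ones(nt)
        for j in range(nt):
            av = asel[~np.isnan(asel[:, j]), j]
            bv = bsel[~np.isnan(bsel[:, j]), j]
            if av.size >= 2 and bv.size >= 2:
                r = welch_t(av, bv)
                tt[j], pp[j] = r.statistic, r.p_two_sided
    else:
        tt, pp = welch_t_grid(asel, bsel)
    mask = bh_fdr(pp, q=q)
    tsel = times[sel]
    windows: list[tuple[float, float]] = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            windows.append((float(tsel[i]), float(tsel[j])))
            i = j + 1
        else:
            i += 1
    return PupilComparison(t=tsel, t_stat=tt, p=pp, mask=mask, windows=windows, q=q)
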