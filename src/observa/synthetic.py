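"""Synthetic cohort simulator for the action-observation paradigm.

Emulates the study conditions the analysis modules assume: observers watch
5.4 s videos of an actor grasping a hammer and pounding a peg, with
movement onset 2.5 s after display onset, on a 1920x1200 display; gaze and
pupil are sampled at 120 Hz; EEG is 32 channels at 500 Hz epoched around
movement onset.  Each trial is either an "efficient" (underhand initial
grip) or "inefficient" (overhand initial grip) action; "localizer" trials
show grip-neutral actions used only to localize action-sensitive neural
activity.

Two observer profiles are provided:

* ``adult_like`` — fixates the hammer and the actor's dominant hand during
  the reach, with condition-dependent looking dynamics
  (``gaze_condition_effect``); shows pupil dilation on inefficient trials
  and condition-dependent mu suppression.
* ``child_like`` — shifts gaze to the goal target (peg) shortly after
  movement onset regardless of condition, shows no pupil condition effect
  and condition-insensitive mu suppression.

Everything is deterministic under a fixed seed.  The condition signal that
a downstream looking-video classifier can pick up lives only in the
dominant-hand appearance during the reach interval (the initial grip);
child-like scanpaths never sample it, so their trials are exchangeable
across condition labels by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AOI_NAMES, DisplaySpec, EEGEpochSet, GazeRecording

# ---------------------------------------------------------------------------
# profiles and cohort configuration

#: 32-channel extended 10-20 montage (ENOBIO-32-style label set).
EEG_CHANNELS_32 = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
]

#: Bilateral sensorimotor + occipital sites available in the 32-ch montage.
SENSORIMOTOR_OCCIPITAL = [
    "FC5", "FC1", "FC2", "FC6", "C3", "C4", "CP5", "CP1", "CP2", "CP6", "O1", "O2",
]

#: Channels carrying the simulated mu-band source, with relative gains.
MU_CHANNEL_GAINS = {"C3": 1.0, "C4": 1.0, "CP1": 0.8, "CP2": 0.8, "FC1": 0.6, "FC2": 0.6}


@dataclass
class SimProfile:
    """Observer profile: gaze strategy and physiological effect sizes.

    ``gaze_condition_effect`` scales how strongly the split of reach-time
    looking between hammer and hand depends on condition (0 = identical in
    law).  ``pupil_effect`` is the peak dilation on inefficient trials in
    percent of baseline.  ``mu_suppression_logratio`` is the target log10
    post/pre power ratio of the mu-band source; ``eeg_condition_effect``
    is the condition difference in that log-ratio (inefficient trials get
    the deeper suppression).  ``anticipation_latency`` is how long after
    movement onset a child-like observer jumps to the peg.
    """

    label: str
    gaze_condition_effect: float
    pupil_effect: float
    mu_band: tuple[float, float]
    mu_suppression_logratio: float
    eeg_condition_effect: float
    anticipation_latency: float
    pupil_window: tuple[float, float] = (0.7, 1.4)  # s after grasp

    def __post_init__(self):
        lo, hi = self.mu_band
        if not (1 <= lo < hi <= 45):
            raise ValueError("mu_band must satisfy 1 <= low < high <= 45 Hz")
        for v in (self.gaze_condition_effect, self.pupil_effect,
                  self.mu_suppression_logratio, self.eeg_condition_effect,
                  self.anticipation_latency):
            if not np.isfinite(v):
                raise ValueError("effect magnitudes must be finite")
        if self.gaze_condition_effect < 0:
            raise ValueError("gaze_condition_effect must be >= 0")

    @classmethod
    def adult_like(cls, **overrides) -> "SimProfile":
        kw = dict(
            label="adult_like",
            gaze_condition_effect=1.0,
            pupil_effect=10.0,
            mu_band=(8.0, 13.0),
            mu_suppression_logratio=-0.42,
            eeg_condition_effect=0.3,
            anticipation_latency=1.8,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def child_like(cls, **overrides) -> "SimProfile":
        kw = dict(
            label="child_like",
            gaze_condition_effect=0.0,
            pupil_effect=0.0,
            mu_band=(6.0, 9.0),
            mu_suppression_logratio=-0.94,
            eeg_condition_effect=0.0,
            anticipation_latency=0.3,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimCohortConfig:
    """One simulated group: who, how many trials, and with what seed."""

    n_participants: int
    profile: SimProfile
    seed: int
    n_trials_per_condition: int = 24  # 48 test videos per participant
    n_localizer_trials: int = 48
    display: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_trials_per_condition < 2:
            raise ValueError("leave-one-out needs >= 2 trials per condition")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


# ---------------------------------------------------------------------------
# display specification

_REST_RECTS = {
    "face": (860.0, 80.0, 1060.0, 280.0),
    "peg": (1400.0, 700.0, 1650.0, 950.0),
    "hammer": (480.0, 640.0, 660.0, 770.0),
    "dominant_hand": (640.0, 900.0, 780.0, 1020.0),
    "non_dominant_hand": (1150.0, 900.0, 1290.0, 1020.0),
}


def _rects_overlap(a, b) -> bool:
    return a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]


def gen_display_spec(
    duration_s: float = 5.4,
    frame_rate_hz: float = 30.0,
    movement_onset_s: float = 2.5,
    grasp_s: float = 3.5,
    resolution: tuple[int, int] = (1920, 1200),
    condition: str = "efficient",
    hammer_s: float = 4.3,
) -> DisplaySpec:
    """Scripted AOI trajectories for one stimulus video.

    The dominant hand rests until movement onset, reaches the hammer by
    ``grasp_s``, then hammer and hand travel together to the peg by
    ``hammer_s`` and pound until the video ends.  The depth history records
    each time a moving AOI enters the space of another AOI (that mover is
    then front-most in the overlap).
    """
    if not (0 < movement_onset_s < grasp_s < hammer_s < duration_s):
        raise ValueError("require 0 < movement_onset < grasp < hammer < duration")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")

    n_frames = int(round(duration_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    scale = np.array([resolution[0] / 1920.0, resolution[1] / 1200.0,
                      resolution[0] / 1920.0, resolution[1] / 1200.0])

    rest = {k: np.asarray(v) * scale for k, v in _REST_RECTS.items()}
    tracks = {k: np.tile(rest[k], (n_frames, 1)) for k in AOI_NAMES}

    def _center(r):
        return np.array([(r[0] + r[2]) / 2, (r[1] + r[3]) / 2])

    def _rect_about(center, ref):
        w, h = ref[2] - ref[0], ref[3] - ref[1]
        return np.array([center[0] - w / 2, center[1] - h / 2,
                         center[0] + w / 2, center[1] + h / 2])

    hand_rest_c = _center(rest["dominant_hand"])
    hammer_rest_c = _center(rest["hammer"])
    peg_c = _center(rest["peg"])

    # reach: hand rest -> hammer; transport: hammer+hand -> peg
    for i, ti in enumerate(t):
        if ti < movement_onset_s:
            continue
        if ti < grasp_s:
            u = (ti - movement_onset_s) / (grasp_s - movement_onset_s)
            c = hand_rest_c + u * (hammer_rest_c - hand_rest_c)
            tracks["dominant_hand"][i] = _rect_about(c, rest["dominant_hand"])
        elif ti < hammer_s:
            u = (ti - grasp_s) / (hammer_s - grasp_s)
            c = hammer_rest_c + u * (peg_c - hammer_rest_c)
            tracks["hammer"][i] = _rect_about(c, rest["hammer"])
            tracks["dominant_hand"][i] = _rect_about(c, rest["dominant_hand"])
        else:
            tracks["hammer"][i] = _rect_about(peg_c, rest["hammer"])
            tracks["dominant_hand"][i] = _rect_about(peg_c, rest["dominant_hand"])

    # depth history: first frame each moving AOI overlaps another AOI
    history: list[tuple[float, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for i, ti in enumerate(t):
        moving = [
            name for name in AOI_NAMES
            if i > 0 and not np.allclose(tracks[name][i], tracks[name][i - 1])
        ]
        for mover in moving:
            for other in AOI_NAMES:
                if other == mover:
                    continue
                pair = (mover, other)
                if _rects_overlap(tracks[mover][i], tracks[other][i]):
                    if pair not in seen:
                        seen.add(pair)
                        history.append((float(ti), mover, other))
                else:
                    seen.discard(pair)  # re-entry counts again

    events = {
        "onset": 0.0,
        "movement": float(movement_onset_s),
        "grasp": float(grasp_s),
        "hammer": float(hammer_s),
        "end": float(duration_s),
    }
    return DisplaySpec(
        resolution=tuple(resolution),
        fps=float(frame_rate_hz),
        events=events,
        condition=condition,
        aoi_tracks=tracks,
        depth_history=history,
        depth_order=("dominant_hand", "hammer", "peg", "face", "non_dominant_hand"),
    )


# ---------------------------------------------------------------------------
# stimulus rendering (for looking videos and probability-map overlays)

_AOI_COLORS = {
    "face": (0.80, 0.62, 0.50),
    "peg": (0.70, 0.20, 0.20),
    "non_dominant_hand": (0.20, 0.30, 0.70),
    "hammer": (0.82, 0.78, 0.20),
    "dominant_hand": (0.85, 0.55, 0.18),
}
_BACKGROUND = (0.15, 0.15, 0.15)
# Initial-grip appearance during the reach: the one condition-dependent
# region of the display (underhand vs overhand preshape of the hand).
_GRIP_COLORS = {"efficient": (0.95, 0.78, 0.40), "inefficient": (0.50, 0.30, 0.08)}


def render_frame(display: DisplaySpec, frame_idx: int, scale: int = 1) -> np.ndarray:
    """Render one synthetic stimulus frame as an (H/scale, W/scale, 3) RGB image.

    AOIs are drawn as flat-colored rectangles, back to front.  During the
    reach interval the dominant hand is drawn in a condition-dependent
    color (the visible difference between initial grips); at all other
    times, and for localizer conditions, its appearance is identical
    across conditions.
    """
    w, h = display.resolution
    if w % scale or h % scale:
        raise ValueError("scale must divide the display resolution")
    img = np.empty((h // scale, w // scale, 3), np.float32)
    img[:] = _BACKGROUND
    t = frame_idx / display.fps
    in_reach = display.events["movement"] <= t < display.events["grasp"]
    # back-to-front: irrelevant AOIs, then peg, hammer, hand (front during reach)
    for name in ("face", "non_dominant_hand", "peg", "hammer", "dominant_hand"):
        color = _AOI_COLORS[name]
        if name == "dominant_hand" and in_reach and display.condition in _GRIP_COLORS:
            color = _GRIP_COLORS[display.condition]
        x0, y0, x1, y1 = display.aoi_tracks[name][frame_idx] / scale
        img[int(y0):int(np.ceil(y1)), int(x0):int(np.ceil(x1))] = color
    return img


# ---------------------------------------------------------------------------
# gaze + pupil generation

def _fixation_schedule(display: DisplaySpec, profile: SimProfile, condition: str,
                       rng: np.random.Generator) -> list[tuple[float, float, str]]:
    """Piecewise-constant fixation targets: (start_s, end_s, aoi_name)."""
    ev = display.events
    segs: list[tuple[float, float, str]] = []
    if profile.label == "child_like":
        shift = min(ev["movement"] + profile.anticipation_latency, ev["end"])
        segs.append((0.0, shift, "face"))
        segs.append((shift, ev["end"], "peg"))
        return segs

    segs.append((0.0, ev["movement"], "face"))
    # reach: alternate hammer/hand, hammer share modulated by condition
    delta = 0.15 * profile.gaze_condition_effect
    p_hammer = 0.5 + (delta if condition == "inefficient" else -delta)
    p_hammer = float(np.clip(p_hammer, 0.05, 0.95))
    t = ev["movement"]
    while t < ev["grasp"]:
        dur = rng.uniform(0.20, 0.35)
        target = "hammer" if rng.random() < p_hammer else "dominant_hand"
        segs.append((t, min(t + dur, ev["grasp"]), target))
        t += dur
    # transport + pounding: alternate hammer (in transit) and peg
    t = ev["grasp"]
    while t < ev["hammer"]:
        dur = rng.uniform(0.20, 0.35)
        target = "hammer" if rng.random() < 0.5 else "peg"
        segs.append((t, min(t + dur, ev["hammer"]), target))
        t += dur
    segs.append((ev["hammer"], ev["end"], "peg"))
    return segs


def gen_gaze_recording(
    display: DisplaySpec,
    profile: SimProfile,
    condition: str,
    sampling_hz: float = 120.0,
    seed: int = 0,
    jitter_px: float = 15.0,
    blink_fraction: float = 0.02,
    pupil_baseline: float = 4.0,
    participant_id: str = "sim",
    trial_id: int = 0,
) -> GazeRecording:
    """One trial of 120 Hz gaze + pupil samples following the profile's scanpath.

    Jitter totals ``jitter_px`` (1 SD per axis), split into slow AR(1)
    drift and fast white tremor so that dispersion-based fixation
    detection at tracker-typical thresholds behaves as it does on real
    recordings.  Blinks occupy ``blink_fraction`` of samples in contiguous
    runs: position invalid, pupil 0.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, display.duration_s, 1.0 / sampling_hz)
    n = t.size

    segs = _fixation_schedule(display, profile, condition, rng)
    x = np.empty(n)
    y = np.empty(n)
    for start, end, name in segs:
        m = (t >= start) & (t < end)
        if not m.any():
            continue
        r = display.aoi_tracks[name][display.frame_at(start)]
        x[m] = (r[0] + r[2]) / 2
        y[m] = (r[1] + r[3]) / 2
    # slow drift (AR(1)) + fast tremor, total SD = jitter_px per axis
    rho = 0.998
    drift_sd = 0.98 * jitter_px
    tremor_sd = 0.20 * jitter_px
    eps = rng.normal(0, drift_sd * np.sqrt(1 - rho**2), (2, n))
    drift = np.empty((2, n))
    drift[:, 0] = rng.normal(0, drift_sd, 2)
    for i in range(1, n):
        drift[:, i] = rho * drift[:, i - 1] + eps[:, i]
    x = x + drift[0] + rng.normal(0, tremor_sd, n)
    y = y + drift[1] + rng.normal(0, tremor_sd, n)
    w, h = display.resolution
    x = np.clip(x, 0, w)
    y = np.clip(y, 0, h)

    # pupil: smooth baseline + noise (+ dilation bump on inefficient trials)
    phase = rng.uniform(0, 2 * np.pi)
    pupil = 1.0 + 0.01 * np.sin(2 * np.pi * 0.1 * t + phase) + rng.normal(0, 0.01, n)
    if condition == "inefficient" and profile.pupil_effect != 0:
        b0 = display.events["grasp"] + profile.pupil_window[0]
        b1 = display.events["grasp"] + profile.pupil_window[1]
        c, wdt = (b0 + b1) / 2, b1 - b0
        inwin = (t >= b0) & (t <= b1)
        bump = np.zeros(n)
        bump[inwin] = 0.5 * (1 + np.cos(2 * np.pi * (t[inwin] - c) / wdt))
        amp = profile.pupil_effect / 100.0 * rng.normal(1.0, 0.05)
        pupil = pupil + amp * bump
    pupil = pupil * pupil_baseline

    valid = np.ones(n, bool)
    if blink_fraction > 0:
        target = int(round(blink_fraction * n))
        covered = 0
        while covered < target:
            dur = int(rng.uniform(0.15, 0.30) * sampling_hz)
            start = int(rng.integers(0, max(n - dur, 1)))
            sl = slice(start, min(start + dur, n))
            covered += int(np.sum(valid[sl]))
            valid[sl] = False
    x[~valid] = np.nan
    y[~valid] = np.nan
    pupil[~valid] = 0.0

    return GazeRecording(
        participant_id=participant_id, trial_id=trial_id, condition=condition,
        t=t, x=x, y=y, pupil=pupil, valid=valid,
    )


# ---------------------------------------------------------------------------
# EEG generation

def _shaped_noise(rng, n_samples, sfreq, rms):
    """1/f-power background noise via spectral shaping of white noise."""
    freqs = np.fft.rfftfreq(n_samples, 1 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(np.maximum(freqs[1:], 1.0))
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)) * shape
    sig = np.fft.irfft(spec, n=n_samples)
    sig *= rms / np.std(sig)
    return sig


def _band_noise(rng, n_samples, sfreq, band, rms):
    """Gaussian noise band-limited to ``band`` (flat in-band spectrum)."""
    freqs = np.fft.rfftfreq(n_samples, 1 / sfreq)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(freqs.size, complex)
    spec[keep] = rng.normal(size=keep.sum()) + 1j * rng.normal(size=keep.sum())
    sig = np.fft.irfft(spec, n=n_samples)
    sig *= rms / np.std(sig)
    return sig


def gen_eeg_epochs(
    profile: SimProfile,
    condition: str,
    n_epochs: int,
    n_channels: int = 32,
    sfreq: float = 500.0,
    epoch_window: tuple[float, float] = (-1.5, 2.9),
    seed: int = 0,
    osc_rms_uv: float = 20.0,
    noise_rms_uv: float = 3.0,
    amp_jitter_log10: float = 0.05,
    suppression_jitter_log10: float = 0.12,
) -> EEGEpochSet:
    """Epoched EEG: 1/f background plus a mu-band source over sensorimotor sites.

    The mu source is band-limited noise in ``profile.mu_band`` whose
    amplitude after time 0 is scaled so the expected post/baseline log10
    power ratio equals ``mu_suppression_logratio``, deepened
    (resp. lightened) by half of ``eeg_condition_effect`` on inefficient
    (resp. efficient) trials.  Per-epoch log-normal jitter on both the
    baseline amplitude and the suppression depth provides trial-to-trial
    variability.
    """
    lo, hi = epoch_window
    if not (lo < 0 < hi):
        raise ValueError("epoch_window must span negative and positive time")
    if profile.mu_band[1] >= sfreq / 2:
        raise ValueError("sampling rate too low for mu band (Nyquist)")
    if n_channels < 1 or n_channels > len(EEG_CHANNELS_32):
        raise ValueError("n_channels must be in [1, 32]")

    rng = np.random.default_rng(seed)
    channels = EEG_CHANNELS_32[:n_channels]
    times = np.arange(round(lo * sfreq), round(hi * sfreq)) / sfreq
    n_samp = times.size
    post = times >= 0
    # 50 ms cosine ramp at onset to avoid a spectral click
    ramp = np.ones(n_samp)
    sel = (times >= 0) & (times < 0.05)
    ramp[sel] = 0.5 * (1 - np.cos(np.pi * times[sel] / 0.05))

    if condition == "inefficient":
        delta = -profile.eeg_condition_effect / 2.0
    elif condition == "efficient":
        delta = +profile.eeg_condition_effect / 2.0
    else:  # localizer videos carry no condition effect
        delta = 0.0

    data = np.empty((n_epochs, n_channels, n_samp))
    labels = [condition] * n_epochs
    for e in range(n_epochs):
        logratio = profile.mu_suppression_logratio + delta + \
            rng.normal(0, suppression_jitter_log10)
        m = np.sqrt(10.0 ** logratio)
        envelope = np.where(post, 1.0 + (m - 1.0) * ramp, 1.0)
        amp = 10.0 ** rng.normal(0, amp_jitter_log10)
        for c, name in enumerate(channels):
            sig = _shaped_noise(rng, n_samp, sfreq, noise_rms_uv)
            gain = MU_CHANNEL_GAINS.get(name, 0.0)
            if gain > 0:
                mu = _band_noise(rng, n_samp, sfreq, profile.mu_band,
                                 osc_rms_uv * gain * amp)
                sig = sig + mu * envelope
            data[e, c] = sig
    return EEGEpochSet(data=data, sfreq=sfreq, times=times,
                       channel_names=channels, labels=labels)


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass
class ParticipantData:
    """Everything simulated for one observer."""

    participant_id: str
    profile: SimProfile
    displays: dict[str, DisplaySpec]
    gaze: list[GazeRecording]
    eeg_test: EEGEpochSet
    eeg_localizer: EEGEpochSet


def simulate_participant(
    profile: SimProfile,
    participant_id: str,
    seed: int,
    n_trials_per_condition: int = 24,
    n_localizer_trials: int = 48,
    display_kwargs: dict | None = None,
    with_eeg: bool = True,
) -> ParticipantData:
    """Simulate one observer's full session (48 test + 48 localizer videos)."""
    rng = np.random.default_rng(seed)
    dkw = dict(display_kwargs or {})
    displays = {c: gen_display_spec(condition=c, **dkw)
                for c in ("efficient", "inefficient")}

    gaze: list[GazeRecording] = []
    trial = 0
    for k in range(n_trials_per_condition):
        for cond in ("efficient", "inefficient"):
            gaze.append(
                gen_gaze_recording(
                    displays[cond], profile, cond,
                    seed=int(rng.integers(2**31)),
                    participant_id=participant_id, trial_id=trial,
                )
            )
            trial += 1

    eeg_test = eeg_loc = None
    if with_eeg:
        half = n_trials_per_condition
        eff = gen_eeg_epochs(profile, "efficient", half, seed=int(rng.integers(2**31)))
        ineff = gen_eeg_epochs(profile, "inefficient", half, seed=int(rng.integers(2**31)))
        eeg_test = EEGEpochSet(
            data=np.concatenate([eff.data, ineff.data]),
            sfreq=eff.sfreq, times=eff.times, channel_names=eff.channel_names,
            labels=eff.labels + ineff.labels,
        )
        eeg_loc = gen_eeg_epochs(profile, "localizer_a", n_localizer_trials,
                                 seed=int(rng.integers(2**31)))
    return ParticipantData(
        participant_id=participant_id, profile=profile, displays=displays,
        gaze=gaze, eeg_test=eeg_test, eeg_localizer=eeg_loc,
    )


def iter_cohort(config: SimCohortConfig, with_eeg: bool = True):
    """Yield :class:`ParticipantData` one observer at a time (memory-friendly)."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(config.n_participants) % (2**31)
    for i in range(config.n_participants):
        yield simulate_participant(
            config.profile, f"{config.profile.label}_{i:02d}", int(seeds[i]),
            n_trials_per_condition=config.n_trials_per_condition,
            n_localizer_trials=config.n_localizer_trials,
            display_kwargs=config.display, with_eeg=with_eeg,
        )
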