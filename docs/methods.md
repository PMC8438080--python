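# Methods

This note documents the models, defaults, and numerical choices behind
`observa`: what the synthetic cohorts emulate, how each analysis stage is
defined, and where design decisions were genuinely open.

## Paradigm and coordinate conventions

Observers watch 5.4 s videos (30 Hz) of an actor grasping a hammer and
pounding a peg on a 1920×1200 display.  Scripted event times: movement
onset 2.5 s after display onset, initial grasp 3.5 s, arrival at the peg
("hammering") 4.3 s, video end 5.4 s.  Trials are *efficient* (underhand
initial grip), *inefficient* (overhand initial grip), or grip-neutral
*localizer* actions.  A session comprises 96 videos: 48 test trials
(24 per condition) and 48 localizer trials.  Gaze and pupil are sampled
at 120 Hz; EEG at 500 Hz from a 32-channel extended 10–20 montage.
Pixels use a top-left origin, x rightward, y downward; times are seconds
from display onset except EEG epoch times, which are relative to
movement onset.

## Synthetic cohorts

The simulator generates the statistical structure the analyses assume,
not photorealistic stimuli.  Displays are flat-colored AOI rectangles
following the scripted trajectory (hand reaches the hammer by grasp
time; hammer + hand travel to the peg by hammering time).  The *only*
condition-dependent pixels are the dominant hand's appearance during the
reach interval — the visible difference between initial grips.  This
placement is deliberate: an observer who samples the hand/hammer region
during the reach acquires condition information; one who looks at the
face or peg acquires none, making their trials exchangeable across
condition labels by construction (the basis of the type-I checks).

Observer profiles:

| parameter | adult_like | child_like | meaning |
|---|---|---|---|
| gaze_condition_effect | 1.0 | 0.0 | modulation of hammer-vs-hand looking during reach (the hammer share of reach fixations is 0.5 ± 0.15·effect by condition) |
| pupil_effect | 10 %% | 0 | peak dilation on inefficient trials, % of baseline |
| mu_band | 8–13 Hz | 6–9 Hz | age-typical mu rhythm band |
| mu_suppression_logratio | −0.42 | −0.94 | post/baseline log10 power ratio of the mu source |
| eeg_condition_effect | 0.3 | 0.0 | condition difference in that log-ratio (inefficient deeper) |
| anticipation_latency | — | 0.3 s | delay after movement onset before the gaze jumps to the peg |

The mu suppression depths are the age-group means reported for this
paradigm; the condition effect sizes are not quantified anywhere in the
literature for this task, so they are free parameters with defaults
chosen to produce clearly separable adult-like observers (classification
accuracies in the 75–95 % range) without being trivially perfect.

**Scanpaths** are piecewise-constant fixation targets (AOI centers at
segment start) with additive Gaussian jitter totalling σ = 15 px per
axis.  The jitter is split into a slow AR(1) drift (ρ = 0.998, σ ≈ 14.7)
plus fast white tremor (σ = 3): purely white jitter at σ = 15 would give
a windowed dispersion (x-range + y-range) near 100 px over 300 ms and no
dispersion-based algorithm at tracker-typical thresholds could ever form
a fixation; correlated drift + small tremor is also a better model of
video-based tracker noise.  Adult-like observers fixate the face until
movement onset, alternate hammer/hand during the reach (segment lengths
0.20–0.35 s), alternate hammer/peg during transport, and end on the peg;
child-like observers jump from the face to the peg `anticipation_latency`
after movement onset and stay there.  Blinks occupy ~2 % of samples in
contiguous 150–300 ms runs (position invalid, pupil 0).

**Pupil** is a smooth baseline (4 a.u.) with a 0.1 Hz sinusoidal drift
(±1 %), white noise (σ = 1 %), and — on inefficient trials only — a
raised-cosine dilation of amplitude `pupil_effect` supported exactly on
0.7–1.4 s after grasp, with 5 % relative amplitude jitter per trial.
This matches the qualitative time course of task-evoked dilation without
claiming a physiological model.

**EEG** epochs are 1/f-shaped background noise (RMS 3 µV) plus a
band-limited-noise mu source (RMS 20 µV at full gain) on C3/C4 (gain 1),
CP1/CP2 (0.8), FC1/FC2 (0.6).  After t = 0 the source amplitude is
scaled by √(10^L) with
L = mu_suppression_logratio ± eeg_condition_effect/2 + per-epoch jitter
(σ = 0.12 log10 units; baseline amplitude jitter σ = 0.05), through a
50 ms cosine ramp.  The oscillation-to-noise power ratio in-band is
≈ 200:1, so the measured ERSP tracks the injected log-ratio with < 0.01
noise-floor bias.  What the generator does **not** emulate: volume
conduction, eye/muscle artifacts, non-stationary background spectra,
actor/identity variation, smooth pursuit.  Green tests therefore show
the *analysis chain* is correct and calibrated, not that the pipeline is
robust to every pathology of real recordings.

## Gaze analysis

AOI conflicts resolve to the **front-most** AOI: the candidate with the
most recent depth-history entry (the AOI that last moved into another's
space) at or before the sample time; with no applicable entry, a fixed
resting depth order (hand, hammer, peg, face, non-dominant hand)
decides.  Fixation detection is I-DT: a window grows while
(x-range + y-range) ≤ 50 px; windows shorter than 100 ms are discarded;
runs split at invalid samples.  Fixations take the majority per-sample
AOI label (ties to the earliest-assigned).  Percent dwell uses valid
samples in both numerator and denominator; percent fixation time
normalizes by summed fixation duration; revisits count entries from
outside the AOI including the first.  Gaze shifts require consecutive
AOI-labeled fixations on different AOIs with an inter-fixation gap
≤ 100 ms and pool both directions per unordered pair (10 pairs).

## Probability maps

A pixel is covered on a frame when its center lies within 75 px
(inclusive, matching "within a radius" literally) of the gaze point
nearest the frame time (within half a frame; otherwise the frame covers
nothing but still counts in the denominator).  The group comparison runs
a pixel-wise Welch *t* with BH-FDR over **all** pixels of the grid (the
correction family is stated rather than implicit; pixels with zero
variance in both groups get p = 1 — no variance, no evidence).  An
integer `downsample` factor (default 1) trades resolution for speed and
is recorded in the map.

## Looking-video classification

Masking keeps the disk of radius 75 px around the gaze interpolated to
each frame (nearest valid sample within half a frame; else the frame is
black).  The default feature extractor is an 8×8 spatial grid of
per-channel means (192 dims/frame): deterministic, dependency-free, and
sufficient because the classifier's burden is *where and when* the
observer looked, not object recognition; a pretrained-CNN extractor can
be registered via `register_extractor`.  Sequences are pooled by
concatenated temporal mean and max (384 dims) and classified with a
least-squares SVM, C = 1, solved in closed form on the Gram matrix (the
dual system with bias).  Accuracy = mean % correct over 500 repetitions
of holding out one random trial per condition (training set 46 of 48
trials).  The shuffle null permutes labels (default 1000 shuffles; 200
in the desk-scale cohort checks) and re-runs the identical procedure
with 50 repetitions per shuffle — a recorded cost compromise; the +1
permutation correction gives p.  Because the pipeline renders synthetic
displays, it rasterizes them at 1/10 scale (192×120, radius 7.5 px) —
the 8×8 pooling is invariant to this beyond rounding.

## Pupillometry

Artifact rule: a sample is rejected when invalid, non-positive, or its
residual from a 500 ms rolling median exceeds 5 scaled MADs, with a
±50 ms margin.  The residual form matters: blinks and saccadic spikes
are *fast*, so they stand out from the rolling median, while slow
physiological dilation (±10–20 % of baseline over ~1 s) rides inside it
— a deviation-from-global-median rule would censor the very effect under
study.  Gaps ≤ 300 ms are linearly interpolated; trials > 50 % missing
are excluded.  Baseline is the mean over the first 1250 ms of the
display; traces are mean-binned to 30 Hz, aligned to movement onset, and
expressed as % of baseline.  Condition comparison: per-timepoint Welch
*t* on participant-mean traces (one value per participant per
timepoint — matching a between-groups df of n₁+n₂−2), BH-FDR across all
timepoints from movement onset to video end, contiguous significant
windows reported.

## EEG

Filtering is a 4th-order zero-phase Butterworth band-pass 1–45 Hz
(≈24 dB/octave per pass); re-referencing subtracts the mastoid average;
ICA-style ocular cleanup is an injectable hook, not reimplemented.
ERSP uses 7-cycle Morlet wavelets (fixed across frequencies, recorded in
the map), decimated to 20 Hz, with cells within one wavelet half-length
of the epoch edges flagged and excluded from baselines and suppression
indices.  Two baseline forms are used deliberately:

- *Epoch-averaged ERSP* (display, suppression indices):
  log10(mean power / mean baseline power) — the conventional form.
- *Per-epoch values* (localizer, classification features): log10 power
  minus the mean **log** baseline power.  Pointwise spectral power is
  approximately exponential, so E[log P] < log E[P]; with an
  arithmetic-mean baseline every single-epoch log-ratio is biased
  negative under stationary noise and a one-sample test against zero
  flags everything.  The log-domain baseline cancels the bias (verified:
  per-channel false-positive rate ≈ α under a null simulation) while
  keeping the same expectation, log10 m², under a true amplitude
  scaling m.

Suppression-index recovery and group summaries average over 0.5–2.5 s
rather than 0–2.9 s because the wavelet smears the baseline→suppressed
transition over roughly a wavelet length around movement onset.

**Localizer.**  Per channel in the sensorimotor + occipital set (FC1/2/5/6,
C3/C4, CP1/2/5/6, O1, O2 — the members of the conventional FC/C/CP rows
present in a 32-channel montage), cells in the 6–20 Hz × (movement
onset → hammering) box are tested with a one-sample *t* of per-epoch
values; cells with t ≤ −t₀.₀₂₅ are grouped by 4-connectivity (no
cross-channel clustering — results are reported per channel); cluster
mass is the summed *t*.  The null sign-flips whole epochs (valid for a
symmetric one-sample null) and records the per-channel minimum cluster
mass; clusters with +1-corrected p < 0.05 are kept.  Cluster *mass*
(not size) is the recorded choice of statistic.  Localizer and test
epochs are disjoint by construction, so feature selection never touches
the classified data.  Participants with empty localizers are reported as
not classifiable rather than assigned chance accuracy.

**Classification** uses one feature per localizer cluster (mean
per-epoch value over the cluster's cells) and the same LS-SVM + shuffle
protocol as the looking videos.

## Statistics

Welch *t* (two-sample and one-sample) with the Welch–Satterthwaite df;
both-samples-zero-variance returns p = 1, flagged.  BH-FDR is the
step-up procedure (delegated to statsmodels, verified against a
brute-force enumeration).  Sidak adjustment is 1−(1−p)^m.  Factorial
ANOVA is between-subjects fixed-effects OLS with type-II sums of squares
(recorded; types coincide for balanced designs), treating trial-level
measurements as observations by default (a participant-mean analysis is
available by passing aggregated tables).

## Problem sizes and determinism

Every generator and stochastic stage takes a seed; pipeline stages
derive theirs from the global seed plus a stage tag, so identical
configs give bit-identical reports.  The desk-scale validation cohorts
use 8 adult-like and 40 child-like observers with the full 24 trials per
condition, 500 observed LOO repetitions, 200 shuffles × 50 repetitions,
and 1000 localizer permutations; probability-map unit checks run at full
1920×1200 resolution while cohort maps default to a downsampling factor.
These sizes were chosen as the smallest that leave the binomial and
Monte-Carlo margins of the validation checks comfortable.

## Known limitations

- The default feature extractor carries no object semantics; conclusions
  about real videos require the pretrained-extractor hook.
- The LS-SVM replaces the original recurrent sequence classifier; with
  temporally pooled features this is a deliberate trade of model
  capacity for exact reproducibility.
- The localizer's per-channel inference does not correct across
  channels (reported per channel, as is conventional for this design).
- Between-participant EEG variability is limited to amplitude/suppression
  jitter; no spatial covariance structure is simulated.
- Trial usability flags (pupil) and dropped epochs (EEG bounds) are
  surfaced as warnings, not modeled as missing-data mechanisms.
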