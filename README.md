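# observa

Multimodal analysis of action observation: did an observer *see* whether a
multi-step action was performed efficiently?  The package implements, as a
reusable and tested pipeline, the analyses used to answer that question
from eye tracking, pupillometry, and EEG while observers watch short
videos of an actor grasping a hammer (with an efficient underhand or an
inefficient overhand initial grip) and pounding a peg — together with a
synthetic cohort simulator that emulates condition-sensitive
("adult-like") and condition-insensitive ("child-like") observers, so the
whole pipeline can be exercised and validated without human data.

It is aimed at developmental and cognitive neuroscientists who want
vendor-independent, reproducible implementations of:

- **Dynamic AOI gaze metrics.**  Gaze samples are scored against five
  time-varying rectangular areas of interest (hammer, peg, dominant hand,
  non-dominant hand, face); overlaps resolve to the front-most AOI (the
  one that most recently moved into another's space).  Per trial:
  percent dwell time, percent fixation time (I-DT fixations ≥ 100 ms),
  revisits, and gaze shifts (consecutive fixations on different AOIs
  within 100 ms) pooled into the 10 unordered AOI pairs.
- **Temporal fixation-probability maps.**  Per pixel, the fraction of
  reach-interval frames on which the pixel fell within 75 px of gaze;
  group maps are compared pixel-wise with Welch *t* tests under
  Benjamini–Hochberg FDR control (*q* < 0.05).
- **Looking-video classification.**  Each trial's display is masked to
  black outside the 75 px gaze disk ("looking video"), converted to a
  frame-feature sequence (default: 8×8×3 grid means, no pretrained
  weights required; a pretrained-CNN hook is pluggable), temporally
  pooled, and classified per participant with a least-squares SVM
  (C = 1): accuracy is the mean over 500 repetitions of holding out one
  trial per condition, and significance comes from a 1000-fold
  label-shuffle null with p = (1 + #{null ≥ obs}) / (1 + n).
- **Pupillometry.**  Artifact cleaning (fast deviations from a rolling
  median; interpolation of gaps ≤ 300 ms), percent-of-baseline
  normalization (baseline = first 1250 ms), 30 Hz resampling aligned to
  movement onset, and a time-resolved FDR-corrected condition comparison
  on participant-mean traces.
- **EEG mu suppression.**  Butterworth 1–45 Hz zero-phase filtering,
  mastoid re-referencing, epoching −1.5 to +2.9 s around movement onset;
  event-related spectral perturbation via 7-cycle Morlet wavelets,
  ERSP(f, t) = log10 P(f, t) / P̄_baseline(f); suppression indices as box
  averages (mu band: 8–13 Hz adults, 6–9 Hz children).  An
  individualized localizer finds per-channel clusters of significant
  suppression (6–20 Hz, movement onset → hammering; one-sample *t* with
  sign-flip permutation, 4-connected cluster mass) on localizer-video
  epochs, and test-video trials are classified from the mean suppression
  in those clusters with the same LS-SVM + shuffle-null protocol.

## Worked example

Simulate one condition-sensitive observer and classify their looking
videos:

```python
import numpy as np
from observa import SimProfile, simulate_participant
from observa.pipeline import participant_classifications

part = simulate_participant(SimProfile.adult_like(), "adult_00", seed=1)
res = participant_classifications(part, n_reps=500, n_shuffles=200, seed=7)
print(res["looking_video"], res["eeg"])
```

```
{'accuracy': 92.6, 'p': 0.004975124378109453} {'accuracy': 81.9, 'p': 0.004975124378109453}
```

The observer's gaze sampled the actor's initial grip during the reach, so
both the gaze-contingent video classifier and the localizer-driven EEG
classifier separate efficient from inefficient trials far above the
shuffle null (chance = 50%; p is the +1-corrected permutation p against
200 shuffles, so 0.005 means the observed accuracy beat every shuffle).
A `SimProfile.child_like()` observer — who shifts gaze to the goal target
early and carries no condition-dependent physiology — yields accuracies
within the null band instead.

The command line mirrors the library: `observa simulate`, `observa aoi`,
`observa probmap`, `observa lookvid`, `observa pupil`, `observa eeg`, and
`observa run --config cfg.yaml` for an end-to-end, seed-deterministic run
that writes `report.json`.

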