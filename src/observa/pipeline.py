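"""End-to-end orchestration: simulate -> analyze -> report.

`run_pipeline` simulates an adult-like and a child-like cohort, runs every
analysis stage (AOI looking measures, gaze-shift matrices, probability
maps with group comparison, looking-video classification, pupillometry,
EEG localizer + classification, suppression indices), and writes a
deterministic ``report.json`` plus tidy tables under the run directory.
Every stochastic stage receives a seed derived from the global seed and a
stable stage tag, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import eeg, gaze, localizer, lookingvideo, probmaps, pupil
from .stats import stage_seed
from .synthetic import (SENSORIMOTOR_OCCIPITAL, SimCohortConfig, SimProfile,
                        iter_cohort)

log = logging.getLogger("observa")

#: scale presets: problem sizes for a desk run vs the full protocol
PRESETS = {
    "desk": dict(n_participants=4, n_trials_per_condition=8, n_localizer_trials=16,
                 n_reps=100, n_shuffles=100, n_reps_per_shuffle=20,
                 n_perm_localizer=200, map_downsample=8, video_scale=10),
    "full": dict(n_participants=22, n_trials_per_condition=24, n_localizer_trials=48,
                 n_reps=500, n_shuffles=1000, n_reps_per_shuffle=50,
                 n_perm_localizer=1000, map_downsample=4, video_scale=10),
}


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    preset: str = "desk"
    alpha: float = 0.05
    q_fdr: float = 0.05
    radius_px: float = 75.0
    ersp_freqs: tuple[float, float, float] = (4.0, 25.0, 1.0)  # lo, hi, step
    overrides: dict = field(default_factory=dict)

    def params(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        p = dict(PRESETS[self.preset])
        p.update(self.overrides)
        return p

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        return cls(**obj)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def summarize_significance(results: dict[str, dict[str, float]],
                           alpha: float = 0.05) -> dict:
    """Counts/fractions of participants with p < alpha per group per modality.

    ``results`` maps group -> {participant_id: p_value}.
    """
    if not results or all(len(v) == 0 for v in results.values()):
        raise ValueError("no classification results to summarize")
    out = {}
    for group, ps in results.items():
        n_sig = sum(1 for p in ps.values() if p < alpha)
        out[group] = {"n": len(ps), "n_significant": n_sig,
                      "fraction": n_sig / len(ps) if ps else 0.0}
    return out


def participant_classifications(
    part,
    n_reps: int = 500,
    n_shuffles: int = 1000,
    n_reps_per_shuffle: int = 50,
    n_perm_localizer: int = 1000,
    seed: int = 0,
    video_scale: int = 10,
    ersp_freqs: np.ndarray | None = None,
) -> dict:
    """Both per-participant classifiers on one simulated observer.

    Runs the looking-video pathway (render, mask, pool, LS-SVM + shuffle
    null) and the EEG pathway (localizer on localizer-video epochs,
    suppression features on test-video epochs, LS-SVM + shuffle null).
    Returns ``{"looking_video": {accuracy, p}, "eeg": {accuracy, p} | None}``
    (``None`` when the localizer is empty: not classifiable).
    """
    if ersp_freqs is None:
        ersp_freqs = np.arange(4.0, 25.5, 1.0)
    frames = {c: lookingvideo.render_video(d, scale=video_scale)
              for c, d in part.displays.items()}
    feats = np.stack([
        lookingvideo.trial_features(g, part.displays[g.condition],
                                    scale=video_scale, frames=frames[g.condition])
        for g in part.gaze
    ])
    labels = np.array([g.condition for g in part.gaze])
    res_lv = lookingvideo.classify_participant(
        feats, labels, n_reps=n_reps, n_shuffles=n_shuffles,
        n_reps_per_shuffle=n_reps_per_shuffle, seed=seed,
    )
    out = {"looking_video": {"accuracy": res_lv.accuracy, "p": res_lv.p_value}}

    loc_set = [c for c in SENSORIMOTOR_OCCIPITAL
               if c in part.eeg_localizer.channel_names]
    lr_loc, times = eeg.epoch_log_ratio(part.eeg_localizer.pick(loc_set), ersp_freqs)
    ev = part.displays["efficient"].events
    loc = localizer.run_localizer(
        lr_loc, ersp_freqs, times, loc_set, loc_set,
        search_times=(0.0, ev["hammer"] - ev["movement"]),
        n_perm=n_perm_localizer, seed=seed + 1,
        participant_id=part.participant_id,
    )
    if loc.clusters:
        lr_test, _ = eeg.epoch_log_ratio(part.eeg_test.pick(loc_set), ersp_freqs)
        feats_eeg = localizer.extract_features(lr_test, ersp_freqs, times,
                                               loc_set, loc)
        res_eeg = localizer.classify_eeg(
            feats_eeg, np.array(part.eeg_test.labels), n_reps=n_reps,
            n_shuffles=n_shuffles, n_reps_per_shuffle=n_reps_per_shuffle,
            seed=seed + 2,
        )
        out["eeg"] = {"accuracy": res_eeg.accuracy, "p": res_eeg.p_value}
    else:
        out["eeg"] = None
    return out


def _analyze_participant(part, cfg: RunConfig, p: dict) -> dict:
    """All per-participant stages; returns a JSON-ready record."""
    t0 = time.monotonic()
    rec: dict = {"participant": part.participant_id, "profile": part.profile.label}
    seed_base = stage_seed(cfg.seed, part.participant_id)

    # --- gaze: looking measures + transitions ------------------------------
    measures = []
    tm_total = gaze.TransitionMatrix.empty()
    for g in part.gaze:
        disp = part.displays[g.condition]
        fx = gaze.detect_fixations(g, disp)
        m = gaze.looking_measures(g, disp, fx)
        measures.append((g.participant_id, g.trial_id, g.condition, m))
        shifts = gaze.gaze_shifts(fx)
        for k in tm_total.counts:
            tm_total.counts[k] += shifts.counts[k]
    rec["measures"] = gaze.measures_table(measures).to_dict("records")
    rec["transitions"] = {f"{a}|{b}": c for (a, b), c in tm_total.counts.items()}

    # --- probability map (reach interval) ----------------------------------
    maps = [
        probmaps.participant_map(g, part.displays[g.condition],
                                 radius_px=cfg.radius_px,
                                 downsample=p["map_downsample"])
        for g in part.gaze
    ]
    rec["_map"] = probmaps.group_map(maps)  # per-participant mean map

    # --- looking-video classification ---------------------------------------
    frames = {c: lookingvideo.render_video(d, scale=p["video_scale"])
              for c, d in part.displays.items()}
    feats = np.stack([
        lookingvideo.trial_features(g, part.displays[g.condition],
                                    radius_px=cfg.radius_px,
                                    scale=p["video_scale"],
                                    frames=frames[g.condition])
        for g in part.gaze
    ])
    labels = np.array([g.condition for g in part.gaze])
    res_lv = lookingvideo.classify_participant(
        feats, labels, n_reps=p["n_reps"], n_shuffles=p["n_shuffles"],
        n_reps_per_shuffle=p["n_reps_per_shuffle"], seed=seed_base + 1,
    )
    rec["looking_video"] = {"accuracy": res_lv.accuracy, "p": res_lv.p_value}

    # --- pupil traces -------------------------------------------------------
    traces = []
    for g in part.gaze:
        cleaned = pupil.preprocess_pupil(g)
        if not cleaned.usable:
            log.warning("dropping unusable pupil trial %s/%s", g.participant_id, g.trial_id)
            continue
        traces.append(pupil.normalize_trace(cleaned, part.displays[g.condition].events,
                                            recording=g))
    rec["_pupil_traces"] = traces

    # --- EEG: localizer on localizer videos, classify test videos -----------
    lo, hi, step = cfg.ersp_freqs
    freqs = np.arange(lo, hi + step / 2, step)
    loc_set = [c for c in SENSORIMOTOR_OCCIPITAL
               if c in part.eeg_localizer.channel_names]
    loc_epochs = part.eeg_localizer.pick(loc_set)
    lr_loc, times = eeg.epoch_log_ratio(loc_epochs, freqs)
    ev = part.displays["efficient"].events
    search_times = (0.0, ev["hammer"] - ev["movement"])
    loc = localizer.run_localizer(
        lr_loc, freqs, times, loc_set, loc_set,
        search_times=search_times, n_perm=p["n_perm_localizer"],
        alpha=cfg.alpha, seed=seed_base + 2, participant_id=part.participant_id,
    )
    rec["localizer"] = loc.summary()

    mu = part.profile.mu_band
    ersp_loc = eeg.compute_ersp(loc_epochs, freqs)
    rec["mu_suppression_index"] = eeg.suppression_index(
        ersp_loc, mu, (0.5, 2.5), channels=[c for c in loc_set if c not in ("O1", "O2")]
    )

    if loc.clusters:
        test_epochs = part.eeg_test.pick(loc_set)
        lr_test, _ = eeg.epoch_log_ratio(test_epochs, freqs)
        feats_eeg = localizer.extract_features(lr_test, freqs, times, loc_set, loc)
        res_eeg = localizer.classify_eeg(
            feats_eeg, np.array(part.eeg_test.labels), n_reps=p["n_reps"],
            n_shuffles=p["n_shuffles"], n_reps_per_shuffle=p["n_reps_per_shuffle"],
            seed=seed_base + 3,
        )
        rec["eeg"] = {"accuracy": res_eeg.accuracy, "p": res_eeg.p_value,
                      "n_features": feats_eeg.shape[1]}
    else:
        rec["eeg"] = {"accuracy": None, "p": None, "not_classifiable": True}

    log.info("participant %s analyzed in %.1fs", part.participant_id,
             time.monotonic() - t0)
    return rec


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages for both cohorts and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.params()
    report: dict = {"config": asdict(cfg), "config_hash": cfg.hash(),
                    "params": p, "groups": {}}

    group_maps: dict[str, list] = {}
    pupil_traces: dict[str, list] = {}
    p_values = {"looking_video": {}, "eeg": {}}

    for label, profile in (("adult_like", SimProfile.adult_like()),
                           ("child_like", SimProfile.child_like())):
        cohort = SimCohortConfig(
            n_participants=p["n_participants"], profile=profile,
            seed=stage_seed(cfg.seed, f"simulate:{label}"),
            n_trials_per_condition=p["n_trials_per_condition"],
            n_localizer_trials=p["n_localizer_trials"],
        )
        parts = []
        group_maps[label] = []
        pupil_traces[label] = []
        for part in iter_cohort(cohort):
            try:
                rec = _analyze_participant(part, cfg, p)
            except Exception:
                log.exception("stage failure at participant %s", part.participant_id)
                raise
            group_maps[label].append(rec.pop("_map"))
            pupil_traces[label].extend(rec.pop("_pupil_traces"))
            parts.append(rec)
            p_values["looking_video"].setdefault(label, {})[part.participant_id] = \
                rec["looking_video"]["p"]
            if rec["eeg"].get("p") is not None:
                p_values["eeg"].setdefault(label, {})[part.participant_id] = rec["eeg"]["p"]
        report["groups"][label] = {"participants": parts}

    # group probability maps + comparison
    cmp_maps = probmaps.compare_maps(group_maps["adult_like"], group_maps["child_like"],
                                     q=cfg.q_fdr)
    report["probability_maps"] = {
        "n_significant_pixels": int(cmp_maps.mask.sum()),
        "grid_shape": list(cmp_maps.mask.shape),
    }

    # pupil condition comparison per group
    report["pupil"] = {}
    for label, traces in pupil_traces.items():
        byp = pupil.participant_mean_traces(traces)
        times = traces[0].t
        conds = {}
        for cond in ("efficient", "inefficient"):
            conds[cond] = np.stack([byc[cond] for byc in byp.values() if cond in byc])
        comp = pupil.compare_conditions(conds, times, q=cfg.q_fdr)
        report["pupil"][label] = {"significant_windows": comp.windows}

    # significance summary per modality
    report["significance"] = {
        mod: summarize_significance(groups, alpha=cfg.alpha)
        for mod, groups in p_values.items() if groups
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))
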