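"""Generators: determinism, scripted geometry, and injected effect sizes."""

import numpy as np
import pytest

from observa.eeg import compute_ersp, suppression_index
from observa.synthetic import (SimCohortConfig, SimProfile, gen_display_spec,
                               gen_eeg_epochs, gen_gaze_recording, iter_cohort,
                               render_frame)


class TestDisplaySpec:
    def test_frame_count_and_events(self, display):
        assert display.n_frames == 162  # 5.4 s at 30 Hz
        assert display.events["movement"] == 2.5
        assert 0 < display.events["movement"] < display.events["grasp"] \
            < display.events["hammer"] < display.events["end"]

    def test_nonincreasing_events_rejected(self):
        with pytest.raises(ValueError):
            gen_display_spec(movement_onset_s=3.5, grasp_s=3.5)
        with pytest.raises(ValueError):
            gen_display_spec(frame_rate_hz=0)

    def test_hand_reaches_hammer_by_grasp(self, display):
        f = display.frame_at(display.events["grasp"])
        hand = display.aoi_tracks["dominant_hand"][f]
        hammer = display.aoi_tracks["hammer"][f]
        # rectangles overlap at grasp
        assert hand[0] <= hammer[2] and hammer[0] <= hand[2]
        assert hand[1] <= hammer[3] and hammer[1] <= hand[3]

    def test_depth_history_marks_hand_frontmost_at_grasp(self, display):
        entries = [(t, m, o) for t, m, o in display.depth_history
                   if m == "dominant_hand" and o == "hammer"]
        assert entries and entries[0][0] <= display.events["grasp"]

    def test_json_round_trip(self, display, tmp_path):
        from observa.containers import DisplaySpec
        p = tmp_path / "d.json"
        display.to_json(p)
        back = DisplaySpec.from_json(p)
        assert back.events == display.events
        for k in display.aoi_tracks:
            np.testing.assert_allclose(back.aoi_tracks[k], display.aoi_tracks[k])
        assert back.depth_history == [(t, a, b) for t, a, b in display.depth_history]


class TestGazeGeneration:
    def test_seed_determinism(self, display, adult_profile):
        a = gen_gaze_recording(display, adult_profile, "efficient", seed=7)
        b = gen_gaze_recording(display, adult_profile, "efficient", seed=7)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.pupil, b.pupil)
        np.testing.assert_array_equal(a.valid, b.valid)

    def test_zero_effect_profiles_condition_invariant(self, display, child_profile):
        """With zero condition effects, equal seeds give identical traces."""
        d_in = gen_display_spec(condition="inefficient")
        a = gen_gaze_recording(display, child_profile, "efficient", seed=3)
        b = gen_gaze_recording(d_in, child_profile, "inefficient", seed=3)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.pupil, b.pupil)

    def test_adult_condition_effect_on_hammer_looking(self, adult_profile):
        """Reach-interval time in the hammer region differs by condition,
        measured by a brute-force per-sample rectangle count."""
        d = {c: gen_display_spec(condition=c) for c in ("efficient", "inefficient")}
        rng = np.random.default_rng(11)

        def brute_hammer_dwell(rec, disp):
            ev = disp.events
            n = 0
            for i in range(rec.t.size):
                t = rec.t[i]
                if not (ev["movement"] <= t < ev["grasp"]) or not rec.valid[i]:
                    continue
                r = disp.aoi_tracks["hammer"][disp.frame_at(t)]
                if r[0] <= rec.x[i] <= r[2] and r[1] <= rec.y[i] <= r[3]:
                    n += 1
            return n

        counts = {c: [] for c in d}
        for _ in range(30):
            for c in d:
                rec = gen_gaze_recording(d[c], adult_profile, c,
                                         seed=int(rng.integers(2**31)))
                counts[c].append(brute_hammer_dwell(rec, d[c]))
        assert np.mean(counts["inefficient"]) > np.mean(counts["efficient"]) + 5

    def test_blink_runs_and_bounds(self, display, adult_profile):
        rec = gen_gaze_recording(display, adult_profile, "efficient", seed=5)
        assert 0.005 < (~rec.valid).mean() < 0.08
        assert np.all(np.isnan(rec.x[~rec.valid]))
        ok = rec.valid
        assert np.all((rec.x[ok] >= 0) & (rec.x[ok] <= display.resolution[0]))

    def test_invalid_sampling_rate(self, display, adult_profile):
        with pytest.raises(ValueError):
            gen_gaze_recording(display, adult_profile, "efficient", sampling_hz=0)


class TestEEGGeneration:
    def test_seed_determinism(self, adult_profile):
        a = gen_eeg_epochs(adult_profile, "efficient", 3, seed=2)
        b = gen_eeg_epochs(adult_profile, "efficient", 3, seed=2)
        np.testing.assert_array_equal(a.data, b.data)

    def test_nyquist_guard(self):
        prof = SimProfile.adult_like()
        with pytest.raises(ValueError, match="Nyquist|mu band"):
            gen_eeg_epochs(prof, "efficient", 2, sfreq=20)

    def test_null_profile_gives_flat_ersp(self):
        prof = SimProfile.adult_like(mu_suppression_logratio=0.0,
                                     eeg_condition_effect=0.0)
        ep = gen_eeg_epochs(prof, "localizer_a", 48, seed=9).pick(["C3", "C4"])
        ersp = compute_ersp(ep, np.arange(6, 20.5, 1.0))
        si = suppression_index(ersp, prof.mu_band, (0.5, 2.5))
        assert abs(si) < 0.05

    def test_amplitude_halving_recovered(self):
        """Halving amplitude post-onset injects a power ratio of 0.25,
        i.e. log10 = -0.602, recovered by the ERSP within tolerance."""
        prof = SimProfile.adult_like(mu_suppression_logratio=np.log10(0.25),
                                     eeg_condition_effect=0.0)
        ep = gen_eeg_epochs(prof, "localizer_a", 60, seed=13,
                            suppression_jitter_log10=0.0).pick(["C3", "C4"])
        ersp = compute_ersp(ep, np.arange(6, 20.5, 1.0))
        si = suppression_index(ersp, prof.mu_band, (0.5, 2.5))
        assert si == pytest.approx(-0.602, abs=0.1)

    def test_channel_labels_extended_1020(self, adult_profile):
        ep = gen_eeg_epochs(adult_profile, "efficient", 2, seed=1)
        assert len(ep.channel_names) == 32
        for c in ("C3", "C4", "FC1", "CP2", "O1", "O2"):
            assert c in ep.channel_names


class TestProfilesAndCohort:
    def test_profile_defaults_follow_age_bands(self, adult_profile, child_profile):
        assert adult_profile.mu_band == (8.0, 13.0)
        assert child_profile.mu_band == (6.0, 9.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            SimProfile.adult_like(mu_band=(13.0, 8.0))

    def test_cohort_config_guard(self, adult_profile):
        with pytest.raises(ValueError):
            SimCohortConfig(n_participants=2, profile=adult_profile, seed=0,
                            n_trials_per_condition=1)

    def test_cohort_determinism_and_counts(self, child_profile):
        cfg = SimCohortConfig(n_participants=2, profile=child_profile, seed=21,
                              n_trials_per_condition=3, n_localizer_trials=4)
        a, b = (list(iter_cohort(cfg, with_eeg=False)) for _ in range(2))
        assert len(a) == 2
        assert len(a[0].gaze) == 6  # 3 per condition
        np.testing.assert_array_equal(a[1].gaze[0].x, b[1].gaze[0].x)


class TestRendering:
    def test_grip_appearance_differs_only_during_reach(self):
        d = {c: gen_display_spec(condition=c) for c in ("efficient", "inefficient")}
        f_pre = d["efficient"].frame_at(1.0)
        f_reach = d["efficient"].frame_at(3.0)
        for f, same in ((f_pre, True), (f_reach, False)):
            a = render_frame(d["efficient"], f, scale=10)
            b = render_frame(d["inefficient"], f, scale=10)
            assert np.array_equal(a, b) == same

    def test_scale_must_divide(self, display):
        with pytest.raises(ValueError):
            render_frame(display, 0, scale=7)
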