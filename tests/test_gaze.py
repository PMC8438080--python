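"""AOI assignment, I-DT fixation detection, looking measures, gaze shifts."""

import numpy as np
import pytest

from observa.containers import AOI_NAMES, DisplaySpec
from observa.gaze import (AOI_PAIRS, Fixation, assign_aoi, detect_fixations,
                          gaze_shifts, looking_measures)
from tests.conftest import make_recording


def _static_display(rects, depth_history=(), duration=2.0, fps=30.0,
                    resolution=(480, 300)):
    n = int(duration * fps)
    tracks = {name: np.tile(np.asarray(r, float), (n, 1))
              for name, r in rects.items()}
    for name in AOI_NAMES:
        tracks.setdefault(name, np.tile(np.array([-10.0, -10.0, -9.0, -9.0]), (n, 1)))
    return DisplaySpec(
        resolution=resolution, fps=fps,
        events={"onset": 0.0, "movement": 0.5, "grasp": 1.0, "hammer": 1.5,
                "end": duration},
        condition="efficient", aoi_tracks=tracks,
        depth_history=list(depth_history),
    )


class TestAssignAoi:
    def test_single_containment(self):
        d = _static_display({"peg": (100, 100, 200, 200)})
        assert assign_aoi(150, 150, 0.5, d) == "peg"

    def test_outside_all_is_none(self):
        d = _static_display({"peg": (100, 100, 200, 200)})
        assert assign_aoi(50, 50, 0.5, d) is None

    def test_frontmost_by_depth_history(self):
        rects = {"hammer": (100, 100, 200, 200),
                 "dominant_hand": (150, 150, 250, 250)}
        d = _static_display(rects, depth_history=[(0.3, "dominant_hand", "hammer")])
        # overlap point after the hand moved into the hammer's space
        assert assign_aoi(175, 175, 0.5, d) == "dominant_hand"
        # before the entry event, the resting depth order applies
        d2 = _static_display(rects, depth_history=[(0.8, "hammer", "dominant_hand")])
        assert assign_aoi(175, 175, 1.0, d2) == "hammer"

    def test_time_out_of_range(self):
        d = _static_display({"peg": (0, 0, 10, 10)})
        with pytest.raises(ValueError):
            assign_aoi(5, 5, 99.0, d)


class TestDetectFixations:
    def test_stationary_gaze_one_fixation(self):
        t = np.arange(0, 0.5, 1 / 120)
        rec = make_recording(t, np.full(t.size, 100.0), np.full(t.size, 100.0))
        fx = detect_fixations(rec)
        assert len(fx) == 1
        assert fx[0].duration_s == pytest.approx(0.5, abs=0.02)

    def test_below_min_duration_discarded(self):
        t = np.arange(0, 0.080, 1 / 120)
        rec = make_recording(t, np.full(t.size, 100.0), np.full(t.size, 100.0))
        assert detect_fixations(rec) == []

    def test_scripted_three_fixation_scanpath(self):
        """Three stationary targets separated by large saccades -> exactly
        the three fixations of the script (hand enumeration)."""
        hz = 120
        spans = [(0.0, 0.3, (100, 100)), (0.3, 0.6, (400, 100)), (0.6, 1.0, (250, 250))]
        t = np.arange(0, 1.0, 1 / hz)
        x = np.empty(t.size)
        y = np.empty(t.size)
        for a, b, (px, py) in spans:
            m = (t >= a) & (t < b)
            x[m], y[m] = px, py
        fx = detect_fixations(make_recording(t, x, y))
        assert len(fx) == 3
        for f, (a, b, (px, py)) in zip(fx, spans):
            assert f.centroid_px == pytest.approx((px, py), abs=1.0)
            assert f.duration_s == pytest.approx(b - a, abs=0.02)

    def test_all_invalid_gives_empty(self):
        t = np.arange(0, 0.5, 1 / 120)
        rec = make_recording(t, np.zeros(t.size), np.zeros(t.size),
                             valid=np.zeros(t.size, bool))
        assert detect_fixations(rec) == []

    def test_aoi_label_majority(self):
        d = _static_display({"peg": (90, 90, 110, 110)})
        t = np.arange(0, 0.3, 1 / 120)
        rec = make_recording(t, np.full(t.size, 100.0), np.full(t.size, 100.0))
        fx = detect_fixations(rec, d)
        assert fx[0].aoi == "peg"


class TestLookingMeasures:
    def test_whole_trial_in_one_aoi(self):
        d = _static_display({"hammer": (90, 90, 110, 110)})
        t = np.arange(0, 1.0, 1 / 120)
        rec = make_recording(t, np.full(t.size, 100.0), np.full(t.size, 100.0))
        m = looking_measures(rec, d)
        assert m.pct_dwell["hammer"] == pytest.approx(100.0)
        assert sum(m.pct_dwell.values()) == pytest.approx(100.0)
        assert m.revisits["hammer"] == 1
        assert m.pct_fixation["hammer"] == pytest.approx(100.0)

    def test_half_half_dwell(self):
        d = _static_display({"peg": (0, 0, 50, 50), "hammer": (100, 100, 150, 150)})
        t = np.arange(0, 1.0, 1 / 120)
        n = t.size
        x = np.where(np.arange(n) < n // 2, 25.0, 125.0)
        m = looking_measures(make_recording(t, x, x), d)
        assert m.pct_dwell["peg"] == pytest.approx(50.0)
        assert m.pct_dwell["hammer"] == pytest.approx(50.0)

    def test_reentry_counts_two_revisits(self):
        d = _static_display({"peg": (0, 0, 50, 50)})
        t = np.arange(0, 0.9, 1 / 120)
        n = t.size
        x = np.full(n, 25.0)
        x[n // 3: 2 * n // 3] = 200.0  # leave the AOI, then re-enter
        m = looking_measures(make_recording(t, x, np.full(n, 25.0)), d)
        assert m.revisits["peg"] == 2

    def test_zero_tracked_time_errors(self):
        d = _static_display({"peg": (0, 0, 50, 50)})
        t = np.arange(0, 0.2, 1 / 120)
        rec = make_recording(t, np.zeros(t.size), np.zeros(t.size),
                             valid=np.zeros(t.size, bool))
        with pytest.raises(ValueError):
            looking_measures(rec, d)

    def test_dwell_partition_property(self, display, adult_profile):
        """AOI dwell plus off-AOI time partitions tracked time exactly."""
        from observa.gaze import assign_aoi_series
        from observa.synthetic import gen_gaze_recording
        rec = gen_gaze_recording(display, adult_profile, "efficient", seed=17)
        m = looking_measures(rec, display)
        labels = assign_aoi_series(rec, display)
        off = 100.0 * sum(l is None for l in labels[rec.valid]) / rec.valid.sum()
        assert sum(m.pct_dwell.values()) + off == pytest.approx(100.0, abs=1e-9)

    def test_time_shift_invariance(self):
        d = _static_display({"peg": (0, 0, 50, 50)}, duration=2.0)
        t = np.arange(0, 0.8, 1 / 120)
        x = np.full(t.size, 25.0)
        m1 = looking_measures(make_recording(t, x, x), d)
        m2 = looking_measures(make_recording(t + 0.5, x, x), d)
        assert m1.pct_dwell == m2.pct_dwell
        assert m1.revisits == m2.revisits


class TestGazeShifts:
    @staticmethod
    def _fx(seq):
        """seq: list of (start, end, aoi)."""
        return [Fixation(s, e, (0, 0), a) for s, e, a in seq]

    def test_back_and_forth_counts_two(self):
        fx = self._fx([(0.0, 0.2, "dominant_hand"), (0.25, 0.4, "hammer"),
                       (0.45, 0.6, "dominant_hand")])
        tm = gaze_shifts(fx)
        assert tm.counts[("hammer", "dominant_hand")] == 2
        assert tm.total() == 2

    def test_single_fixation_no_shifts(self):
        assert gaze_shifts(self._fx([(0, 1, "peg")])).total() == 0

    def test_gap_above_threshold_not_counted(self):
        fx = self._fx([(0.0, 0.2, "dominant_hand"), (0.35, 0.5, "hammer")])
        assert gaze_shifts(fx).total() == 0

    def test_ten_unordered_pairs(self):
        assert len(AOI_PAIRS) == 10

    def test_total_matches_direct_scan(self):
        """Pair-count total equals a direct scan of qualifying consecutive
        pairs on random fixation sequences."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            seq = []
            t = 0.0
            for _ in range(rng.integers(2, 25)):
                dur = rng.uniform(0.1, 0.3)
                aoi = rng.choice(list(AOI_NAMES) + [None])
                seq.append((t, t + dur, aoi))
                t += dur + rng.uniform(0.0, 0.2)
            fx = self._fx(seq)
            labeled = [f for f in fx if f.aoi is not None]
            expected = sum(
                1 for a, b in zip(labeled, labeled[1:])
                if a.aoi != b.aoi and b.start_s - a.end_s <= 0.100
            )
            assert gaze_shifts(fx).total() == expected
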