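"""Cluster-based suppression localizer and localizer-driven classification."""

import numpy as np
import pytest
from scipy import stats as sps

from observa.localizer import (LocalizerResult, _negative_clusters, classify_eeg,
                               extract_features, run_localizer)


def _bruteforce_clusters(t_map, threshold):
    """Independent oracle: threshold, then BFS 4-connected components."""
    supra = t_map <= -threshold
    seen = np.zeros_like(supra, bool)
    comps = []
    nf, nt = t_map.shape
    for i in range(nf):
        for j in range(nt):
            if supra[i, j] and not seen[i, j]:
                stack, cells = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    cells.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if 0 <= na < nf and 0 <= nb < nt and supra[na, nb] \
                                and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
                mask = np.zeros_like(supra)
                for c in cells:
                    mask[c] = True
                comps.append((mask, float(t_map[mask].sum())))
    return comps


class TestClusterDetection:
    def test_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t_map = rng.normal(0, 2, (12, 20))
            thr = rng.uniform(1.0, 2.5)
            labels, masses = _negative_clusters(t_map, thr)
            oracle = _bruteforce_clusters(t_map, thr)
            assert len(masses) == len(oracle)
            got = sorted(
                (frozenset(zip(*np.where(labels == k + 1))), round(m, 9))
                for k, m in enumerate(masses)
            )
            want = sorted(
                (frozenset(zip(*np.where(mask))), round(m, 9)) for mask, m in oracle
            )
            assert got == want


def _synthetic_logratio(n_epochs, channels, freqs, times, inject=None, seed=0):
    """Per-epoch log-ratio grids: N(0, 0.3) noise; ``inject`` adds a mean
    shift over (channel, freq-slice, time-slice) boxes."""
    rng = np.random.default_rng(seed)
    lr = rng.normal(0, 0.3, (n_epochs, len(channels), freqs.size, times.size))
    if inject:
        for ch, fsl, tsl, depth in inject:
            ci = channels.index(ch)
            fi = (freqs >= fsl[0]) & (freqs <= fsl[1])
            ti = (times >= tsl[0]) & (times <= tsl[1])
            lr[:, ci, np.ix_(fi, ti)[0], np.ix_(fi, ti)[1]] += depth
    return lr


class TestRunLocalizer:
    FREQS = np.arange(4.0, 25.0, 1.0)
    TIMES = np.linspace(-1.0, 2.5, 36)
    CHANNELS = ["C3", "C4", "O1"]

    def test_injected_suppression_recovered(self):
        lr = _synthetic_logratio(
            40, self.CHANNELS, self.FREQS, self.TIMES,
            inject=[("C3", (8, 13), (0.2, 1.2), -0.6),
                    ("C4", (8, 13), (0.2, 1.2), -0.6)], seed=1)
        res = run_localizer(lr, self.FREQS, self.TIMES, self.CHANNELS,
                            self.CHANNELS, search_times=(0.0, 1.8), n_perm=300,
                            seed=2)
        chans = {c.channel for c in res.clusters}
        assert {"C3", "C4"} <= chans
        for c in res.clusters:
            if c.channel in ("C3", "C4"):
                assert c.freq_range[0] >= 6.0 and c.freq_range[1] <= 15.0
                assert c.mass < 0

    def test_cluster_cells_match_oracle_t_map(self):
        """Retained cluster cell sets are components of the observed t-map."""
        lr = _synthetic_logratio(30, ["C3"], self.FREQS, self.TIMES,
                                 inject=[("C3", (8, 12), (0.3, 1.0), -0.8)], seed=3)
        res = run_localizer(lr, self.FREQS, self.TIMES, ["C3"], ["C3"],
                            search_times=(0.0, 1.8), n_perm=200, seed=4)
        fsel = (self.FREQS >= 6) & (self.FREQS <= 20)
        tsel = (self.TIMES >= 0) & (self.TIMES <= 1.8)
        sub = lr[:, 0][:, fsel][:, :, tsel]
        t_map = sps.ttest_1samp(sub, 0.0, axis=0).statistic
        thr = sps.t.ppf(1 - 0.05 / 2, sub.shape[0] - 1)
        oracle = _bruteforce_clusters(t_map, thr)
        oracle_sets = {frozenset(zip(*np.where(m))) for m, _ in oracle}
        for cl in res.clusters:
            assert frozenset(zip(*np.where(cl.cells))) in oracle_sets

    def test_null_type_one_error_rate(self):
        """Pure-noise grids: per-channel significant-cluster rate ~ alpha."""
        sig = tot = 0
        for s in range(12):
            lr = _synthetic_logratio(30, self.CHANNELS, self.FREQS, self.TIMES,
                                     seed=100 + s)
            res = run_localizer(lr, self.FREQS, self.TIMES, self.CHANNELS,
                                self.CHANNELS, search_times=(0.0, 1.8),
                                n_perm=200, seed=s)
            sig += res.n_channels_significant
            tot += len(self.CHANNELS)
        assert sig / tot < 0.17  # ~alpha with Monte-Carlo slack at 36 channels

    def test_empty_channel_set_errors(self):
        lr = _synthetic_logratio(10, ["C3"], self.FREQS, self.TIMES, seed=5)
        with pytest.raises(ValueError):
            run_localizer(lr, self.FREQS, self.TIMES, ["C3"], [])

    def test_unavailable_channel_errors(self):
        lr = _synthetic_logratio(10, ["C3"], self.FREQS, self.TIMES, seed=6)
        with pytest.raises(ValueError, match="not available"):
            run_localizer(lr, self.FREQS, self.TIMES, ["C3"], ["C9"])


class TestExtractFeatures:
    FREQS = np.arange(4.0, 25.0, 1.0)
    TIMES = np.linspace(-1.0, 2.5, 36)

    def _localizer_with_clusters(self, n):
        from observa.localizer import Cluster
        fsel = (self.FREQS >= 6) & (self.FREQS <= 20)
        tsel = (self.TIMES >= 0) & (self.TIMES <= 1.8)
        f_in, t_in = self.FREQS[fsel], self.TIMES[tsel]
        clusters = []
        for k in range(n):
            cells = np.zeros((f_in.size, t_in.size), bool)
            cells[k, : 3 + k] = True
            clusters.append(Cluster("C3", cells, -5.0, (f_in[k], f_in[k]),
                                    (t_in[0], t_in[2 + k]), 0.01))
        return LocalizerResult("p", clusters, ["C3"], (6, 20), (0, 1.8),
                               f_in, t_in, 100, 0.05)

    def test_constant_box_gives_constant_feature(self):
        loc = self._localizer_with_clusters(1)
        lr = np.full((5, 1, self.FREQS.size, self.TIMES.size), -0.4)
        feats = extract_features(lr, self.FREQS, self.TIMES, ["C3"], loc)
        np.testing.assert_allclose(feats, -0.4)
        assert feats.shape == (5, 1)

    def test_two_windows_two_dims_in_order(self):
        loc = self._localizer_with_clusters(2)
        lr = np.zeros((4, 1, self.FREQS.size, self.TIMES.size))
        # fill the first cluster's cells with -1, others 0
        fi = list(self.FREQS).index(loc.freqs[0])
        feats = extract_features(lr, self.FREQS, self.TIMES, ["C3"], loc)
        assert feats.shape == (4, 2)

    def test_empty_localizer_not_classifiable(self):
        loc = LocalizerResult("p", [], ["C3"], (6, 20), (0, 1.8),
                              self.FREQS, self.TIMES, 100, 0.05)
        with pytest.raises(ValueError, match="not classifiable"):
            extract_features(np.zeros((2, 1, self.FREQS.size, self.TIMES.size)),
                             self.FREQS, self.TIMES, ["C3"], loc)


class TestClassifyEEG:
    def test_separable_features(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(-0.8, 0.05, (8, 2)),
                            rng.normal(-0.2, 0.05, (8, 2))])
        y = np.array(["efficient"] * 8 + ["inefficient"] * 8)
        res = classify_eeg(X, y, n_reps=50, n_shuffles=99, n_reps_per_shuffle=10,
                           seed=9)
        assert res.accuracy == 100.0
        assert res.p_value == pytest.approx(1 / 100)

    def test_label_independent_features_near_chance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 3))
        y = np.array(["efficient", "inefficient"] * 10)
        res = classify_eeg(X, y, n_reps=100, n_shuffles=99, n_reps_per_shuffle=20,
                           seed=11)
        lo, hi = np.percentile(res.null_distribution, [2.5, 97.5])
        assert lo - 10 <= res.accuracy <= hi + 10
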