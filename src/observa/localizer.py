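"""Individualized EEG localizer and localizer-driven classification.

The localizer finds, per sensorimotor/occipital channel, clusters of
significant power suppression in the 6–20 Hz range between movement onset
and hammering, using data from grip-neutral localizer videos only.  Cells
are tested with a one-sample t of per-epoch log-ratios against zero,
thresholded at the two-sided alpha critical value keeping the negative
(suppression) tail, grouped by 4-connectivity in the (frequency, time)
grid, and each cluster's mass (sum of t) is compared with a sign-flip
permutation null of the per-channel minimum cluster mass.

Classification then lives on disjoint data: for each test-video trial,
the mean single-trial log-ratio over each significant cluster's cells
forms the feature vector, classified with the shared LS-SVM (C = 1)
leave-one-out + shuffle-null protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .classify import ClassificationResult, classify_trials


@dataclass
class Cluster:
    channel: str
    cells: np.ndarray  # boolean (n_freqs, n_times)
    mass: float  # sum of t over cells (< 0: suppression)
    freq_range: tuple[float, float]
    time_range: tuple[float, float]
    p_value: float


@dataclass
class LocalizerResult:
    participant_id: str
    clusters: list[Cluster]
    channel_set: list[str]
    search_freqs: tuple[float, float]
    search_times: tuple[float, float]
    freqs: np.ndarray
    times: np.ndarray
    n_perm: int
    alpha: float

    @property
    def n_channels_significant(self) -> int:
        return len({c.channel for c in self.clusters})

    def summary(self) -> dict:
        """Per-participant row: channel count, clusters per channel, freq range."""
        chans = {c.channel for c in self.clusters}
        return {
            "participant": self.participant_id,
            "n_channels": len(chans),
            "clusters_per_channel": (len(self.clusters) / len(chans)) if chans else 0.0,
            "freq_range": (
                (min(c.freq_range[0] for c in self.clusters),
                 max(c.freq_range[1] for c in self.clusters))
                if self.clusters else None
            ),
        }


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """t over the leading (epoch) axis; zero-variance cells get t = 0."""
    n = x.shape[0]
    m = x.mean(0)
    s = x.std(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    return np.where(s == 0, 0.0, t)


def _negative_clusters(t_map: np.ndarray, threshold: float):
    """Suprathreshold negative cells grouped by 4-connectivity.

    Returns (labels, masses) where labels is the int component map and
    masses[k] is the t-mass of component k+1.
    """
    supra = t_map <= -threshold
    labels, n = ndimage.label(supra, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return labels, np.zeros(0)
    masses = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
    return labels, masses


def run_localizer(
    logratio: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    channel_names: list[str],
    channel_set: list[str],
    search_freqs: tuple[float, float] = (6.0, 20.0),
    search_times: tuple[float, float] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    participant_id: str = "",
) -> LocalizerResult:
    """Cluster-based suppression localizer on per-epoch log-ratios.

    ``logratio`` is (n_epochs, n_channels, n_freqs, n_times), e.g. from
    :func:`observa.eeg.epoch_log_ratio` on localizer-video epochs.  The
    sign-flip null (valid for a one-sample test against 0) flips whole
    epochs; the per-channel null statistic is the minimum (most negative)
    cluster mass in the flipped t-map.  Clusters with
    p = (1 + #{null <= mass}) / (1 + n_perm) < alpha are retained.
    """
    logratio = np.asarray(logratio, float)
    if logratio.ndim != 4 or logratio.shape[0] < 2:
        raise ValueError("need (epochs, channels, freqs, times) with >= 2 epochs")
    if not channel_set:
        raise ValueError("empty channel_set")
    missing = [c for c in channel_set if c not in channel_names]
    if missing:
        raise ValueError(f"channels not available: {missing}")
    if search_times is None:
        search_times = (0.0, float(times[-1]))

    fsel = (freqs >= search_freqs[0]) & (freqs <= search_freqs[1])
    tsel = (times >= search_times[0]) & (times <= search_times[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty search box")
    ch_idx = [channel_names.index(c) for c in channel_set]
    box = logratio[np.ix_(np.arange(logratio.shape[0]), ch_idx,
                          np.flatnonzero(fsel), np.flatnonzero(tsel))]
    n_epochs = box.shape[0]
    t_crit = float(sps.t.ppf(1 - alpha / 2, n_epochs - 1))

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_epochs))

    clusters: list[Cluster] = []
    nf = int(fsel.sum())
    nt = int(tsel.sum())
    f_in = freqs[fsel]
    t_in = times[tsel]
    n_cells = nf * nt
    for ci, cname in enumerate(channel_set):
        sub = box[:, ci].reshape(n_epochs, n_cells)
        t_obs = _one_sample_t(sub.reshape(n_epochs, nf, nt))
        labels, masses = _negative_clusters(t_obs, t_crit)

        # sign-flip null, vectorized: sum(x^2) per cell is flip-invariant
        means = flips @ sub / n_epochs  # (n_perm, cells)
        var = (sub**2).sum(0)
        s2 = (var[None, :] - n_epochs * means**2) / (n_epochs - 1)
        s2 = np.maximum(s2, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = means / np.sqrt(s2 / n_epochs)
        t_null = np.where(s2 == 0, 0.0, t_null).reshape(n_perm, nf, nt)
        null_min = np.zeros(n_perm)
        for p_i in range(n_perm):
            _, m = _negative_clusters(t_null[p_i], t_crit)
            if m.size:
                null_min[p_i] = m.min()

        for k, mass in enumerate(masses):
            p = float((1 + np.sum(null_min <= mass)) / (1 + n_perm))
            if p < alpha:
                cells = labels == (k + 1)
                fi = np.flatnonzero(cells.any(axis=1))
                ti = np.flatnonzero(cells.any(axis=0))
                clusters.append(Cluster(
                    channel=cname, cells=cells, mass=float(mass),
                    freq_range=(float(f_in[fi[0]]), float(f_in[fi[-1]])),
                    time_range=(float(t_in[ti[0]]), float(t_in[ti[-1]])),
                    p_value=p,
                ))
    return LocalizerResult(
        participant_id=participant_id, clusters=clusters,
        channel_set=list(channel_set), search_freqs=search_freqs,
        search_times=search_times, freqs=f_in, times=t_in,
        n_perm=n_perm, alpha=alpha,
    )


def extract_features(
    test_logratio: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    channel_names: list[str],
    localizer: LocalizerResult,
) -> np.ndarray:
    """Per-trial suppression features: one mean log-ratio per localizer
    cluster, in localizer order.  Empty localizer -> participant is not
    classifiable (raises)."""
    if not localizer.clusters:
        raise ValueError("empty localizer: participant not classifiable")
    fsel = np.flatnonzero(np.isin(freqs, localizer.freqs))
    tsel = np.flatnonzero(np.isin(times, localizer.times))
    if fsel.size != localizer.freqs.size or tsel.size != localizer.times.size:
        raise ValueError("test grid does not contain the localizer grid")
    feats = np.empty((test_logratio.shape[0], len(localizer.clusters)))
    for j, cl in enumerate(localizer.clusters):
        ci = channel_names.index(cl.channel)
        sub = test_logratio[:, ci][:, fsel][:, :, tsel]
        feats[:, j] = sub[:, cl.cells].mean(axis=1)
    return feats


def classify_eeg(
    features: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 500,
    n_shuffles: int = 1000,
    n_reps_per_shuffle: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationResult:
    """LS-SVM (least-squares cost, C = 1) leave-one-out classification of
    efficient vs inefficient trials on localizer-selected features."""
    return classify_trials(features, labels, n_reps=n_reps, n_shuffles=n_shuffles,
                           n_reps_per_shuffle=n_reps_per_shuffle, C=C, seed=seed)
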