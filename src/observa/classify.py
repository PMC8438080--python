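"""Shared per-participant classification scheme.

Both the looking-video and the EEG analyses use the same protocol: a
binary least-squares SVM (LS-SVM, regularization constant C) is trained
on all but one randomly held-out trial per condition, scored on the two
held-out trials, and the percent correct averaged over repetitions
(default 500) is the participant's accuracy.  Significance comes from a
label-shuffle null: labels are permuted (default 1000 shuffles), the same
procedure re-run (with a reduced repetition count per shuffle, recorded
in the result), and p = (1 + #{null >= observed}) / (1 + n_shuffles).

The LS-SVM dual system with bias,

    [[K + I/C, 1], [1^T, 0]] [alpha; b] = [y; 0],

is solved in closed form on the precomputed Gram matrix.  Because the
Gram matrix never changes across repetitions or shuffles, the LU
factorization for each distinct held-out pair is computed once and
cached, which makes the full 500-rep x 1000-shuffle protocol tractable on
one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve


@dataclass
class ClassificationResult:
    """Observed accuracy, its shuffle null, and run metadata."""

    accuracy: float  # percent correct in [0, 100]
    n_reps: int
    null_distribution: np.ndarray  # accuracies under label shuffles (%)
    n_shuffles: int
    p_value: float
    seed: int
    n_reps_per_shuffle: int = 0

    def __post_init__(self):
        if not 0 <= self.accuracy <= 100:
            raise ValueError("accuracy must be a percentage in [0, 100]")


class _LooLSSVM:
    """Leave-one-out-per-condition LS-SVM runner on a fixed trial set."""

    def __init__(self, X: np.ndarray, C: float = 1.0):
        X = np.asarray(X, float)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.n = X.shape[0]
        self.K = X @ X.T
        self.C = C
        self._cache: dict[tuple[int, int], tuple] = {}

    def _factor(self, held: tuple[int, int]):
        fac = self._cache.get(held)
        if fac is None:
            train = np.setdiff1d(np.arange(self.n), held)
            m = train.size
            A = np.empty((m + 1, m + 1))
            A[:m, :m] = self.K[np.ix_(train, train)] + np.eye(m) / self.C
            A[:m, m] = 1.0
            A[m, :m] = 1.0
            A[m, m] = 0.0
            fac = (lu_factor(A), train)
            self._cache[held] = fac
        return fac

    def score_rep(self, y: np.ndarray, held: tuple[int, int]) -> float:
        """Train on all but ``held``, return fraction correct on ``held``."""
        (lu, train) = self._factor(held)
        rhs = np.concatenate([y[train], [0.0]])
        sol = lu_solve(lu, rhs)
        alpha, b = sol[:-1], sol[-1]
        scores = self.K[np.ix_(list(held), train)] @ alpha + b
        pred = np.where(scores >= 0, 1.0, -1.0)
        return float(np.mean(pred == y[list(held)]))


def loo_accuracy(
    runner: _LooLSSVM, y: np.ndarray, n_reps: int, rng: np.random.Generator
) -> float:
    """Mean percent correct over ``n_reps`` random held-out pairs."""
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    acc = 0.0
    for _ in range(n_reps):
        held = (int(rng.choice(pos)), int(rng.choice(neg)))
        acc += runner.score_rep(y, held)
    return 100.0 * acc / n_reps


def classify_trials(
    X: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 500,
    n_shuffles: int = 1000,
    n_reps_per_shuffle: int = 50,
    C: float = 1.0,
    seed: int = 0,
) -> ClassificationResult:
    """Full per-participant protocol: observed accuracy + shuffle null + p.

    ``labels`` may be any two distinct values; they are mapped to ±1.
    Preconditions: >= 2 trials per condition, common feature
    dimensionality, n_shuffles >= 1.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    y = np.where(labels == classes[0], 1.0, -1.0)
    if np.sum(y > 0) < 2 or np.sum(y < 0) < 2:
        raise ValueError("need >= 2 trials per condition")
    if n_reps < 1 or n_reps_per_shuffle < 1:
        raise ValueError("repetition counts must be >= 1")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")

    rng = np.random.default_rng(seed)
    runner = _LooLSSVM(X, C=C)
    observed = loo_accuracy(runner, y, n_reps, rng)

    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        null[s] = loo_accuracy(runner, ys, n_reps_per_shuffle, rng)
    p = float((1 + np.sum(null >= observed)) / (1 + n_shuffles))
    return ClassificationResult(
        accuracy=observed, n_reps=n_reps, null_distribution=null,
        n_shuffles=n_shuffles, p_value=p, seed=seed,
        n_reps_per_shuffle=n_reps_per_shuffle,
    )
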