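"""Shared statistics: Welch t, BH-FDR, Sidak post-hocs, factorial ANOVA,
permutation-seed utilities.

Conventions used throughout the package:

* All p-values are two-sided unless noted.
* Degenerate inputs with zero variance in both samples return ``p = 1``
  with ``degenerate=True`` — no variance, no evidence — rather than NaN,
  so pixel-/timepoint-wise maps stay well defined.
* Permutation p-values elsewhere use the +1 finite-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    direction: int  # sign of the effect (mean difference), 0 if none
    degenerate: bool = False


def welch_t(a, b=None, popmean: float = 0.0) -> TestResult:
    """Unequal-variance (Welch) t-test.

    Two-sample when ``b`` is given (Welch–Satterthwaite df), otherwise a
    one-sample t-test of ``a`` against ``popmean``.  Zero variance in every
    sample yields the ``p = 1`` degenerate convention.
    """
    a = np.asarray(a, float)
    if b is None:
        if a.size < 2:
            raise ValueError("one-sample t needs n >= 2")
        if np.var(a, ddof=1) == 0:
            d = np.sign(a.mean() - popmean)
            return TestResult(0.0 if d == 0 else np.inf * d, a.size - 1, 1.0 if d == 0 else 0.0,
                              int(d), degenerate=True)
        res = sps.ttest_1samp(a, popmean)
        return TestResult(float(res.statistic), float(a.size - 1), float(res.pvalue),
                          int(np.sign(a.mean() - popmean)))
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs n >= 2 per sample")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        d = np.sign(a.mean() - b.mean())
        if d == 0:
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, 0, degenerate=True)
        return TestResult(np.inf * d, float(a.size + b.size - 2), 0.0, int(d), degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite df
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue),
                      int(np.sign(a.mean() - b.mean())))


def welch_t_grid(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample Welch t over the leading axis.

    ``a`` is (n_a, ...) and ``b`` is (n_b, ...); returns (t, p) arrays of
    the trailing shape.  Cells with zero variance in both groups get
    t = 0, p = 1 when the means agree and p = 0 with t = ±inf otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    ma, mb = a.mean(0), b.mean(0)
    va, vb = a.var(0, ddof=1), b.var(0, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(degenerate & (diff == 0), 0.0, t)
    t = np.where(degenerate & (diff > 0), np.inf, t)
    t = np.where(degenerate & (diff < 0), -np.inf, t)
    df = np.where(degenerate, na + nb - 2, df)
    p = np.where(np.isfinite(t), 2 * sps.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df), 0.0)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    return t, p


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, float).ravel()
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def sidak_adjust(p: float, m: int) -> float:
    """Sidak-corrected p for ``m`` comparisons: 1 - (1-p)^m, clipped to 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def factorial_anova(table: pd.DataFrame, dv: str, factors: list[str],
                    ss_type: int = 2) -> pd.DataFrame:
    """Between-subjects fixed-effects factorial ANOVA with all interactions.

    Observations are the rows of ``table`` (by default trial-level
    measurements, so error df follows the trial count); pass participant
    means for a participant-level analysis.  Returns a frame indexed by
    effect with columns F, df_num, df_den, p.  Empty design cells raise,
    naming the cell.
    """
    import itertools

    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    levels = [table[f].unique() for f in factors]
    for cell in itertools.product(*levels):
        m = np.ones(len(table), bool)
        for f, v in zip(factors, cell):
            m &= (table[f] == v).to_numpy()
        if not m.any():
            raise ValueError(f"empty design cell: {dict(zip(factors, cell))}")
    formula = f"{dv} ~ " + " * ".join(f"C({f})" for f in factors)
    fit = ols(formula, data=table).fit()
    aov = anova_lm(fit, typ=ss_type)
    aov = aov.rename(columns={"PR(>F)": "p", "df": "df_num"})
    resid_df = float(aov.loc["Residual", "df_num"])
    out = aov.drop(index="Residual")[["F", "df_num", "p"]].copy()
    out["df_den"] = resid_df
    out.index = [
        i.replace("C(", "").replace(")", "").replace(":", " x ") for i in out.index
    ]
    return out[["F", "df_num", "df_den", "p"]]


def permutation_p(observed: float, null: np.ndarray) -> float:
    """One-sided permutation p with the +1 correction: P(null >= observed)."""
    null = np.asarray(null, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def stage_seed(global_seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a global seed."""
    ss = np.random.SeedSequence([int(global_seed), *[ord(c) for c in tag]])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(global_seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, tag))
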