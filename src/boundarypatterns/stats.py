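"""Group-level inference: t-tests, effect sizes, multiple-comparison masks.

All group tests in this package are one-sample or paired two-tailed
Student t-tests across subjects, reported with Cohen's d_z (= t / sqrt(n))
and a 95% confidence interval of the mean. Multiple comparisons across
parcels or matrix cells use Bonferroni (strict inequality) or the
Benjamini-Hochberg step-up procedure (non-strict, as originally defined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupTestResult:
    t_stat: float
    df: int
    p_two_tailed: float
    d_z: float
    ci95: tuple[float, float]
    n: int
    mean: float

    def as_dict(self) -> dict:
        return {
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_two_tailed,
            "d_z": self.d_z,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n": self.n,
            "mean": self.mean,
        }


def one_sample_t(values, mu: float = 0.0) -> GroupTestResult:
    """Two-tailed one-sample t-test of ``values`` against ``mu``."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample standard deviation")
    res = sps.ttest_1samp(x, popmean=mu)
    t = float(res.statistic)
    df = n - 1
    mean = float(x.mean())
    half = sps.t.ppf(0.975, df) * sd / math.sqrt(n)
    return GroupTestResult(
        t_stat=t,
        df=df,
        p_two_tailed=float(res.pvalue),
        d_z=cohens_dz(t, n),
        ci95=(mean - half, mean + half),
        n=n,
        mean=mean,
    )


def paired_t(a, b) -> GroupTestResult:
    """Two-tailed paired-samples t-test; identical to a one-sample test on
    the element-wise differences ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b)


def cohens_dz(t_stat: float, n: int) -> float:
    """Standardized effect size for one-sample/paired designs: t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t_stat) / math.sqrt(n)


def _check_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bonferroni_mask(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean rejection mask at the Bonferroni-corrected level alpha/m.

    Uses a strict inequality (p < alpha/m).
    """
    p = _check_pvalues(p_values)
    return p < alpha / p.size


def bh_mask(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    Sort p ascending, find the largest k with p_(k) <= k*q/m, and reject
    the k smallest p-values.
    """
    p = _check_pvalues(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= thresh)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1] + 1
        mask[order[:k]] = True
    return mask


def vectorized_one_sample_t(matrix: np.ndarray, mu: float = 0.0):
    """Row-stacked one-sample t-tests: ``matrix`` is subjects x variables.

    Returns (t, p, mean_effect) arrays over variables. Used for vertex-wise
    and cell-wise maps where constructing GroupTestResult objects would be
    wasteful.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D subjects x variables array with n >= 2")
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(
            "zero-variance variables at indices "
            f"{np.flatnonzero(sd == 0).tolist()[:10]}"
        )
    t = (mean - mu) / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    return t, p, mean
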