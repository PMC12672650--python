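"""Shared statistical primitives.

Benjamini-Hochberg adjustment, Fisher p-value combination, cosine and
Pearson similarities, and the two-sample / paired t-tests used across the
abundance, movement-reproducibility and pool-shift analyses. Everything here
delegates the distribution work to scipy; the functions only fix the exact
conventions (two-tailed, pooled variance, clamping of zero p-values) so that
every module applies them identically.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "benjamini_hochberg",
    "fisher_combine",
    "cosine_similarity",
    "pearson",
    "pairwise_pearson",
    "two_sample_t",
    "paired_t",
]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, clipped to [0, 1]).

    NaN inputs propagate to NaN outputs and do not count towards the number
    of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    scaled = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    restored = np.empty(n)
    restored[order] = np.clip(adj, 0.0, 1.0)
    out[mask] = restored
    return out


def fisher_combine(pvalues, axis: int = -1) -> np.ndarray:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2k df.

    Zero p-values are clamped to the smallest positive float so the log is
    finite (the result is then the machine-resolution minimum p).
    """
    p = np.asarray(pvalues, dtype=float)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    statistic = -2.0 * np.sum(np.log(p), axis=axis)
    k = p.shape[axis]
    return stats.chi2.sf(statistic, 2 * k)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def pearson(a, b) -> float:
    """Pearson correlation; NaN for constant inputs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_pearson(vectors) -> np.ndarray:
    """All pairwise Pearson correlations of a list of vectors (i < j order)."""
    vals = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            vals.append(pearson(vectors[i], vectors[j]))
    return np.asarray(vals)


def two_sample_t(a, b):
    """Student (pooled-variance) two-tailed t-test.

    Returns (t, p). Matches the Perseus default used for volcano analyses.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return float(t), float(p)


def paired_t(a, b):
    """Two-tailed paired t-test of b - a. Returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_rel(b, a)
    return float(t), float(p)
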