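"""Movement-reproducibility (MR) analysis of organellar map comparisons.

For each protein profiled in all replicates of two conditions, the
treatment profile minus the control profile of the cognate replicate gives
a *delta profile* (six components summing to zero). Proteins that do not
relocalize have delta profiles near baseline; relocalizers are multivariate
outliers. Per replicate, an iteratively trimmed robust Mahalanobis
statistic (location/scatter estimated from the least-moving
``static_proportion`` of proteins over ``outlier_iterations`` rounds)
yields an upper-tail chi-square p-value with 5 degrees of freedom (the
rank of the sum-zero subspace). Replicate p-values are Fisher-combined,
BH-adjusted across proteins, and -log10-transformed into the movement
score M; the median pairwise Pearson correlation of the replicate delta
profiles is the reproducibility score R. A hit requires M > 1.3 (FDR < 5%),
R > 0.8 and a movement p-value < 0.05 in at least two of three replicates.

Delta profiles are whitened per protein before the outlier test: profile
noise is strongly heteroscedastic across proteins because it scales with
profile shape, and a pooled scatter alone would mis-calibrate the
chi-square null. Under multiplicative intensity noise, the noise of a
normalized profile p is delta ~ (diag(p) - p p^T) epsilon, which gives a
closed-form per-protein covariance shape; each delta vector is whitened by
the inverse square root of that matrix (built from the protein's mean
profile over all maps), and the pooled robust scatter then absorbs the
global noise scale. Whitening depends only on the mean profile, not on the
between-condition difference, so planted shifts are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, cosine_similarity, fisher_combine, pairwise_pearson
from .io_model import AnalysisConfig, DomsError, PELLET_FRACTIONS

__all__ = [
    "prefilter",
    "delta_profiles",
    "robust_outlier_pvalues",
    "m_score",
    "r_score",
    "call_hits",
    "mr_analysis",
]


def prefilter(control_maps: Mapping[int, pd.DataFrame],
              treatment_maps: Mapping[int, pd.DataFrame],
              cfg: AnalysisConfig) -> set[str]:
    """Proteins profiled in every replicate of both conditions whose
    within-condition replicate profiles all have pairwise cosine
    correlation above ``cfg.cosine_prefilter``."""
    common = None
    for maps in (control_maps, treatment_maps):
        for df in maps.values():
            common = df.index if common is None else common.intersection(df.index)
    if common is None or len(common) == 0:
        return set()
    keep = set()
    for pid in common:
        ok = True
        for maps in (control_maps, treatment_maps):
            profiles = [maps[rep].loc[pid].to_numpy() for rep in sorted(maps)]
            for i in range(len(profiles)):
                for j in range(i + 1, len(profiles)):
                    if cosine_similarity(profiles[i], profiles[j]) <= cfg.cosine_prefilter:
                        ok = False
        if ok:
            keep.add(pid)
    return keep


def delta_profiles(control_maps: Mapping[int, pd.DataFrame],
                   treatment_maps: Mapping[int, pd.DataFrame],
                   proteins: Sequence[str] | None = None) -> dict[int, pd.DataFrame]:
    """Replicate-paired delta profiles (treatment - control, replicate i
    with replicate i). Components of each delta sum to zero."""
    if sorted(control_maps) != sorted(treatment_maps):
        raise DomsError("unpaired replicates between conditions")
    deltas = {}
    for rep in sorted(control_maps):
        ctrl = control_maps[rep]
        trt = treatment_maps[rep]
        idx = ctrl.index.intersection(trt.index)
        if proteins is not None:
            idx = idx.intersection(pd.Index(proteins))
        idx = idx.sort_values()
        deltas[rep] = pd.DataFrame(
            trt.loc[idx].to_numpy() - ctrl.loc[idx].to_numpy(),
            index=idx, columns=list(PELLET_FRACTIONS),
        )
    return deltas


def mean_profiles(control_maps: Mapping[int, pd.DataFrame],
                  treatment_maps: Mapping[int, pd.DataFrame],
                  proteins: pd.Index) -> pd.DataFrame:
    """Per-protein mean normalized profile over every map of both
    conditions (the anchor for noise whitening)."""
    stack = np.stack([
        maps[r].loc[proteins].to_numpy()
        for maps in (control_maps, treatment_maps) for r in sorted(maps)
    ])
    return pd.DataFrame(stack.mean(axis=0), index=proteins,
                        columns=list(PELLET_FRACTIONS))


def _sum_zero_basis() -> np.ndarray:
    """Orthonormal basis (6 x 5) of the sum-zero subspace (Helmert)."""
    basis = np.zeros((6, 5))
    for k in range(1, 6):
        v = np.zeros(6)
        v[:k] = 1.0
        v[k] = -k
        basis[:, k - 1] = v / np.linalg.norm(v)
    return basis


_HELMERT = _sum_zero_basis()


def _trimming_consistency(proportion: float, dim: int) -> float:
    """MCD-style consistency factor for a covariance estimated from the
    ``proportion`` of points with smallest Mahalanobis distance."""
    q = stats.chi2.ppf(proportion, dim)
    return proportion / stats.chi2.cdf(q, dim + 2)


def _whiten_deltas(X: np.ndarray, profiles: np.ndarray,
                   eig_floor: float = 1e-4) -> np.ndarray:
    """Whiten delta vectors by the per-protein noise covariance shape.

    For multiplicative intensity noise, a normalized profile p has noise
    delta ~ A eps with A = diag(p) - p p^T, so the delta covariance is
    proportional to A^2 (restricted to the sum-zero subspace). Each delta
    is mapped to the Helmert basis and multiplied by (B^T A^2 B)^(-1/2);
    near-zero eigenvalues (fractions with no signal) are floored at 1e-4
    of the largest to keep censored components from exploding.
    """
    Z = np.empty((X.shape[0], 5))
    for i in range(X.shape[0]):
        p = profiles[i]
        A = np.diag(p) - np.outer(p, p)
        M = _HELMERT.T @ (A @ A) @ _HELMERT
        w, U = np.linalg.eigh(M)
        w = np.maximum(w, w.max() * eig_floor)
        Z[i] = (U @ np.diag(w ** -0.5) @ U.T) @ (_HELMERT.T @ X[i])
    return Z


def robust_outlier_pvalues(deltas: pd.DataFrame, cfg: AnalysisConfig,
                           profiles: pd.DataFrame | None = None) -> pd.Series:
    """Robust multivariate outlier p-values for one replicate's deltas.

    ``profiles`` (per-protein mean normalized profiles, see
    :func:`mean_profiles`) activates per-protein noise whitening; without
    it the raw deltas are used in the sum-zero subspace. Location and
    scatter of the (whitened) delta vectors are estimated from the
    least-moving ``cfg.static_proportion`` of proteins, iteratively
    re-selected for ``cfg.outlier_iterations`` rounds, with a chi-square
    consistency correction for the trimming. Squared robust Mahalanobis
    distances in the rank-5 sum-zero subspace are referred to the
    chi-square distribution with 5 df.
    """
    if len(deltas) < 20:
        raise DomsError("outlier test needs at least 20 proteins per replicate")
    X = deltas.to_numpy(dtype=float)
    if profiles is not None:
        Y = _whiten_deltas(X, profiles.loc[deltas.index].to_numpy(dtype=float))
    else:
        Y = X @ _HELMERT  # n x 5
    n, d = Y.shape
    h = max(int(np.ceil(cfg.static_proportion * n)), d + 2)
    factor = _trimming_consistency(cfg.static_proportion, d)
    subset = np.arange(n)
    trimmed = False
    d2 = None
    for _ in range(cfg.outlier_iterations):
        mu = Y[subset].mean(axis=0)
        S = np.cov(Y[subset], rowvar=False)
        if trimmed:
            S = S * factor
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            warnings.warn("singular scatter matrix; ridge-regularized")
            S = S + np.eye(d) * (np.trace(S) / d * 1e-6 + 1e-12)
            Sinv = np.linalg.inv(S)
        centered = Y - mu
        d2 = np.einsum("ij,jk,ik->i", centered, Sinv, centered)
        subset = np.argsort(d2, kind="mergesort")[:h]
        trimmed = True
    p = stats.chi2.sf(d2, d)
    return pd.Series(p, index=deltas.index)


def m_score(p_per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combine replicate movement p-values, BH-adjust across the
    protein universe, and -log10-transform into the M score.

    An adjusted p of 0.01 gives M = 2 (significant movement at an
    estimated FDR of 1%); the 5% FDR cut-off corresponds to M = 1.3.
    """
    pmat = p_per_replicate.to_numpy(dtype=float)
    if np.any(pmat <= 0):
        warnings.warn("zero movement p-values clamped to machine minimum")
    joint = fisher_combine(pmat, axis=1)
    adjusted = benjamini_hochberg(joint)
    with np.errstate(divide="ignore"):
        m = -np.log10(np.clip(adjusted, np.finfo(float).tiny, None))
    return pd.DataFrame(
        {"joint_p": joint, "adjusted_p": adjusted, "M": m},
        index=p_per_replicate.index,
    )


def r_score(deltas: Sequence[np.ndarray]) -> float:
    """Median of the pairwise Pearson correlations of replicate delta
    profiles. NaN (protein cannot be a hit) for constant deltas."""
    corr = pairwise_pearson([np.asarray(d, dtype=float) for d in deltas])
    if np.any(np.isnan(corr)):
        return np.nan
    return float(np.median(corr))


def call_hits(result: pd.DataFrame, cfg: AnalysisConfig) -> pd.Series:
    """Hit flag: M > m_cutoff, R > r_cutoff, and movement p < 0.05 in at
    least ``min_significant_replicates`` replicates."""
    pcols = [c for c in result.columns if c.startswith("p_rep")]
    n_sig = (result[pcols] < cfg.per_replicate_p).sum(axis=1)
    hits = (
        (result["M"] > cfg.m_cutoff)
        & (result["R"] > cfg.r_cutoff)
        & (n_sig >= cfg.min_significant_replicates)
    )
    return hits.fillna(False)


@dataclass
class MRResult:
    """Full per-protein MR table plus the eligible universe size."""

    table: pd.DataFrame
    n_tested: int

    @property
    def hits(self) -> pd.Index:
        return self.table.index[self.table["hit"]]


def mr_analysis(control_maps: Mapping[int, pd.DataFrame],
                treatment_maps: Mapping[int, pd.DataFrame],
                cfg: AnalysisConfig | None = None) -> MRResult:
    """End-to-end MR comparison of two mapped conditions.

    Returns a table with per-replicate movement p-values, the Fisher joint
    p, the BH-adjusted p, M, R and the hit flag.
    """
    cfg = cfg or AnalysisConfig()
    eligible = prefilter(control_maps, treatment_maps, cfg)
    if len(eligible) < 20:
        raise DomsError("fewer than 20 proteins pass the MR prefilter")
    deltas = delta_profiles(control_maps, treatment_maps, sorted(eligible))
    reps = sorted(deltas)
    index = deltas[reps[0]].index
    anchors = mean_profiles(control_maps, treatment_maps, index)
    pmat = pd.DataFrame(
        {f"p_rep{rep}": robust_outlier_pvalues(deltas[rep], cfg, profiles=anchors)
         for rep in reps},
        index=index,
    )
    scores = m_score(pmat)
    r = pd.Series(
        [r_score([deltas[rep].loc[pid].to_numpy() for rep in reps]) for pid in index],
        index=index, name="R",
    )
    table = pd.concat([pmat, scores, r], axis=1)
    table["hit"] = call_hits(table, cfg)
    return MRResult(table=table, n_tested=len(index))
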