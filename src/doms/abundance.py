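"""Full-proteome statistics: imputation, permutation-FDR volcano analysis,
cross-treatment concordance and proteomic-ruler copy numbers.

The volcano analysis follows the SAM/Perseus convention: per protein a
Student two-tailed t-test on log2 intensities plus a variance-shrunken
statistic t' = (mean difference) / (SE + S0); the significance cut-off on
|t'| is the smallest threshold at which the median number of permuted
exceedances divided by the observed number stays below the requested FDR.

The proteomic ruler anchors total cellular protein mass to DNA mass via
histone MS signal (histones are stoichiometric with DNA), converting
intensities into copies per cell and molar concentrations without spike-in
standards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import two_sample_t
from .io_model import DomsError

__all__ = [
    "impute_missing",
    "volcano_test",
    "shared_unique_hits",
    "estimate_ploidy",
    "genome_mass",
    "interpolate_concentration",
    "proteomic_ruler",
]

AVOGADRO = 6.02214076e23
BASE_PAIR_G_PER_MOL = 650.0  # average molar mass of one DNA base pair


def impute_missing(log2_matrix: pd.DataFrame, downshift: float = 1.8,
                   width: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Impute missing log2 intensities from a down-shifted normal.

    Per column, missing entries are drawn from
    Normal(mean - downshift * sd, (width * sd)^2) computed from the
    observed values of that column: left-censored low-abundance proteins
    are replaced by plausible values near the detection limit. Observed
    entries are untouched.
    """
    rng = np.random.default_rng(seed)
    out = log2_matrix.copy()
    for col in out.columns:
        values = out[col]
        observed = values.dropna()
        if len(observed) < 2:
            raise DomsError(f"column {col!r} has fewer than 2 observed values")
        n_missing = values.isna().sum()
        if n_missing:
            mu = observed.mean() - downshift * observed.std(ddof=1)
            sd = width * observed.std(ddof=1)
            out.loc[values.isna(), col] = rng.normal(mu, sd, size=n_missing)
    return out


@dataclass
class VolcanoResult:
    """Per-protein volcano table plus the |t'| threshold that realizes the
    requested permutation FDR (inf when no threshold qualifies)."""

    table: pd.DataFrame
    threshold: float
    s0: float
    fdr: float

    @property
    def hits(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _modified_t(group_a: np.ndarray, group_b: np.ndarray, s0: float):
    """Per-row mean difference, pooled SE, Student p and SAM statistic."""
    na, nb = group_a.shape[1], group_b.shape[1]
    mean_a = group_a.mean(axis=1)
    mean_b = group_b.mean(axis=1)
    var_a = group_a.var(axis=1, ddof=1)
    var_b = group_b.var(axis=1, ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = mean_b - mean_a
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p)
    tprime = diff / (se + s0)
    return diff, p, tprime


def volcano_test(group_a: pd.DataFrame, group_b: pd.DataFrame,
                 s0: float = 0.1, fdr: float = 0.05,
                 n_permutations: int = 250, seed: int = 0) -> VolcanoResult:
    """Two-group volcano analysis with permutation-based FDR cut-off.

    ``group_a``/``group_b`` are proteins x replicates log2 matrices
    (imputation already applied, equal replicate counts). At n = 3 + 3 all
    20 balanced relabelings are enumerated; for larger designs
    ``n_permutations`` random balanced relabelings are drawn.
    """
    if list(group_a.index) != list(group_b.index):
        raise DomsError("groups must share the same protein universe")
    if group_a.shape[1] != group_b.shape[1]:
        raise DomsError("equal replicate counts required")
    if s0 <= 0:
        raise DomsError("s0 must be positive")
    A = group_a.to_numpy(dtype=float)
    B = group_b.to_numpy(dtype=float)
    na = A.shape[1]
    diff, p, tprime = _modified_t(A, B, s0)

    combined = np.hstack([A, B])
    total = combined.shape[1]
    all_splits = list(combinations(range(total), na))
    if len(all_splits) <= n_permutations:
        splits = all_splits
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(all_splits), size=n_permutations, replace=False)
        splits = [all_splits[i] for i in chosen]

    abs_obs = np.abs(tprime)
    order = np.argsort(abs_obs)[::-1]
    sorted_obs = abs_obs[order]
    perm_abs = []
    for split in splits:
        rest = [j for j in range(total) if j not in split]
        _, _, tp = _modified_t(combined[:, list(split)], combined[:, rest], s0)
        perm_abs.append(np.sort(np.abs(tp)))
    perm_abs = np.vstack(perm_abs)  # P x n, each row ascending

    threshold = math.inf
    n = len(sorted_obs)
    for k in range(n):  # candidate cut at the (k+1) largest observed |t'|
        c = sorted_obs[k]
        observed_count = k + 1
        false_counts = np.array([row.size - np.searchsorted(row, c, side="left")
                                 for row in perm_abs])
        est_fdr = np.median(false_counts) / observed_count
        if est_fdr <= fdr:
            threshold = c
        else:
            break
    significant = abs_obs >= threshold if math.isfinite(threshold) else np.zeros(n, bool)
    table = pd.DataFrame(
        {"log2_fc": diff, "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
         "modified_t": tprime, "significant": significant},
        index=group_a.index,
    )
    return VolcanoResult(table=table, threshold=threshold, s0=s0, fdr=fdr)


def shared_unique_hits(volcano_a: VolcanoResult, volcano_b: VolcanoResult) -> dict:
    """Concordance of two volcano analyses on the same protein universe.

    Returns shared hits (significant in both), unique hits (in exactly
    one), and for each group the fraction with the same fold-change sign
    in both treatments.
    """
    ta, tb = volcano_a.table, volcano_b.table
    if list(ta.index) != list(tb.index):
        raise DomsError("volcano results must share the same protein universe")
    hits_a = set(volcano_a.hits)
    hits_b = set(volcano_b.hits)
    shared = sorted(hits_a & hits_b)
    unique = sorted(hits_a ^ hits_b)
    same_sign = np.sign(ta["log2_fc"]) == np.sign(tb["log2_fc"])

    def concordance(ids):
        if not ids:
            return np.nan
        return float(same_sign.loc[ids].mean())

    return {
        "shared": shared,
        "unique": unique,
        "shared_concordance": concordance(shared),
        "unique_concordance": concordance(unique),
    }


def estimate_ploidy(dna_pg_per_cell: float, genome_pg: float) -> float:
    """Genome equivalents per cell from DNA mass per cell, one decimal."""
    if dna_pg_per_cell <= 0 or genome_pg <= 0:
        raise DomsError("DNA masses must be positive")
    return round(dna_pg_per_cell / genome_pg, 1)


def genome_mass(base_pairs: float) -> float:
    """Mass of one genome in pg, at 650 g/mol per base pair."""
    return base_pairs * BASE_PAIR_G_PER_MOL / AVOGADRO * 1e12


def interpolate_concentration(ploidy: float, haploid_gl: float = 94.0,
                              diploid_gl: float = 79.0) -> int:
    """Total protein concentration (g/l) linearly interpolated in ploidy
    between the haploid and diploid reference values; the integer report
    truncates (1.7 genomes/cell -> 83 g/l)."""
    if not 1.0 <= ploidy <= 2.0:
        warnings.warn("ploidy outside [1, 2]; extrapolating")
    value = haploid_gl + (ploidy - 1.0) * (diploid_gl - haploid_gl)
    return int(value)


@dataclass
class CopyNumberEstimate:
    """Per-protein copies/cell and molar concentrations plus cell totals."""

    table: pd.DataFrame
    total_protein_pg: float
    cell_volume_l: float
    ploidy: float | None = None


def proteomic_ruler(intensities: pd.Series, molecular_weights: pd.Series,
                    histone_ids: Sequence[str], dna_pg: float,
                    conc_gl: float, ploidy: float | None = None) -> CopyNumberEstimate:
    """Proteomic-ruler copy numbers anchored to cellular DNA mass.

    Histones package DNA stoichiometrically, so total protein mass per
    cell is M = dna_pg * (sum of all intensities) / (sum of histone
    intensities). Copies are proportional to intensity / molecular weight,
    scaled so the summed protein mass matches M; cell volume follows from
    the total protein concentration, and molar concentrations from copies
    and volume. Copies are invariant to global intensity rescaling.
    """
    intensities = intensities.astype(float)
    mw = molecular_weights.astype(float).reindex(intensities.index)
    if mw.isna().any():
        raise DomsError("molecular weight missing for some proteins")
    histones = [h for h in histone_ids if h in intensities.index]
    histone_signal = intensities.loc[histones].sum()
    if not histones or histone_signal <= 0:
        raise DomsError("no measured histone signal to anchor the ruler")
    total_signal = intensities.sum()
    total_pg = dna_pg * total_signal / histone_signal
    total_g = total_pg * 1e-12
    scale = total_g * AVOGADRO / total_signal
    copies = intensities / mw * scale
    volume_l = total_g / conc_gl
    concentration = copies / (AVOGADRO * volume_l)
    table = pd.DataFrame({
        "copies_per_cell": copies,
        "concentration_mol_l": concentration,
    })
    return CopyNumberEstimate(table=table, total_protein_pg=float(total_pg),
                              cell_volume_l=float(volume_l), ploidy=ploidy)
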