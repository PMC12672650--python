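"""Cytosolic-pool estimation, organelle-level shift tests and the
ER-redistribution candidate cascade.

A *pool profile* extends the six-pellet profile with the cytosol fraction:
normalized intensities in each of the seven fractions are weighted by the
relative protein yield of that fraction (BCA assay) and renormalized, so
the seven entries partition a protein's recovery and the seventh entry is
its cytosolic pool. Pool shifts between control and the two ER stressors
(DTT, tunicamycin) are tested with paired t-tests, Fisher-combined across
treatments and BH-adjusted across proteins.

Organelle-level shifts compare condition-average marker profiles per
replicate: the smallest of the six datapoint-wise paired-t p-values times
six gives the shift Q-value, and the mean replicate-pair L1 distance gives
the shift magnitude (negligible/small/medium/large at 0.1/0.2/0.3).

ER-redistribution candidates are proteins whose profile correlation with
the average ER marker profile rises under DTT (positive DeltaCorrelER),
exceeds 0.75 under DTT, that are MR hits, and that reside in post-ER
secretory compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, fisher_combine, paired_t, pearson
from .io_model import (
    AnalysisConfig,
    CYTOSOL_FRACTION,
    DomsError,
    PELLET_FRACTIONS,
    average_condition_profiles,
    normalize_profile,
)

__all__ = [
    "pool_profile",
    "pool_profiles",
    "pool_shift_test",
    "organelle_shift_test",
    "er_shift_candidates",
    "classify_lumenal_er",
    "classify_post_er",
]

POOL_FRACTIONS: tuple[str, ...] = PELLET_FRACTIONS + (CYTOSOL_FRACTION,)

#: Post-ER secretory compartments (localization categories downstream of
#: the ER in the secretory pathway).
POST_ER_COMPARTMENTS = ("ERGIC", "Golgi", "plasma membrane", "cell wall",
                        "vacuole", "endosomes")

MAGNITUDE_BINS = ((0.1, "negligible"), (0.2, "small"), (0.3, "medium"))


def pool_profile(intensities_7, yields: Mapping[str, float]) -> np.ndarray:
    """Yield-weighted seven-point recovery profile.

    Intensities (six pellets + cytosol fraction, missing treated as 0) are
    normalized, weighted by the per-fraction relative protein yields, and
    renormalized; the seventh entry is the cytosolic pool.
    """
    values = np.nan_to_num(np.asarray(intensities_7, dtype=float), nan=0.0)
    if values.shape != (7,):
        raise DomsError("pool profile needs 7 fraction intensities")
    w = np.array([yields[f] for f in POOL_FRACTIONS], dtype=float)
    if np.any(w[values > 0] <= 0):
        raise DomsError("measured fraction with non-positive yield")
    weighted = values / values.sum() * w if values.sum() > 0 else values
    total = weighted.sum()
    if total <= 0:
        raise DomsError("all-zero weighted pool profile")
    return weighted / total


def pool_profiles(table, condition: str, replicate: int,
                  yields: Mapping[str, float]) -> pd.DataFrame:
    """Seven-point pool profiles for every protein of one replicate map
    with any signal; the ``cytosol`` column is the cytosolic pool."""
    cols = [(condition, replicate, f) for f in POOL_FRACTIONS]
    raw = table.intensity[cols].copy()
    raw.columns = list(POOL_FRACTIONS)
    values = np.nan_to_num(raw.to_numpy(dtype=float), nan=0.0)
    keep = values.sum(axis=1) > 0
    values = values[keep]
    w = np.array([yields[f] for f in POOL_FRACTIONS], dtype=float)
    weighted = values / values.sum(axis=1, keepdims=True) * w
    weighted = weighted / weighted.sum(axis=1, keepdims=True)
    return pd.DataFrame(weighted, index=raw.index[keep], columns=list(POOL_FRACTIONS))


def _cytosolic_pools(pools_by_condition, condition) -> pd.DataFrame:
    """Replicates x proteins frame of cytosolic pools for one condition."""
    reps = sorted(pools_by_condition[condition])
    return pd.DataFrame({rep: pools_by_condition[condition][rep][CYTOSOL_FRACTION]
                         for rep in reps})


def pool_shift_test(pools_by_condition: Mapping[str, Mapping[int, pd.DataFrame]],
                    cfg: AnalysisConfig | None = None,
                    control: str = "control", dtt: str = "DTT",
                    tm: str = "Tm") -> pd.DataFrame:
    """Cytosolic-pool shift analysis combining both ER stressors.

    Per protein with cytosolic pools measured in all replicates of the
    control and at least one treatment: a paired two-tailed t-test per
    treatment, Fisher combination of the two p-values, BH adjustment
    across proteins. Hits require adjusted FDR below ``cfg.pool_fdr``,
    p < ``pool_p_dtt`` (DTT) and p < ``pool_p_tm`` (tunicamycin), an
    absolute pool change above ``pool_change_cutoff`` percentage points
    under both treatments, and the same direction of change (positive =
    toward the cytosol).
    """
    cfg = cfg or AnalysisConfig()
    ctrl = _cytosolic_pools(pools_by_condition, control)
    treat = {name: _cytosolic_pools(pools_by_condition, cond)
             for name, cond in (("dtt", dtt), ("tm", tm)) if cond in pools_by_condition}
    if not treat:
        raise DomsError("no treatment condition supplied")

    eligible = ctrl.dropna().index
    any_complete = None
    for df in treat.values():
        complete = df.dropna().index
        any_complete = complete if any_complete is None else any_complete.union(complete)
    eligible = eligible.intersection(any_complete).sort_values()

    rows = []
    for pid in eligible:
        row = {"protein_id": pid}
        for name, df in treat.items():
            paired = pd.concat([ctrl.loc[pid], df.loc[pid]], axis=1, keys=["c", "t"]).dropna()
            if len(paired) < 2:
                row[f"p_{name}"] = np.nan
                row[f"change_{name}"] = np.nan
                continue
            delta = paired["t"] - paired["c"]
            if np.allclose(delta, 0):
                t, p = 0.0, 1.0
            else:
                t, p = paired_t(paired["c"], paired["t"])
            row[f"p_{name}"] = p
            row[f"change_{name}"] = float(delta.mean() * 100.0)  # percentage points
        rows.append(row)
    result = pd.DataFrame(rows).set_index("protein_id")

    pcols = [f"p_{name}" for name in treat]
    result["combined_p"] = fisher_combine(result[pcols].to_numpy(), axis=1) \
        if len(pcols) > 1 else result[pcols[0]]
    result["adjusted_p"] = benjamini_hochberg(result["combined_p"])

    hit = result["adjusted_p"] < cfg.pool_fdr
    if "dtt" in treat:
        hit &= (result["p_dtt"] < cfg.pool_p_dtt) & \
               (result["change_dtt"].abs() > cfg.pool_change_cutoff)
    if "tm" in treat:
        hit &= (result["p_tm"] < cfg.pool_p_tm) & \
               (result["change_tm"].abs() > cfg.pool_change_cutoff)
    if len(treat) == 2:
        hit &= np.sign(result["change_dtt"]) == np.sign(result["change_tm"])
    result["hit"] = hit.fillna(False)
    return result


def _magnitude(distance: float) -> str:
    for cut, label in MAGNITUDE_BINS:
        if distance < cut:
            return label
    return "large"


def organelle_shift_test(control_maps: Mapping[int, pd.DataFrame],
                         treatment_maps: Mapping[int, pd.DataFrame],
                         markers: pd.Series,
                         cfg: AnalysisConfig | None = None,
                         exclude: Sequence[str] = ("lipid droplets", "peroxisomes"),
                         min_markers: int = 5) -> pd.DataFrame:
    """Organelle-level shift test on average marker profiles.

    Per organelle and replicate, the average normalized profile of its
    marker proteins is computed for both conditions. Q is the smallest of
    the six datapoint-wise paired-t p-values multiplied by six (capped at
    1); the shift magnitude is the mean over cognate replicate pairs of
    the L1 profile distance. An organelle is flagged as shifted when
    Q < ``cfg.organelle_shift_fdr`` and the distance exceeds
    ``cfg.organelle_shift_min_distance``.
    """
    cfg = cfg or AnalysisConfig()
    reps = sorted(control_maps)
    if reps != sorted(treatment_maps):
        raise DomsError("unpaired replicates between conditions")
    rows = []
    for organelle in sorted(markers.unique()):
        if organelle in exclude:
            continue
        ids = markers.index[markers == organelle]
        avail = [pid for pid in ids
                 if all(pid in control_maps[r].index for r in reps)
                 and all(pid in treatment_maps[r].index for r in reps)]
        if len(avail) < max(min_markers, 2):
            continue
        ctrl_avg = np.stack([
            normalize_profile(control_maps[r].loc[avail].mean(axis=0)) for r in reps])
        trt_avg = np.stack([
            normalize_profile(treatment_maps[r].loc[avail].mean(axis=0)) for r in reps])
        pvals = []
        for j in range(6):
            diffs = trt_avg[:, j] - ctrl_avg[:, j]
            if np.std(diffs, ddof=1) < 1e-15:
                # degenerate fraction: identical across replicates
                pvals.append(1.0 if np.allclose(diffs, 0.0) else 0.0)
            else:
                pvals.append(paired_t(ctrl_avg[:, j], trt_avg[:, j])[1])
        q = min(1.0, 6.0 * float(np.min(pvals)))
        distance = float(np.mean(np.abs(trt_avg - ctrl_avg).sum(axis=1)))
        rows.append({
            "organelle": organelle,
            "n_markers": len(avail),
            "Q": q,
            "distance": distance,
            "magnitude": _magnitude(distance),
            "shifted": bool(q < cfg.organelle_shift_fdr
                            and distance > cfg.organelle_shift_min_distance),
        })
    return pd.DataFrame(rows).set_index("organelle")


def classify_lumenal_er(annotations: pd.DataFrame) -> set[str]:
    """ER-category proteins with a signal peptide and no transmembrane
    domains: the soluble residents of the ER lumen."""
    sel = (
        (annotations["category"] == "ER")
        & annotations["has_signal_peptide"]
        & (annotations["n_tm_domains"] == 0)
    )
    return set(annotations.index[sel])


def classify_post_er(annotations: pd.DataFrame,
                     localizations: pd.Series | None = None) -> set[str]:
    """Post-ER secretory pathway proteins.

    Requires an ER-targeting signal peptide and/or at least one
    transmembrane domain, no mitochondrial transit peptide, and a
    localization in a post-ER secretory compartment (ERGIC, Golgi, plasma
    membrane, cell wall, vacuole or endosomes). ``localizations``
    overrides the annotation category where provided (e.g. with SVM
    predictions).
    """
    loc = annotations["category"].copy()
    if localizations is not None:
        loc.update(localizations.reindex(loc.index).dropna())
    sel = (
        (annotations["has_signal_peptide"] | (annotations["n_tm_domains"] >= 1))
        & ~annotations["has_transit_peptide"]
        & loc.isin(POST_ER_COMPARTMENTS)
    )
    return set(annotations.index[sel])


@dataclass
class ErShiftReport:
    """Candidate table plus the near-miss report (proteins passing every
    filter except the DTT ER-correlation cut-off by at most 0.05)."""

    table: pd.DataFrame
    near_misses: pd.DataFrame

    @property
    def candidates(self) -> pd.Index:
        return self.table.index[self.table["candidate"]]


def er_shift_candidates(control_maps: Mapping[int, pd.DataFrame],
                        treatment_maps: Mapping[int, pd.DataFrame],
                        er_markers: Sequence[str],
                        mr_hits: Sequence[str],
                        post_er: Sequence[str],
                        cfg: AnalysisConfig | None = None) -> ErShiftReport:
    """Proteins redistributing towards the ER under DTT stress.

    Condition-average profiles are correlated with the average ER marker
    profile in control and DTT maps. Candidates must be MR hits, have a
    positive DeltaCorrelER, correlate with the DTT ER profile above
    ``cfg.er_correl_cutoff``, and have a post-ER secretory localization.
    Constant profiles (undefined correlation) are excluded and flagged.
    """
    cfg = cfg or AnalysisConfig()
    ctrl_avg = average_condition_profiles(control_maps)
    trt_avg = average_condition_profiles(treatment_maps)
    common = ctrl_avg.index.intersection(trt_avg.index)
    er_ids = [pid for pid in er_markers if pid in common]
    if not er_ids:
        raise DomsError("no ER markers present in both conditions")
    er_ctrl = normalize_profile(ctrl_avg.loc[er_ids].mean(axis=0))
    er_trt = normalize_profile(trt_avg.loc[er_ids].mean(axis=0))

    mr_hits = set(mr_hits)
    post_er = set(post_er)
    rows = []
    for pid in common:
        c_ctrl = pearson(ctrl_avg.loc[pid].to_numpy(), er_ctrl)
        c_trt = pearson(trt_avg.loc[pid].to_numpy(), er_trt)
        undefined = np.isnan(c_ctrl) or np.isnan(c_trt)
        delta = c_trt - c_ctrl
        rows.append({
            "protein_id": pid,
            "correl_con_er": c_ctrl,
            "correl_dtt_er": c_trt,
            "delta_correl_er": delta,
            "mr_hit": pid in mr_hits,
            "post_er": pid in post_er,
            "undefined_correlation": undefined,
        })
    table = pd.DataFrame(rows).set_index("protein_id")
    table["candidate"] = (
        table["mr_hit"]
        & table["post_er"]
        & ~table["undefined_correlation"]
        & (table["delta_correl_er"] > 0)
        & (table["correl_dtt_er"] > cfg.er_correl_cutoff)
    )
    near = table[
        table["mr_hit"] & table["post_er"] & ~table["candidate"]
        & ~table["undefined_correlation"]
        & (table["delta_correl_er"] > 0)
        & (table["correl_dtt_er"] > cfg.er_correl_cutoff - 0.05)
    ]
    return ErShiftReport(table=table, near_misses=near)
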