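"""Synthetic truth-recovery experiments.

Each function simulates a fractionation experiment with known ground
truth, runs the corresponding analysis stage end to end, and scores the
result against the planted truth. These are the validation experiments
behind `doms report` and the reproduction script; they are deterministic
given a seed.

Sensitivity and false-discovery rates are computed over the proteins that
enter the respective test (i.e. that survive the data-quality filters):
they measure the statistic, not upstream detectability of low-abundance
proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import impute_missing, shared_unique_hits, volcano_test
from .classify import benchmark_f1, initial_markers, iterate_marker_training
from .io_model import (
    AnalysisConfig,
    FULL_PROTEOME,
    concatenate_replicates,
    condition_maps,
)
from .mr import mr_analysis
from .pools_shifts import classify_post_er, er_shift_candidates
from .synthetic_data import SimulationConfig, make_annotations, simulate_experiment

__all__ = [
    "null_calibration",
    "mr_recovery",
    "er_recovery",
    "classification_benchmark",
    "volcano_benchmark",
]


def null_calibration(seed: int = 0, n_proteins: int = 2000,
                     cfg: AnalysisConfig | None = None) -> dict:
    """MR analysis of a no-shift simulation.

    Returns the KS distance of the pooled replicate-wise movement
    p-values from U(0, 1), the number of proteins tested and the number
    of (false) hits.
    """
    cfg = cfg or AnalysisConfig()
    sim = SimulationConfig(n_proteins=n_proteins, n_relocalizers=0, seed=seed)
    table, _ = simulate_experiment(sim, conditions=("control", "DTT"))
    ctrl = condition_maps(table, "control", cfg)
    trt = condition_maps(table, "DTT", cfg)
    result = mr_analysis(ctrl, trt, cfg)
    pcols = [c for c in result.table.columns if c.startswith("p_rep")]
    pooled = result.table[pcols].to_numpy().ravel()
    ks = stats.kstest(pooled, "uniform").statistic
    return {
        "ks_distance": float(ks),
        "n_tested": result.n_tested,
        "n_hits": int(result.table["hit"].sum()),
        "pvalues": pooled,
        "table": result.table,
    }


def mr_recovery(seed: int = 0, n_proteins: int = 2000, n_relocalizers: int = 100,
                alpha_shift_sizes: tuple[float, ...] = (0.5, 0.7, 1.0),
                cfg: AnalysisConfig | None = None) -> dict:
    """Sensitivity and empirical FDR of the MR analysis on planted
    relocalizers (mixing shift alpha >= 0.5 at default 10% CV noise)."""
    cfg = cfg or AnalysisConfig()
    sim = SimulationConfig(n_proteins=n_proteins, n_relocalizers=n_relocalizers,
                           alpha_shift_sizes=alpha_shift_sizes, seed=seed)
    table, truth = simulate_experiment(sim, conditions=("control", "DTT"))
    ctrl = condition_maps(table, "control", cfg)
    trt = condition_maps(table, "DTT", cfg)
    result = mr_analysis(ctrl, trt, cfg)
    tested = result.table.index
    planted = truth.index[truth["alpha_treatment"] > 0].intersection(tested)
    hits = set(result.hits)
    tp = len(planted.intersection(hits))
    fp = len(hits - set(planted))
    return {
        "sensitivity": tp / len(planted) if len(planted) else np.nan,
        "empirical_fdr": fp / len(hits) if hits else 0.0,
        "n_tested": result.n_tested,
        "n_planted_tested": len(planted),
        "n_hits": len(hits),
    }


def er_recovery(seed: int = 0, n_proteins: int = 1500, n_movers: int = 60,
                alpha_shift_sizes: tuple[float, ...] = (0.7, 0.9),
                cfg: AnalysisConfig | None = None) -> dict:
    """Recovery of planted post-ER -> ER relocalizers by the
    ER-redistribution candidate cascade (alpha shift >= 0.7)."""
    cfg = cfg or AnalysisConfig()
    sim = SimulationConfig(n_proteins=n_proteins, n_relocalizers=n_movers,
                           alpha_shift_sizes=alpha_shift_sizes, seed=seed)
    table, truth = simulate_experiment(
        sim, conditions=("control", "DTT"),
        relocalizer_pool=("Golgi", "plasma membrane", "vacuole"),
        relocalizer_target="ER",
    )
    annotations = make_annotations(truth, seed=seed)
    ctrl = condition_maps(table, "control", cfg)
    trt = condition_maps(table, "DTT", cfg)
    result = mr_analysis(ctrl, trt, cfg)
    er_markers = truth.index[truth["compartment"] == "ER"]
    post_er = classify_post_er(annotations)
    report = er_shift_candidates(ctrl, trt, er_markers, result.hits, post_er, cfg)
    tested = report.table.index
    planted = truth.index[(truth["alpha_treatment"] > 0)
                          & (truth["compartment_b"] == "ER")].intersection(tested)
    recovered = planted.intersection(report.candidates)
    return {
        "recovery": len(recovered) / len(planted) if len(planted) else np.nan,
        "n_planted_tested": len(planted),
        "n_candidates": len(report.candidates),
        "report": report,
    }


def classification_benchmark(seed: int = 0, n_proteins: int = 1200,
                             cfg: AnalysisConfig | None = None) -> dict:
    """Iterative marker training plus 80:20 F1 benchmark on a simulated
    steady-state map (three replicate maps, default noise)."""
    cfg = cfg or AnalysisConfig()
    sim = SimulationConfig(n_proteins=n_proteins, seed=seed)
    table, truth = simulate_experiment(sim, conditions=("control",))
    maps = condition_maps(table, "control", cfg)
    features = concatenate_replicates(maps)
    reference = truth["compartment"]
    abundance = truth["copies_per_cell"].astype(float)
    seeds = initial_markers(reference, abundance, features.index)
    training = iterate_marker_training(seeds, features, reference, cfg, seed=seed)
    f1 = benchmark_f1(features, training.markers, cfg, seed=seed)
    return {
        "final_recall": training.final_recall,
        "n_markers": len(training.markers),
        "n_rounds": len(training.audit),
        "f1_per_class": f1,
        "macro_f1": float(f1.dropna().mean()),
        "audit": training.audit,
    }


def _full_proteome_log2(table, condition: str) -> pd.DataFrame:
    reps = table.replicates(condition)
    cols = {f"{condition}_{r}": table.fraction_intensity(condition, r, FULL_PROTEOME)
            for r in reps}
    return np.log2(pd.DataFrame(cols))


def volcano_benchmark(seed: int = 0, n_proteins: int = 1000,
                      n_changers: int = 150,
                      cfg: AnalysisConfig | None = None) -> dict:
    """Volcano analyses of simulated full proteomes for both stressors.

    Abundance changers are planted identically in both treatments, so
    shared hits should change in the same direction; also runs a pure-null
    volcano (control resplit against itself is not possible with n = 3, so
    a zero-changer simulation is used) to check the FDR contract.
    """
    cfg = cfg or AnalysisConfig()
    sim = SimulationConfig(n_proteins=n_proteins, n_abundance_changers=n_changers,
                           seed=seed)
    table, truth = simulate_experiment(sim, conditions=("control", "DTT", "Tm"))
    ctrl = _full_proteome_log2(table, "control")
    measured = ctrl.notna().sum(axis=1) >= 3
    results = {}
    for cond in ("DTT", "Tm"):
        trt = _full_proteome_log2(table, cond)
        keep = measured | (trt.notna().sum(axis=1) >= 3)
        both = impute_missing(pd.concat([ctrl[keep], trt[keep]], axis=1),
                              cfg.impute_downshift, cfg.impute_width, seed=seed)
        a = both[ctrl.columns]
        b = both[trt.columns]
        results[cond] = volcano_test(a, b, s0=cfg.volcano_s0, fdr=cfg.volcano_fdr,
                                     seed=seed)
    concordance = shared_unique_hits(results["DTT"], results["Tm"])

    null_sim = SimulationConfig(n_proteins=n_proteins, n_abundance_changers=0,
                                seed=seed + 1)
    null_table, _ = simulate_experiment(null_sim, conditions=("control", "DTT"))
    nc = _full_proteome_log2(null_table, "control")
    nt = _full_proteome_log2(null_table, "DTT")
    keep = (nc.notna().sum(axis=1) >= 3) | (nt.notna().sum(axis=1) >= 3)
    both = impute_missing(pd.concat([nc[keep], nt[keep]], axis=1),
                          cfg.impute_downshift, cfg.impute_width, seed=seed)
    null_result = volcano_test(both[nc.columns], both[nt.columns],
                               s0=cfg.volcano_s0, fdr=cfg.volcano_fdr, seed=seed)
    planted = set(truth.index[truth["abundance_log2fc"] != 0])
    dtt_hits = set(results["DTT"].hits)
    return {
        "volcanoes": results,
        "shared_concordance": concordance["shared_concordance"],
        "n_shared": len(concordance["shared"]),
        "dtt_sensitivity": len(dtt_hits & planted) / len(planted) if planted else np.nan,
        "null_hits": len(null_result.hits),
        "null_universe": len(null_result.table),
    }
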