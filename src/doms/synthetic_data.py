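"""Synthetic fractionation experiments with known ground truth.

The simulator emulates a differential-centrifugation profiling experiment:
each compartment has a characteristic six-pellet abundance template plus a
cytosol-leakage share; each protein draws its expected profile from its
compartment (or a mixture of two compartments for planted relocalizers),
is scaled by a log-uniform abundance, perturbed by log-normal multiplicative
replicate noise per fraction, and left-censored below a detection threshold.
MS/MS counts are Poisson with a rate proportional to log-intensity above
threshold. The ground truth (compartments, planted mixing shifts, abundance
changes, copies per cell) is returned alongside the experiment table so
every downstream stage can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_model import (
    ALL_FRACTIONS,
    CYTOSOL_FRACTION,
    FULL_PROTEOME,
    PELLET_FRACTIONS,
    DomsError,
    ExperimentTable,
    default_layout,
    sample_name,
    write_protein_groups,
)

__all__ = [
    "CompartmentTemplate",
    "SimulationConfig",
    "default_templates",
    "default_yields",
    "simulate_experiment",
    "make_annotations",
    "write_fixture",
]


@dataclass(frozen=True)
class CompartmentTemplate:
    """Fractionation behavior of one compartment.

    ``pellet_profile`` is the normalized six-point shape of the organellar
    pellets; ``cytosol_leak`` is the share of the compartment's protein that
    ends up in the 78k supernatant (≈1 for cytosolic proteins, small for
    well-sealed organelles, sizeable for mechanically damaged nuclei).
    """

    name: str
    pellet_profile: tuple[float, ...]
    cytosol_leak: float

    def __post_init__(self):
        profile = np.asarray(self.pellet_profile, dtype=float)
        if profile.shape != (6,) or profile.min() < 0:
            raise DomsError("pellet_profile must be 6 non-negative values")
        if abs(profile.sum() - 1.0) > 1e-9:
            raise DomsError(f"template {self.name}: pellet profile must sum to 1")
        if not 0.0 <= self.cytosol_leak <= 1.0:
            raise DomsError("cytosol_leak must be in [0, 1]")

    @property
    def profile(self) -> np.ndarray:
        return np.asarray(self.pellet_profile, dtype=float)


def default_templates() -> list[CompartmentTemplate]:
    """Twelve compartment templates with pairwise L1 distance >= 0.4.

    Heavy compartments (nucleus, plasma membrane sheets, mitochondria)
    pellet early; Golgi and small vesicles later; ribosomes peak in the 78k
    pellet; cytosolic proteins mostly stay in the supernatant.
    """
    return [
        CompartmentTemplate("nucleus", (0.70, 0.15, 0.07, 0.04, 0.02, 0.02), 0.30),
        CompartmentTemplate("plasma membrane", (0.40, 0.35, 0.13, 0.06, 0.04, 0.02), 0.05),
        CompartmentTemplate("mitochondria", (0.10, 0.45, 0.30, 0.08, 0.04, 0.03), 0.02),
        CompartmentTemplate("vacuole", (0.25, 0.10, 0.40, 0.13, 0.07, 0.05), 0.10),
        CompartmentTemplate("ER", (0.05, 0.15, 0.30, 0.35, 0.10, 0.05), 0.05),
        CompartmentTemplate("nuclear envelope", (0.35, 0.10, 0.10, 0.30, 0.10, 0.05), 0.10),
        CompartmentTemplate("Golgi", (0.03, 0.07, 0.12, 0.30, 0.35, 0.13), 0.08),
        CompartmentTemplate("peroxisomes", (0.05, 0.25, 0.10, 0.10, 0.35, 0.15), 0.05),
        CompartmentTemplate("lipid droplets", (0.15, 0.05, 0.05, 0.15, 0.40, 0.20), 0.05),
        CompartmentTemplate("proteasome", (0.05, 0.05, 0.08, 0.12, 0.25, 0.45), 0.40),
        CompartmentTemplate("ribosome", (0.02, 0.03, 0.05, 0.08, 0.17, 0.65), 0.20),
        CompartmentTemplate("cytosol", (0.20, 0.12, 0.10, 0.12, 0.20, 0.26), 0.90),
    ]


#: Relative frequency of each compartment among simulated proteins,
#: approximating the composition of a mapped yeast proteome.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "nucleus": 0.18,
    "cytosol": 0.24,
    "mitochondria": 0.15,
    "ER": 0.08,
    "vacuole": 0.06,
    "plasma membrane": 0.06,
    "Golgi": 0.04,
    "ribosome": 0.08,
    "nuclear envelope": 0.03,
    "proteasome": 0.04,
    "lipid droplets": 0.015,
    "peroxisomes": 0.025,
}


def default_yields() -> dict[str, float]:
    """Relative protein recovery per fraction (BCA-style), summing to 0.9:
    most protein mass is in the first pellet and the cytosol fraction, the
    remainder is lost during washes."""
    return {"1k": 0.20, "3k": 0.07, "6k": 0.05, "12k": 0.04,
            "24k": 0.04, "78k": 0.05, CYTOSOL_FRACTION: 0.45}


@dataclass
class SimulationConfig:
    """Study conditions of a simulated experiment.

    ``replicate_cv`` is the multiplicative (log-normal) noise per fraction;
    abundances are drawn log-uniformly over four decades of intensity;
    intensities below ``detection_threshold`` are censored to missing.
    Relocalizers mix toward a second compartment by ``alpha`` in treated
    conditions; abundance changers scale their full-proteome level.
    """

    n_proteins: int = 2000
    n_relocalizers: int = 0
    alpha_shift_sizes: tuple[float, ...] = (0.5, 0.7, 1.0)
    n_abundance_changers: int = 0
    abundance_log2fc_sizes: tuple[float, ...] = (1.0, 2.0, 3.0)
    replicate_cv: float = 0.10
    detection_threshold: float = 1e5
    abundance_range: tuple[float, float] = (1e6, 1e10)
    intensity_per_copy: float = 1e4
    ms_count_rate: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.replicate_cv < 0 or self.detection_threshold < 0 or self.ms_count_rate < 0:
            raise DomsError("rates must be non-negative")


def _assign_compartments(cfg: SimulationConfig, templates, rng) -> np.ndarray:
    names = [t.name for t in templates]
    weights = np.array([DEFAULT_CLASS_WEIGHTS.get(n, 0.01) for n in names])
    weights = weights / weights.sum()
    # deterministic proportional assignment, then shuffle: guarantees every
    # class is populated at realistic frequency for any n_proteins
    counts = np.floor(weights * cfg.n_proteins).astype(int)
    while counts.sum() < cfg.n_proteins:
        counts[np.argmax(weights * cfg.n_proteins - counts)] += 1
    labels = np.repeat(np.arange(len(names)), counts)
    rng.shuffle(labels)
    return labels


def simulate_experiment(
    cfg: SimulationConfig,
    templates: Sequence[CompartmentTemplate] | None = None,
    conditions: Sequence[str] = ("control", "DTT", "Tm"),
    n_replicates: int = 3,
    relocalizer_pool: Sequence[str] | None = None,
    relocalizer_target: str | None = None,
) -> tuple[ExperimentTable, pd.DataFrame]:
    """Simulate a multi-condition fractionation experiment.

    Returns the experiment table and a truth frame with columns
    ``compartment, compartment_b, alpha_control, alpha_treatment,
    abundance_log2fc, copies_per_cell``. Planted relocalizers mix from
    compartment A toward compartment B by ``alpha_treatment`` in every
    non-control condition. ``relocalizer_pool`` restricts which source
    compartments may host relocalizers and ``relocalizer_target`` pins the
    destination (e.g. "ER" for retention scenarios); by default both are
    unrestricted. Identical seeds give identical output, and per-protein
    random streams are keyed by protein index so output is stable under
    reordering.
    """
    templates = list(templates) if templates is not None else default_templates()
    if cfg.n_relocalizers > 0 and len(templates) < 2:
        raise DomsError("relocalizers need at least 2 compartment templates")
    by_name = {t.name: t for t in templates}
    master = np.random.default_rng([int(cfg.seed), 0xD0])
    labels = _assign_compartments(cfg, templates, master)
    names = [t.name for t in templates]

    n = cfg.n_proteins
    lo, hi = cfg.abundance_range
    abundance = 10 ** master.uniform(np.log10(lo), np.log10(hi), size=n)

    compartment_b = np.array([""] * n, dtype=object)
    alpha_treatment = np.zeros(n)
    if cfg.n_relocalizers > 0:
        if relocalizer_pool is not None:
            eligible = np.flatnonzero(np.isin([names[l] for l in labels], list(relocalizer_pool)))
        else:
            eligible = np.arange(n)
        if eligible.size < cfg.n_relocalizers:
            raise DomsError("not enough eligible proteins to plant relocalizers")
        chosen = master.choice(eligible, size=cfg.n_relocalizers, replace=False)
        for k, idx in enumerate(chosen):
            source = names[labels[idx]]
            if relocalizer_target is not None:
                target = relocalizer_target
                if target == source:
                    others = [nm for nm in names if nm != source]
                    target = others[master.integers(len(others))]
            else:
                others = [nm for nm in names if nm != source]
                target = others[master.integers(len(others))]
            compartment_b[idx] = target
            alpha_treatment[idx] = cfg.alpha_shift_sizes[k % len(cfg.alpha_shift_sizes)]

    abundance_log2fc = np.zeros(n)
    if cfg.n_abundance_changers > 0:
        changers = master.choice(n, size=cfg.n_abundance_changers, replace=False)
        for k, idx in enumerate(changers):
            size = cfg.abundance_log2fc_sizes[k % len(cfg.abundance_log2fc_sizes)]
            abundance_log2fc[idx] = size if k % 2 == 0 else -size

    sigma = np.sqrt(np.log1p(cfg.replicate_cv ** 2))
    protein_ids = [f"P{i:05d}" for i in range(n)]
    layout_keys = [(c, r, f) for c in conditions
                   for r in range(1, n_replicates + 1) for f in ALL_FRACTIONS]
    columns = pd.MultiIndex.from_tuples(layout_keys,
                                        names=["condition", "replicate", "fraction"])
    intens = np.full((n, len(layout_keys)), np.nan)
    counts = np.zeros((n, len(layout_keys)))

    col_index = {key: j for j, key in enumerate(layout_keys)}
    for i in range(n):
        rng = np.random.default_rng([int(cfg.seed), 1, i])
        template_a = by_name[names[labels[i]]]
        template_b = by_name[compartment_b[i]] if compartment_b[i] else None
        for cond in conditions:
            treated = cond != "control"
            alpha = alpha_treatment[i] if (treated and template_b is not None) else 0.0
            level = abundance[i] * (2.0 ** abundance_log2fc[i] if treated else 1.0)
            if template_b is not None:
                pellet_shape = (1 - alpha) * template_a.profile + alpha * template_b.profile
                leak = (1 - alpha) * template_a.cytosol_leak + alpha * template_b.cytosol_leak
            else:
                pellet_shape = template_a.profile
                leak = template_a.cytosol_leak
            expected = np.concatenate([
                level * (1.0 - leak) * pellet_shape,  # six pellets
                [level * leak],                       # cytosol fraction
                [level],                              # full proteome
            ])
            count_ref = max(cfg.detection_threshold, 1.0)
            for rep in range(1, n_replicates + 1):
                noisy = expected * np.exp(rng.normal(0.0, sigma, size=8))
                observed = np.where(noisy >= cfg.detection_threshold, noisy, np.nan)
                with np.errstate(divide="ignore", invalid="ignore"):
                    log_excess = np.log10(noisy / count_ref)
                rate = cfg.ms_count_rate * np.clip(np.nan_to_num(log_excess), 0.0, 1e3)
                ms = rng.poisson(rate).astype(float)
                ms = np.where(np.isnan(observed), 0.0, ms)
                for k, frac in enumerate(ALL_FRACTIONS):
                    j = col_index[(cond, rep, frac)]
                    intens[i, j] = observed[k]
                    counts[i, j] = ms[k]

    table = ExperimentTable(
        intensity=pd.DataFrame(intens, index=protein_ids, columns=columns),
        ms_count=pd.DataFrame(counts, index=protein_ids, columns=columns),
        gene_name=pd.Series([f"GEN{i}" for i in range(n)], index=protein_ids),
    )
    truth = pd.DataFrame(
        {
            "compartment": [names[l] for l in labels],
            "compartment_b": compartment_b,
            "alpha_control": np.zeros(n),
            "alpha_treatment": alpha_treatment,
            "abundance_log2fc": abundance_log2fc,
            "copies_per_cell": np.round(abundance / cfg.intensity_per_copy).astype(int),
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return table, truth


def make_annotations(truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Reference-annotation table consistent with the simulated truth.

    Category mirrors the planted compartment. Topology flags follow the
    biology of each class: secretory-pathway membranes carry transmembrane
    domains, lumenal secretory proteins a signal peptide, mitochondrial
    proteins a transit peptide; soluble cytosolic/nuclear proteins carry
    neither.
    """
    rng = np.random.default_rng([int(seed), 0xA])
    membrane_classes = {"ER", "Golgi", "plasma membrane", "vacuole",
                        "nuclear envelope", "peroxisomes", "lipid droplets"}
    secretory = {"ER", "Golgi", "plasma membrane", "vacuole"}
    rows = []
    for pid, row in truth.iterrows():
        comp = row["compartment"]
        is_membrane = comp in membrane_classes and rng.random() < 0.7
        has_sp = comp in secretory and (not is_membrane or rng.random() < 0.5)
        has_tp = comp == "mitochondria" and rng.random() < 0.8
        rows.append({
            "protein_id": pid,
            "category": comp,
            "n_tm_domains": int(rng.integers(1, 8)) if is_membrane else 0,
            "has_signal_peptide": bool(has_sp),
            "has_transit_peptide": bool(has_tp),
            "molecular_weight": float(np.round(10 ** rng.normal(4.65, 0.25), 1)),
        })
    return pd.DataFrame(rows).set_index("protein_id")


def write_fixture(table: ExperimentTable, truth: pd.DataFrame, out_dir,
                  yields: Mapping[str, float] | None = None,
                  annotations: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write a complete on-disk fixture consumable by the io layer.

    Emits protein_groups.tsv (MaxQuant dialect), truth.tsv, yields.tsv,
    annotations.tsv and layout.yaml; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": out / "protein_groups.tsv",
        "truth": out / "truth.tsv",
        "yields": out / "yields.tsv",
        "annotations": out / "annotations.tsv",
        "layout": out / "layout.yaml",
    }
    write_protein_groups(table, paths["protein_groups"])
    truth.to_csv(paths["truth"], sep="\t")
    yields = dict(yields) if yields is not None else default_yields()
    pd.DataFrame({"fraction": list(yields), "yield": list(yields.values())}).to_csv(
        paths["yields"], sep="\t", index=False)
    if annotations is None:
        annotations = make_annotations(truth)
    annotations.to_csv(paths["annotations"], sep="\t")
    layout = {sample_name(*key): list(key) for key in table.samples}
    paths["layout"].write_text(yaml.safe_dump(layout, sort_keys=False))
    return paths


def read_layout(path) -> dict[str, tuple[str, int, str]]:
    """Read a layout.yaml written by :func:`write_fixture`."""
    raw = yaml.safe_load(Path(path).read_text())
    return {name: (str(c), int(r), str(f)) for name, (c, r, f) in raw.items()}
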