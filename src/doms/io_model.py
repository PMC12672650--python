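"""Data model, readers/writers, profile construction and quality filtering.

The pipeline consumes MaxQuant-style protein-groups tables: one row per
protein group, with per-sample ``LFQ intensity <sample>`` and
``MS/MS count <sample>`` columns. A *sample* is one subcellular fraction of
one replicate map of one condition. The six pellet fractions
(1k, 3k, 6k, 12k, 24k and 78k x 1000 g) carry the organellar map; the 78k
supernatant ("cytosol") and the unfractionated lysate ("full_proteome") feed
the cytosolic-pool and abundance analyses.

A protein's six-point *fraction profile* is its pellet intensities
normalized to sum 1. Profiles are comparable between proteins irrespective
of abundance and are the substrate for PCA, compartment classification and
all shift statistics.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

PELLET_FRACTIONS: tuple[str, ...] = ("1k", "3k", "6k", "12k", "24k", "78k")
CYTOSOL_FRACTION = "cytosol"
FULL_PROTEOME = "full_proteome"
ALL_FRACTIONS: tuple[str, ...] = PELLET_FRACTIONS + (CYTOSOL_FRACTION, FULL_PROTEOME)

#: Closed vocabulary of reference-annotation localization categories:
#: 18 curated localizations plus "ambiguous" and "unknown".
REFERENCE_CATEGORIES: tuple[str, ...] = (
    "actin-associated",
    "cell wall",
    "COPI",
    "COPII",
    "cytosol",
    "ER",
    "endosomes",
    "ERGIC",
    "Golgi",
    "lipid droplets",
    "mitochondria",
    "nucleus",
    "nuclear envelope",
    "peroxisomes",
    "plasma membrane",
    "proteasome",
    "ribosome",
    "vacuole",
    "ambiguous",
    "unknown",
)

#: The twelve compartment classes resolved by the SVMs.
SVM_CLASSES: tuple[str, ...] = (
    "nucleus",
    "cytosol",
    "mitochondria",
    "vacuole",
    "plasma membrane",
    "Golgi",
    "ER",
    "ribosome",
    "nuclear envelope",
    "proteasome",
    "lipid droplets",
    "peroxisomes",
)

REVERSE_COL = "Reverse"
SITE_COL = "Only identified by site"
CONTAMINANT_COL = "Potential contaminant"
PROTEIN_ID_COL = "Protein IDs"
GENE_NAME_COL = "Gene names"


class DomsError(Exception):
    """Base class for pipeline errors."""


class UndefinedProfileError(DomsError):
    """Raised when a profile cannot be normalized (all-zero input)."""


def sample_name(condition: str, replicate: int, fraction: str) -> str:
    """Serialize a sample key as ``<condition>_<replicate>_<fraction>``."""
    return f"{condition}_{replicate}_{fraction}"


def default_layout(conditions: Sequence[str], n_replicates: int,
                   fractions: Sequence[str] = ALL_FRACTIONS) -> dict[str, tuple[str, int, str]]:
    """Sample-name -> (condition, replicate, fraction) mapping for the
    canonical serialized naming scheme."""
    layout = {}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for frac in fractions:
                layout[sample_name(cond, rep, frac)] = (cond, rep, frac)
    return layout


@dataclass
class AnalysisConfig:
    """Scalar parameters of the whole analysis.

    Defaults are the published operating point of the pipeline: profiles
    need >=3 consecutive measured pellet fractions and a mean MS/MS count
    >=2; the MR analysis prefilters at cosine > 0.9, runs the robust
    outlier test with a 75% static proportion over 11 iterations and calls
    hits at M > 1.3, R > 0.8 with movement p < 0.05 in >=2 of 3 replicates;
    pool-shift hits need FDR < 5%, p < 0.05 (DTT) and p < 0.1 (tunicamycin)
    and a >10 percentage-point change of the same sign under both
    treatments; ER-redistribution candidates need an ER-profile correlation
    > 0.75 under DTT. SVM hyperparameters are searched over C in [1, 30]
    and gamma in [1, 50] for 5 iterations with 5-fold cross-validation, and
    assignment confidence tiers are cut at scores of 0.95/0.8/0.65/0.4.
    """

    min_consecutive_fractions: int = 3
    min_avg_ms_count: float = 2.0
    cosine_prefilter: float = 0.9
    static_proportion: float = 0.75
    outlier_iterations: int = 11
    m_cutoff: float = 1.3
    r_cutoff: float = 0.8
    per_replicate_p: float = 0.05
    min_significant_replicates: int = 2
    pool_change_cutoff: float = 10.0  # percentage points
    pool_p_dtt: float = 0.05
    pool_p_tm: float = 0.1
    pool_fdr: float = 0.05
    er_correl_cutoff: float = 0.75
    dual_localization_pool_cutoff: float = 0.30
    svm_c_range: tuple[float, float] = (1.0, 30.0)
    svm_gamma_range: tuple[float, float] = (1.0, 50.0)
    svm_search_iterations: int = 5
    svm_min_markers: int = 5
    confidence_tiers: tuple[float, float, float, float] = (0.95, 0.8, 0.65, 0.4)
    impute_downshift: float = 1.8
    impute_width: float = 0.3
    volcano_s0: float = 0.1
    volcano_fdr: float = 0.05
    organelle_shift_fdr: float = 0.05
    organelle_shift_min_distance: float = 0.1
    marker_training_max_rounds: int = 20
    rng_seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DomsError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(getattr(cls, f.name, None), tuple):
                data[f.name] = tuple(data[f.name])
        return cls(**data)


@dataclass
class ExperimentTable:
    """Protein x sample intensities and MS/MS counts.

    Both frames are indexed by protein_id and share MultiIndex columns
    ``(condition, replicate, fraction)``. Missing measurements are NaN,
    distinct from literal zero.
    """

    intensity: pd.DataFrame
    ms_count: pd.DataFrame
    gene_name: pd.Series = field(default=None)

    def __post_init__(self):
        if not self.intensity.index.is_unique:
            dupes = self.intensity.index[self.intensity.index.duplicated()]
            raise DomsError(f"duplicate protein ids: {sorted(set(dupes))[:5]}")
        if self.gene_name is None:
            self.gene_name = pd.Series("", index=self.intensity.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def samples(self) -> list[tuple[str, int, str]]:
        return list(self.intensity.columns)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(c for c, _, _ in self.intensity.columns))

    def replicates(self, condition: str) -> list[int]:
        return sorted({r for c, r, _ in self.intensity.columns if c == condition})

    def pellet_intensities(self, condition: str, replicate: int) -> pd.DataFrame:
        """Proteins x 6 pellet fractions for one replicate map."""
        cols = [(condition, replicate, f) for f in PELLET_FRACTIONS]
        df = self.intensity[cols].copy()
        df.columns = list(PELLET_FRACTIONS)
        return df

    def pellet_ms_counts(self, condition: str, replicate: int) -> pd.DataFrame:
        cols = [(condition, replicate, f) for f in PELLET_FRACTIONS]
        df = self.ms_count[cols].copy()
        df.columns = list(PELLET_FRACTIONS)
        return df

    def fraction_intensity(self, condition: str, replicate: int, fraction: str) -> pd.Series:
        return self.intensity[(condition, replicate, fraction)]


def read_protein_groups(path, layout: Mapping[str, tuple[str, int, str]]) -> ExperimentTable:
    """Read a MaxQuant-dialect protein-groups TSV.

    ``layout`` maps sample names (as they appear after ``LFQ intensity``)
    to ``(condition, replicate, fraction)`` keys. Rows flagged as reverse
    hits, only-identified-by-site or potential contaminants are dropped.
    Empty cells become NaN; a literal 0 stays 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={PROTEIN_ID_COL: str}, low_memory=False)
    if PROTEIN_ID_COL not in df.columns:
        raise DomsError(f"missing required column {PROTEIN_ID_COL!r} in {path}")
    missing = []
    for name in layout:
        for prefix in ("LFQ intensity", "MS/MS count"):
            col = f"{prefix} {name}"
            if col not in df.columns:
                missing.append(col)
    if missing:
        raise DomsError(f"missing declared sample columns: {missing}")

    for flag in (REVERSE_COL, SITE_COL, CONTAMINANT_COL):
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]

    if df[PROTEIN_ID_COL].duplicated().any():
        dupes = df.loc[df[PROTEIN_ID_COL].duplicated(), PROTEIN_ID_COL]
        raise DomsError(f"duplicate protein ids: {sorted(set(dupes))[:5]}")
    df = df.set_index(PROTEIN_ID_COL)

    keys = [layout[name] for name in layout]
    columns = pd.MultiIndex.from_tuples(keys, names=["condition", "replicate", "fraction"])
    intensity = pd.DataFrame(
        {key: pd.to_numeric(df[f"LFQ intensity {name}"], errors="coerce")
         for name, key in zip(layout, keys)},
        index=df.index,
    )
    ms_count = pd.DataFrame(
        {key: pd.to_numeric(df[f"MS/MS count {name}"], errors="coerce")
         for name, key in zip(layout, keys)},
        index=df.index,
    )
    intensity.columns = columns
    ms_count.columns = columns
    gene = df[GENE_NAME_COL].fillna("") if GENE_NAME_COL in df.columns else None
    return ExperimentTable(intensity=intensity, ms_count=ms_count, gene_name=gene)


def write_protein_groups(table: ExperimentTable, path) -> None:
    """Write an ExperimentTable back to a MaxQuant-dialect TSV (lossless
    round trip through :func:`read_protein_groups`)."""
    columns = {GENE_NAME_COL: table.gene_name}
    for key in table.samples:
        name = sample_name(*key)
        columns[f"LFQ intensity {name}"] = table.intensity[key]
        columns[f"MS/MS count {name}"] = table.ms_count[key]
    for flag in (REVERSE_COL, SITE_COL, CONTAMINANT_COL):
        columns[flag] = pd.Series("", index=table.protein_ids)
    out = pd.DataFrame(columns, index=table.protein_ids)
    out.index.name = PROTEIN_ID_COL
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_reference_annotation(path) -> pd.DataFrame:
    """Reference annotation TSV: protein_id, category, n_tm_domains,
    has_signal_peptide, has_transit_peptide, molecular_weight."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "category", "n_tm_domains", "has_signal_peptide",
                "has_transit_peptide", "molecular_weight"}
    missing = required - set(df.columns)
    if missing:
        raise DomsError(f"annotation table missing columns: {sorted(missing)}")
    bad = set(df["category"]) - set(REFERENCE_CATEGORIES)
    if bad:
        raise DomsError(f"unknown annotation categories: {sorted(bad)}")
    df["has_signal_peptide"] = df["has_signal_peptide"].astype(bool)
    df["has_transit_peptide"] = df["has_transit_peptide"].astype(bool)
    return df.set_index("protein_id")


def read_yields(path) -> dict[str, float]:
    """Per-fraction relative protein yields (BCA), fractions summing to <=1."""
    df = pd.read_csv(path, sep="\t")
    if not {"fraction", "yield"} <= set(df.columns):
        raise DomsError("yields table needs 'fraction' and 'yield' columns")
    yields = dict(zip(df["fraction"], df["yield"].astype(float)))
    if any(v < 0 for v in yields.values()):
        raise DomsError("negative yield")
    if sum(yields.values()) > 1.0 + 1e-9:
        raise DomsError("yields sum to more than 1")
    return yields


# ---------------------------------------------------------------------------
# Profile construction

def _consecutive_run(present: np.ndarray) -> int:
    """Longest run of True values (evaluated in fixed 1k -> 78k order)."""
    best = run = 0
    for flag in present:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def filter_map_profiles(table: ExperimentTable, condition: str, replicate: int,
                        cfg: AnalysisConfig) -> set[str]:
    """Quality filter for one replicate map.

    Keeps proteins with >= ``min_consecutive_fractions`` consecutive
    measured pellet intensities (0 counts as not measured) AND a mean MS/MS
    count across the six pellet fractions (missing counted as 0) of at
    least ``min_avg_ms_count``.
    """
    intens = table.pellet_intensities(condition, replicate)
    counts = table.pellet_ms_counts(condition, replicate)
    present = intens.to_numpy() > 0  # NaN and 0 both fail
    runs = np.apply_along_axis(_consecutive_run, 1, present) if len(intens) else np.array([])
    mean_counts = np.nan_to_num(counts.to_numpy(), nan=0.0).mean(axis=1) if len(counts) else np.array([])
    keep = (runs >= cfg.min_consecutive_fractions) & (mean_counts >= cfg.min_avg_ms_count)
    return set(intens.index[keep])


def normalize_profile(intensities) -> np.ndarray:
    """0-to-1 normalize six pellet intensities (missing treated as 0).

    Each value is divided by the total summed intensity across the six
    fractions, so the profile reflects subcellular distribution only.
    """
    values = np.nan_to_num(np.asarray(intensities, dtype=float), nan=0.0)
    if values.min() < 0:
        raise DomsError("negative intensity")
    total = values.sum()
    if total <= 0:
        raise UndefinedProfileError("cannot normalize an all-zero profile")
    return values / total


def normalize_profiles(intensities: pd.DataFrame) -> pd.DataFrame:
    """Row-wise profile normalization of a proteins x fractions frame.

    All-zero rows are dropped (they carry no distribution information).
    """
    values = np.nan_to_num(intensities.to_numpy(dtype=float), nan=0.0)
    totals = values.sum(axis=1)
    keep = totals > 0
    normalized = values[keep] / totals[keep, None]
    return pd.DataFrame(normalized, index=intensities.index[keep],
                        columns=intensities.columns)


def map_profiles(table: ExperimentTable, condition: str, replicate: int,
                 cfg: AnalysisConfig) -> pd.DataFrame:
    """Filtered, normalized six-fraction profiles for one replicate map."""
    kept = filter_map_profiles(table, condition, replicate, cfg)
    intens = table.pellet_intensities(condition, replicate)
    return normalize_profiles(intens.loc[sorted(kept)])


def condition_maps(table: ExperimentTable, condition: str,
                   cfg: AnalysisConfig) -> dict[int, pd.DataFrame]:
    """All replicate maps of one condition, keyed by replicate number."""
    return {rep: map_profiles(table, condition, rep, cfg)
            for rep in table.replicates(condition)}


def condition_average_profile(profiles: Iterable[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of replicate profiles, renormalized to sum 1."""
    stack = np.vstack([np.asarray(p, dtype=float) for p in profiles])
    return normalize_profile(stack.mean(axis=0))


def average_condition_profiles(maps: Mapping[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-protein condition-average profiles over the proteins present in
    every replicate map."""
    common = None
    for df in maps.values():
        common = df.index if common is None else common.intersection(df.index)
    common = common.sort_values()
    mean = sum(df.loc[common].to_numpy() for df in maps.values()) / len(maps)
    mean = mean / mean.sum(axis=1, keepdims=True)
    return pd.DataFrame(mean, index=common, columns=list(PELLET_FRACTIONS))


def concatenate_replicates(maps: Mapping[int, pd.DataFrame]) -> pd.DataFrame:
    """Column-wise concatenation of replicate profiles (6R columns),
    restricted to proteins present in every replicate."""
    common = None
    for df in maps.values():
        common = df.index if common is None else common.intersection(df.index)
    common = common.sort_values()
    parts = []
    for rep in sorted(maps):
        part = maps[rep].loc[common].copy()
        part.columns = [f"rep{rep}_{c}" for c in part.columns]
        parts.append(part)
    return pd.concat(parts, axis=1)


def pca_project(profiles: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores on the first two principal components of (mean-centered)
    concatenated profiles, plus explained-variance fractions."""
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise DomsError("PCA needs at least 3 proteins")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < 2:
        raise DomsError("profile matrix has rank < 2; PCA undefined")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(centered)
    coords = pd.DataFrame(scores, index=profiles.index, columns=["PC1", "PC2"])
    return coords, pca.explained_variance_ratio_.copy()
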