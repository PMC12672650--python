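"""SVM compartment classification with iterative marker refinement.

Proteins are classified into twelve compartments from their concatenated
replicate fraction profiles by an RBF-kernel support vector machine with
probability outputs (pairwise coupling). Hyperparameters are searched over
C in [1, 30] and gamma in [1, 50] (log-uniform) for a configurable number
of candidate draws with five-fold cross-validation.

Marker training is iterative: starting from an abundance-ranked seed set
drawn from the curated reference annotation, each round trains the SVMs,
classifies all profiled proteins, and builds the next training set from
the correctly recalled markers plus all non-markers whose at-least-medium
confidence prediction matches the reference. The loop stops when training
recall is 100% and no further proteins are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, uniform
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC

from ._stats import pearson
from .io_model import AnalysisConfig, DomsError, SVM_CLASSES

__all__ = [
    "CompartmentClassifier",
    "train_svm",
    "confidence_tier",
    "classify_proteins",
    "initial_markers",
    "iterate_marker_training",
    "benchmark_f1",
    "agreement_with_reference",
    "neighborhood",
]

TIER_NAMES = ("very_high", "high", "medium", "low", "best_guess")

#: Reference categories with no SVM counterpart, dropped before agreement
#: scoring.
UNAVAILABLE_CATEGORIES = ("actin-associated", "ambiguous", "COPI", "COPII",
                          "ERGIC", "unknown")
#: Reference-to-SVM category merges: endosomes are pooled with the vacuole,
#: the cell wall with the plasma membrane.
CATEGORY_MERGES = {"endosomes": "vacuole", "cell wall": "plasma membrane"}


@dataclass
class CompartmentClassifier:
    """Fitted probabilistic SVM plus the hyperparameters and CV score that
    selected it."""

    model: SVC
    best_params: dict
    cv_accuracy: float
    feature_columns: list = field(default_factory=list)

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def predict_proba(self, profiles: pd.DataFrame) -> pd.DataFrame:
        proba = self.model.predict_proba(profiles.to_numpy(dtype=float))
        return pd.DataFrame(proba, index=profiles.index, columns=self.classes_)


def train_svm(profiles: pd.DataFrame, markers: pd.Series,
              cfg: AnalysisConfig | None = None, seed: int = 0) -> CompartmentClassifier:
    """Train the compartment SVM on marker proteins.

    ``profiles`` holds one row of (concatenated replicate) profile features
    per protein; ``markers`` maps marker protein ids to class labels.
    Classes with fewer than ``cfg.svm_min_markers`` members are excluded
    with a warning. Candidate (C, gamma) pairs are sampled from the
    configured ranges (gamma log-uniformly) and scored by stratified
    five-fold CV accuracy; the winner is refit with probability
    calibration. Deterministic under ``seed``.
    """
    cfg = cfg or AnalysisConfig()
    markers = markers[markers.index.isin(profiles.index)]
    counts = markers.value_counts()
    small = counts[counts < cfg.svm_min_markers]
    if len(small):
        warnings.warn(f"classes with too few markers excluded: {sorted(small.index)}")
        markers = markers[~markers.isin(small.index)]
    if markers.nunique() < 2:
        raise DomsError("need at least 2 classes with enough markers")
    X = profiles.loc[markers.index].to_numpy(dtype=float)
    y = markers.to_numpy()

    c_lo, c_hi = cfg.svm_c_range
    g_lo, g_hi = cfg.svm_gamma_range
    sampler = ParameterSampler(
        {"C": uniform(c_lo, c_hi - c_lo), "gamma": loguniform(g_lo, g_hi)},
        n_iter=cfg.svm_search_iterations, random_state=seed,
    )
    n_splits = min(5, int(counts[counts >= cfg.svm_min_markers].min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in sampler:
        clf = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"], random_state=seed)
        score = cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean()
        if score > best_score:
            best_score, best_params = score, params
    model = SVC(kernel="rbf", C=best_params["C"], gamma=best_params["gamma"],
                probability=True, random_state=seed)
    model.fit(X, y)
    return CompartmentClassifier(model=model, best_params=dict(best_params),
                                 cv_accuracy=float(best_score),
                                 feature_columns=list(profiles.columns))


def confidence_tier(max_score: float) -> str:
    """Assignment confidence from the top class probability.

    Strictly greater-than thresholds: >0.95 very_high, >0.8 high,
    >0.65 medium, >0.4 low, otherwise best_guess.
    """
    if not 0.0 <= max_score <= 1.0:
        raise DomsError("score must be in [0, 1]")
    for name, cut in zip(TIER_NAMES[:4], (0.95, 0.8, 0.65, 0.4)):
        if max_score > cut:
            return name
    return "best_guess"


def classify_proteins(classifier: CompartmentClassifier,
                      profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-protein class probabilities, argmax assignment and confidence
    tier. Probability ties resolve to the lexicographically first class
    and are flagged in the ``tie`` column."""
    proba = classifier.predict_proba(profiles)
    classes = np.array(sorted(proba.columns))
    proba = proba[classes]
    scores = proba.to_numpy()
    top = scores.argmax(axis=1)
    max_score = scores[np.arange(len(scores)), top]
    tie = (np.isclose(scores, max_score[:, None]).sum(axis=1) > 1)
    result = proba.add_prefix("score_")
    result["assigned_class"] = classes[top]
    result["max_score"] = max_score
    result["tier"] = [confidence_tier(s) for s in max_score]
    result["tie"] = tie
    return result


def initial_markers(reference: pd.Series, abundance: pd.Series,
                    profiled_ids: Sequence[str], top_n: int = 100) -> pd.Series:
    """Seed training set from the reference annotation.

    For the large classes (cytosol, ER, mitochondria, nucleus, plasma
    membrane, vacuole) the ``top_n`` most abundant profiled proteins are
    taken; for the small classes every profiled member is used. Categories
    with inherently ambiguous fractionation are not seeded.
    """
    large = {"cytosol", "ER", "mitochondria", "nucleus", "plasma membrane", "vacuole"}
    reference = reference[reference.index.isin(profiled_ids)]
    reference = reference[reference.isin(SVM_CLASSES)]
    parts = []
    for cls, members in reference.groupby(reference):
        ids = members.index
        if cls in large and len(ids) > top_n:
            ids = abundance.reindex(ids).sort_values(ascending=False).index[:top_n]
        parts.append(pd.Series(cls, index=ids))
    return pd.concat(parts)


@dataclass
class MarkerTrainingResult:
    markers: pd.Series
    classifier: CompartmentClassifier
    audit: list
    final_recall: float


def iterate_marker_training(initial: pd.Series, profiles: pd.DataFrame,
                            reference: pd.Series, cfg: AnalysisConfig | None = None,
                            seed: int = 0) -> MarkerTrainingResult:
    """Iterative marker refinement loop.

    Each round trains on the current marker set and classifies every
    profiled protein. The next training set is the union of correctly
    recalled markers and non-markers whose >= medium-confidence prediction
    matches the reference annotation. Terminates when recall is 100% and
    nothing is added; raises after ``cfg.marker_training_max_rounds``
    rounds otherwise, attaching the per-round audit log.
    """
    cfg = cfg or AnalysisConfig()
    current = initial.copy()
    audit = []
    confident = {"very_high", "high", "medium"}
    for round_no in range(1, cfg.marker_training_max_rounds + 1):
        classifier = train_svm(profiles, current, cfg, seed=seed)
        predictions = classify_proteins(classifier, profiles)
        trained = current[current.index.isin(profiles.index)]
        assigned = predictions.loc[trained.index, "assigned_class"]
        recalled = trained[assigned == trained]
        recall = len(recalled) / len(trained)
        others = predictions.index.difference(trained.index)
        matchable = reference.reindex(others).dropna()
        preds = predictions.loc[matchable.index]
        addable = matchable[
            (preds["assigned_class"] == matchable) & preds["tier"].isin(confident)
        ]
        audit.append({
            "round": round_no,
            "n_markers": len(trained),
            "recall": recall,
            "n_added": len(addable),
        })
        new = pd.concat([recalled, addable]).sort_index()
        if recall == 1.0 and len(addable) == 0:
            return MarkerTrainingResult(markers=trained.sort_index(),
                                        classifier=classifier, audit=audit,
                                        final_recall=recall)
        current = new
    raise DomsError(f"marker training did not converge; audit: {audit}")


def benchmark_f1(profiles: pd.DataFrame, markers: pd.Series,
                 cfg: AnalysisConfig | None = None, seed: int = 0,
                 exclude: Sequence[str] = ("lipid droplets", "peroxisomes"),
                 n_subsamples: int = 20, subsample_fraction: float = 0.75) -> pd.Series:
    """Per-class F1 from a stratified 80:20 marker split.

    The model is trained (with CV hyperparameter search) on the 80% split
    and applied to the leave-out 20%; per-class F1 scores are averaged over
    ``n_subsamples`` random 75% subsamples of the test predictions.
    Classes without test members are reported as NaN (not benchmarkable);
    classes listed in ``exclude`` have too few members for an informative
    test set and are left out entirely.
    """
    cfg = cfg or AnalysisConfig()
    markers = markers[markers.index.isin(profiles.index)]
    markers = markers[~markers.isin(list(exclude))]
    train_ids, test_ids = train_test_split(
        markers.index, test_size=0.2, stratify=markers.to_numpy(), random_state=seed)
    classifier = train_svm(profiles, markers.loc[train_ids], cfg, seed=seed)
    predicted = classify_proteins(classifier, profiles.loc[test_ids])["assigned_class"]
    truth = markers.loc[test_ids]
    classes = sorted(markers.unique())
    rng = np.random.default_rng(seed)
    scores = np.zeros((n_subsamples, len(classes)))
    k = max(1, int(round(subsample_fraction * len(test_ids))))
    for s in range(n_subsamples):
        pick = rng.choice(len(test_ids), size=k, replace=False)
        sub_truth = truth.iloc[pick]
        sub_pred = predicted.iloc[pick]
        scores[s] = f1_score(sub_truth, sub_pred, labels=classes,
                             average=None, zero_division=0)
        absent = ~np.isin(classes, sub_truth.unique())
        scores[s, absent] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_scores = np.nanmean(scores, axis=0)
    return pd.Series(mean_scores, index=classes, name="F1")


def agreement_with_reference(predictions: pd.Series, reference: pd.Series,
                             cytosolic_pools: pd.Series,
                             cfg: AnalysisConfig | None = None) -> tuple[float, pd.DataFrame]:
    """Agreement of SVM assignments with the curated reference.

    Reference categories unavailable to the SVMs are dropped; endosomes
    are merged into vacuole and cell wall into plasma membrane. A
    prediction matches when it equals the merged reference category or
    when it is "cytosol" and the protein's measured cytosolic pool exceeds
    the dual-localization cut-off (default 30%).
    """
    cfg = cfg or AnalysisConfig()
    shared = predictions.index.intersection(reference.index)
    ref = reference.loc[shared]
    ref = ref[~ref.isin(UNAVAILABLE_CATEGORIES)]
    ref = ref.replace(CATEGORY_MERGES)
    pred = predictions.loc[ref.index]
    pools = cytosolic_pools.reindex(ref.index)
    direct = pred == ref
    dual = (pred == "cytosol") & (pools > cfg.dual_localization_pool_cutoff)
    match = direct | dual.fillna(False)
    table = pd.DataFrame({
        "predicted": pred, "reference": ref,
        "cytosolic_pool": pools, "match": match,
    })
    return float(match.mean()), table


def neighborhood(query_id: str, profiles: pd.DataFrame, k: int = 10) -> pd.Series:
    """The k proteins with the smallest Pearson-correlation distance
    (1 - r on concatenated replicate profiles) to the query, nearest
    first; the query itself is excluded."""
    if query_id not in profiles.index:
        raise DomsError(f"unknown protein id {query_id!r}")
    query = profiles.loc[query_id].to_numpy(dtype=float)
    others = profiles.drop(index=query_id)
    dist = others.apply(lambda row: 1.0 - pearson(query, row.to_numpy()), axis=1)
    return dist.sort_values().head(k)
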