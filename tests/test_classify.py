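"""Compartment classification: SVM training, confidence tiers, the
iterative marker loop, benchmarking, reference agreement and the
neighborhood predictor."""

import numpy as np
import pandas as pd
import pytest

from doms.classify import (
    agreement_with_reference,
    benchmark_f1,
    classify_proteins,
    confidence_tier,
    initial_markers,
    iterate_marker_training,
    neighborhood,
    train_svm,
)
from doms.io_model import AnalysisConfig, DomsError


def separable_profiles(n_per_class=20, n_classes=3, noise=0.01, seed=0):
    """Well-separated synthetic profile clusters."""
    rng = np.random.default_rng(seed)
    centers = np.eye(6)[:n_classes] * 0.8 + 0.04
    rows, labels, ids = [], [], []
    for k in range(n_classes):
        for i in range(n_per_class):
            prof = np.abs(centers[k] + rng.normal(0, noise, 6))
            rows.append(prof / prof.sum())
            labels.append(f"class{k}")
            ids.append(f"C{k}_{i}")
    profiles = pd.DataFrame(rows, index=ids)
    return profiles, pd.Series(labels, index=ids)


class TestTrainSvm:
    def test_separable_data_perfect_cv(self, cfg):
        profiles, markers = separable_profiles()
        clf = train_svm(profiles, markers, cfg, seed=1)
        assert clf.cv_accuracy == pytest.approx(1.0)
        assert 1.0 <= clf.best_params["C"] <= 30.0
        assert 1.0 <= clf.best_params["gamma"] <= 50.0

    def test_same_seed_same_hyperparameters(self, cfg):
        profiles, markers = separable_profiles()
        a = train_svm(profiles, markers, cfg, seed=5)
        b = train_svm(profiles, markers, cfg, seed=5)
        assert a.best_params == b.best_params

    def test_small_class_excluded_with_warning(self, cfg):
        profiles, markers = separable_profiles()
        markers.iloc[:3] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            clf = train_svm(profiles, markers, cfg, seed=0)
        assert "tiny" not in clf.classes_


class TestConfidenceTier:
    @pytest.mark.parametrize("score,tier", [
        (0.96, "very_high"),
        (0.95, "high"),      # strict >
        (0.81, "high"),
        (0.66, "medium"),
        (0.41, "low"),
        (0.40, "best_guess"),  # boundary, strict >
        (0.10, "best_guess"),
    ])
    def test_thresholds(self, score, tier):
        assert confidence_tier(score) == tier

    def test_total_on_unit_interval(self):
        for s in np.linspace(0, 1, 101):
            assert confidence_tier(s) in ("very_high", "high", "medium",
                                          "low", "best_guess")
        with pytest.raises(DomsError):
            confidence_tier(1.5)


def test_classification_scores_sum_to_one(cfg):
    profiles, markers = separable_profiles()
    clf = train_svm(profiles, markers, cfg, seed=2)
    out = classify_proteins(clf, profiles)
    score_cols = [c for c in out.columns if c.startswith("score_")]
    np.testing.assert_allclose(out[score_cols].sum(axis=1), 1.0, atol=1e-6)
    # assignment is the argmax of the probability scores
    argmax = out[score_cols].to_numpy().argmax(axis=1)
    names = [c.removeprefix("score_") for c in score_cols]
    assert all(out["assigned_class"].iloc[i] == names[argmax[i]]
               for i in range(len(out)))


class TestIterativeTraining:
    def test_converges_and_keeps_correct_markers(self, cfg):
        profiles, reference = separable_profiles(n_per_class=30)
        seed_markers = reference.groupby(reference).head(10)
        result = iterate_marker_training(seed_markers, profiles, reference,
                                         cfg, seed=3)
        assert result.final_recall == 1.0
        assert set(seed_markers.index) <= set(result.markers.index)
        assert len(result.markers) > len(seed_markers)  # confident additions

    def test_idempotent_on_own_output(self, cfg):
        profiles, reference = separable_profiles(n_per_class=30)
        seed_markers = reference.groupby(reference).head(10)
        first = iterate_marker_training(seed_markers, profiles, reference,
                                        cfg, seed=3)
        second = iterate_marker_training(first.markers, profiles, reference,
                                         cfg, seed=3)
        assert set(second.markers.index) == set(first.markers.index)

    def test_mislabeled_cluster_never_enters(self, cfg):
        profiles, reference = separable_profiles(n_per_class=30)
        wrong = reference.copy()
        liars = wrong.index[wrong == "class2"]
        wrong.loc[liars] = "class0"  # reference deliberately contradicts profiles
        seed_markers = reference.groupby(reference).head(10)
        seed_markers = seed_markers[seed_markers != "class2"]
        result = iterate_marker_training(seed_markers, profiles, wrong, cfg, seed=3)
        assert not set(liars) & set(result.markers.index)


class TestBenchmarkF1:
    def test_perfect_classifier(self, cfg):
        profiles, markers = separable_profiles(n_per_class=40)
        f1 = benchmark_f1(profiles, markers, cfg, seed=4, exclude=())
        assert (f1.dropna() == 1.0).all()

    def test_f1_is_harmonic_mean_on_hand_confusion(self):
        """Cross-check the F1 definition on a hand-built 2x2 confusion
        table: precision 2/3, recall 1/2 -> F1 = 4/7."""
        from sklearn.metrics import f1_score

        truth = ["a", "a", "a", "a", "b", "b"]
        pred = ["a", "a", "b", "b", "a", "b"]
        f1 = f1_score(truth, pred, labels=["a", "b"], average=None)
        precision, recall = 2 / 3, 2 / 4
        assert f1[0] == pytest.approx(2 * precision * recall / (precision + recall))


def test_initial_markers_top_abundance():
    reference = pd.Series(
        ["cytosol"] * 150 + ["Golgi"] * 8,
        index=[f"P{i}" for i in range(158)])
    abundance = pd.Series(np.arange(158.0), index=reference.index)
    out = initial_markers(reference, abundance, reference.index, top_n=100)
    assert (out == "cytosol").sum() == 100
    assert (out == "Golgi").sum() == 8  # small class: all members
    kept_cytosol = out.index[out == "cytosol"]
    assert abundance.loc[kept_cytosol].min() == 50.0  # most abundant kept


class TestAgreement:
    def test_identical_labels(self, cfg):
        pred = pd.Series({"P1": "ER", "P2": "Golgi"})
        ref = pd.Series({"P1": "ER", "P2": "Golgi"})
        pools = pd.Series({"P1": 0.0, "P2": 0.0})
        frac, _ = agreement_with_reference(pred, ref, pools, cfg)
        assert frac == 1.0

    def test_category_merges_and_dual_localization(self, cfg):
        pred = pd.Series({"P1": "vacuole", "P2": "plasma membrane",
                          "P3": "cytosol", "P4": "cytosol", "P5": "ER"})
        ref = pd.Series({"P1": "endosomes", "P2": "cell wall",
                         "P3": "nucleus", "P4": "nucleus", "P5": "ambiguous"})
        pools = pd.Series({"P1": 0.0, "P2": 0.0, "P3": 0.45, "P4": 0.10,
                           "P5": 0.0})
        frac, table = agreement_with_reference(pred, ref, pools, cfg)
        assert "P5" not in table.index  # unavailable category dropped
        assert bool(table.loc["P1", "match"])   # endosomes -> vacuole
        assert bool(table.loc["P2", "match"])   # cell wall -> plasma membrane
        assert bool(table.loc["P3", "match"])   # dual localization, pool > 30%
        assert not bool(table.loc["P4", "match"])
        assert frac == pytest.approx(3 / 4)


class TestNeighborhood:
    def test_duplicate_profile_ranks_first(self):
        profiles, _ = separable_profiles()
        profiles.loc["twin"] = profiles.loc["C0_0"]
        nn = neighborhood("C0_0", profiles, k=3)
        assert nn.index[0] == "twin"
        assert nn.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_universe(self):
        profiles, _ = separable_profiles(n_per_class=3, n_classes=2)
        nn = neighborhood("C0_0", profiles, k=100)
        assert len(nn) == len(profiles) - 1
        assert (nn.diff().dropna() >= -1e-12).all()  # ordered

    def test_unknown_id(self):
        profiles, _ = separable_profiles()
        with pytest.raises(DomsError):
            neighborhood("nope", profiles)

    def test_same_compartment_neighbors(self, cfg, small_simulation):
        from doms.io_model import concatenate_replicates, condition_maps

        table, truth = small_simulation
        features = concatenate_replicates(condition_maps(table, "control", cfg))
        er = truth.index[(truth["compartment"] == "ER")
                         & (truth["alpha_treatment"] == 0)]
        er = er.intersection(features.index)
        nn = neighborhood(er[0], features, k=5)
        neighbor_classes = truth.loc[nn.index, "compartment"]
        assert (neighbor_classes == "ER").mean() >= 0.8
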