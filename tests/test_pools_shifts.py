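"""Cytosolic pools, pool-shift calling, organelle-level shifts and the
ER-redistribution cascade."""

import numpy as np
import pandas as pd
import pytest

from doms.io_model import AnalysisConfig, PELLET_FRACTIONS, condition_maps
from doms.pools_shifts import (
    POOL_FRACTIONS,
    classify_lumenal_er,
    classify_post_er,
    er_shift_candidates,
    organelle_shift_test,
    pool_profile,
    pool_profiles,
    pool_shift_test,
)
from doms.synthetic_data import SimulationConfig, default_yields, make_annotations, simulate_experiment

EQUAL_YIELDS = {f: 0.1 for f in POOL_FRACTIONS}


class TestPoolProfile:
    def test_all_signal_in_cytosol(self):
        prof = pool_profile([0, 0, 0, 0, 0, 0, 5.0], EQUAL_YIELDS)
        assert prof[6] == pytest.approx(1.0)

    def test_equal_weighted_intensities(self):
        prof = pool_profile(np.ones(7), EQUAL_YIELDS)
        np.testing.assert_allclose(prof, np.full(7, 1 / 7))

    def test_hand_arithmetic(self):
        yields = {f: 0.1 for f in PELLET_FRACTIONS} | {"cytosol": 0.4}
        prof = pool_profile([1, 1, 1, 1, 1, 1, 2.0], yields)
        assert prof[6] == pytest.approx(0.8 / 1.4)  # 0.571

    def test_partition_of_recovery(self):
        rng = np.random.default_rng(0)
        yields = default_yields()
        for _ in range(20):
            prof = pool_profile(rng.uniform(0.1, 10, 7), yields)
            assert prof.sum() == pytest.approx(1.0)
            assert prof[6] + prof[:6].sum() == pytest.approx(1.0)


def make_pools(control, dtt, tm, noise=0.0, seed=0):
    """Three-condition replicate pool frames for a single-protein test,
    plus stable null proteins to populate the BH universe."""
    rng = np.random.default_rng(seed)
    out = {}
    for cond, center in (("control", control), ("DTT", dtt), ("Tm", tm)):
        out[cond] = {}
        for rep in (1, 2, 3):
            pools = {"P0": center + noise * rng.normal()}
            for i in range(1, 20):
                pools[f"N{i}"] = 0.3 + 0.001 * rng.normal()
            frame = pd.DataFrame({"cytosol": pools})
            for f in PELLET_FRACTIONS:
                frame[f] = (1 - frame["cytosol"]) / 6
            out[cond][rep] = frame[list(POOL_FRACTIONS)]
    return out


class TestPoolShift:
    def test_no_change_is_not_hit(self, cfg):
        pools = make_pools(0.3, 0.3, 0.3)
        result = pool_shift_test(pools, cfg)
        assert result.loc["P0", "p_dtt"] == pytest.approx(1.0)
        assert not result["hit"].any()

    def test_planted_twenty_point_shift_is_hit(self, cfg):
        pools = make_pools(0.30, 0.50, 0.50, noise=0.01, seed=1)
        result = pool_shift_test(pools, cfg)
        assert bool(result.loc["P0", "hit"])
        assert result.loc["P0", "change_dtt"] == pytest.approx(20, abs=3)

    def test_five_point_shift_blocked_by_magnitude_filter(self, cfg):
        pools = make_pools(0.30, 0.35, 0.35, noise=0.001, seed=2)
        result = pool_shift_test(pools, cfg)
        assert result.loc["P0", "p_dtt"] < 0.05  # significant but small
        assert not bool(result.loc["P0", "hit"])

    def test_opposite_directions_blocked(self, cfg):
        pools = make_pools(0.30, 0.55, 0.30, noise=0.005, seed=3)
        for rep in (1, 2, 3):  # Tm moves the other way
            pools["Tm"][rep].loc["P0", "cytosol"] = 0.05
        result = pool_shift_test(pools, cfg)
        assert not bool(result.loc["P0", "hit"])


class TestOrganelleShift:
    def build_maps(self, shift=0.0, seed=0, n_markers=8):
        rng = np.random.default_rng(seed)
        base = np.array([0.5, 0.2, 0.1, 0.1, 0.05, 0.05])
        moved = base + shift * np.array([-1, 1, 0, 0, 0, 0]) * 0.5
        markers = pd.Series("orgA", index=[f"A{i}" for i in range(n_markers)])
        ctrl, trt = {}, {}
        for rep in (1, 2, 3):
            rows_c, rows_t = {}, {}
            for pid in markers.index:
                noise = rng.normal(0, 0.003, 6)
                c = np.abs(base + noise)
                t = np.abs(moved + rng.normal(0, 0.003, 6))
                rows_c[pid] = c / c.sum()
                rows_t[pid] = t / t.sum()
            ctrl[rep] = pd.DataFrame.from_dict(rows_c, orient="index",
                                               columns=list(PELLET_FRACTIONS))
            trt[rep] = pd.DataFrame.from_dict(rows_t, orient="index",
                                              columns=list(PELLET_FRACTIONS))
        return ctrl, trt, markers

    def test_identical_conditions_not_shifted(self, cfg):
        ctrl, _, markers = self.build_maps(seed=1)
        result = organelle_shift_test(ctrl, ctrl, markers, cfg)
        assert result.loc["orgA", "distance"] == 0.0
        assert not bool(result.loc["orgA", "shifted"])

    def test_large_shift_flagged(self, cfg):
        ctrl, trt, markers = self.build_maps(shift=0.5, seed=2)
        result = organelle_shift_test(ctrl, trt, markers, cfg)
        row = result.loc["orgA"]
        assert row["magnitude"] == "large"  # L1 distance ~0.5 > 0.3
        assert bool(row["shifted"])
        assert row["Q"] < 0.05

    def test_q_is_six_times_min_p(self, cfg):
        """Unit vectors swapping fractions: distance 2, magnitude large."""
        markers = pd.Series("orgA", index=["A0", "A1", "A2", "A3", "A4"])
        def prof1(r):
            return [1 - 2e-4 * r, 1e-4 * r, 1e-4 * r, 0, 0, 0.0]

        def prof2(r):
            return [1e-4 * r, 1 - 3e-4 * r, 2e-4 * r, 0, 0, 0.0]

        ctrl = {r: pd.DataFrame([prof1(r)] * 5, index=markers.index,
                                columns=list(PELLET_FRACTIONS)) for r in (1, 2, 3)}
        trt = {r: pd.DataFrame([prof2(r)] * 5, index=markers.index,
                               columns=list(PELLET_FRACTIONS)) for r in (1, 2, 3)}
        result = organelle_shift_test(ctrl, trt, markers, cfg)
        row = result.loc["orgA"]
        assert row["distance"] == pytest.approx(2.0, abs=1e-2)
        assert row["magnitude"] == "large"
        # Q = min(1, 6 * smallest datapoint p)
        from doms._stats import paired_t

        pmin = min(paired_t([c.iloc[0, j] for c in ctrl.values()],
                            [t.iloc[0, j] for t in trt.values()])[1]
                   for j in range(6))
        assert row["Q"] == pytest.approx(min(1.0, 6 * pmin), rel=1e-6)

    def test_marker_order_invariance(self, cfg):
        ctrl, trt, markers = self.build_maps(shift=0.3, seed=3)
        shuffled = markers.sample(frac=1.0, random_state=1)
        a = organelle_shift_test(ctrl, trt, markers, cfg)
        b = organelle_shift_test(ctrl, trt, shuffled, cfg)
        assert a.loc["orgA", "Q"] == pytest.approx(b.loc["orgA", "Q"])
        assert a.loc["orgA", "distance"] == pytest.approx(b.loc["orgA", "distance"])

    def test_only_displaced_organelle_flagged(self, cfg):
        """A global displacement of one compartment template flags that
        organelle and only that organelle."""
        sim = SimulationConfig(n_proteins=400, seed=9)
        templates_shifted = None
        from doms.synthetic_data import CompartmentTemplate, default_templates

        shifted = []
        for t in default_templates():
            if t.name == "ER":  # emulate the stress-induced ER shift
                prof = np.roll(t.profile, -2)
                shifted.append(CompartmentTemplate("ER", tuple(prof / prof.sum()),
                                                   t.cytosol_leak))
            else:
                shifted.append(t)
        table_c, truth = simulate_experiment(sim, conditions=("control",))
        sim2 = SimulationConfig(n_proteins=400, seed=9)
        table_t, _ = simulate_experiment(sim2, templates=shifted,
                                         conditions=("control",))
        ctrl = condition_maps(table_c, "control", cfg)
        trt = condition_maps(table_t, "control", cfg)
        markers = truth["compartment"]
        result = organelle_shift_test(ctrl, trt, markers, cfg)
        assert bool(result.loc["ER", "shifted"])
        others = result.drop(index="ER")
        assert not others["shifted"].any()


class TestAnnotationFilters:
    def annotations(self):
        return pd.DataFrame({
            "category": ["ER", "ER", "Golgi", "Golgi", "mitochondria", "ER"],
            "n_tm_domains": [0, 1, 1, 0, 1, 0],
            "has_signal_peptide": [True, True, False, True, False, False],
            "has_transit_peptide": [False, False, False, False, True, False],
            "molecular_weight": [5e4] * 6,
        }, index=["LUM", "MEM", "GOL", "GSP", "MITO", "ERBARE"])

    def test_lumenal_er(self):
        assert classify_lumenal_er(self.annotations()) == {"LUM"}

    def test_post_er(self):
        out = classify_post_er(self.annotations())
        assert out == {"GOL", "GSP"}  # ER excluded, transit peptide excluded

    def test_post_er_with_override_localizations(self):
        ann = self.annotations()
        override = pd.Series({"MEM": "Golgi"})  # SVM disagrees with reference
        assert "MEM" in classify_post_er(ann, override)


class TestErShiftCandidates:
    def test_recovers_planted_movers(self, cfg):
        sim = SimulationConfig(n_proteins=500, n_relocalizers=10,
                               alpha_shift_sizes=(0.8,), seed=13)
        table, truth = simulate_experiment(
            sim, conditions=("control", "DTT"),
            relocalizer_pool=("Golgi", "plasma membrane", "vacuole"),
            relocalizer_target="ER")
        from doms.mr import mr_analysis

        annotations = make_annotations(truth, seed=13)
        ctrl = condition_maps(table, "control", cfg)
        trt = condition_maps(table, "DTT", cfg)
        mr = mr_analysis(ctrl, trt, cfg)
        er_ids = truth.index[truth["compartment"] == "ER"]
        post_er = classify_post_er(annotations)
        report = er_shift_candidates(ctrl, trt, er_ids, mr.hits, post_er, cfg)
        planted = truth.index[(truth["alpha_treatment"] > 0)].intersection(report.table.index)
        assert len(planted) >= 5
        recovered = planted.intersection(report.candidates)
        assert len(recovered) / len(planted) >= 0.9
        # a planted mover correlates with the ER profile under stress
        assert (report.table.loc[recovered, "correl_dtt_er"] > 0.75).all()
        assert (report.table.loc[recovered, "delta_correl_er"] > 0).all()
        # non-secretory proteins are excluded by the post-ER filter
        cytosolic = truth.index[truth["compartment"] == "cytosol"]
        assert not set(cytosolic) & set(report.candidates)

    def test_protein_identical_to_er_profile_not_candidate(self, cfg):
        """DeltaCorrelER = 0 for a protein that tracks the ER average in
        both conditions, so it cannot qualify."""
        rng = np.random.default_rng(1)
        er_base = np.array([0.05, 0.15, 0.30, 0.35, 0.10, 0.05])
        rows = {f"ER{i}": np.abs(er_base + rng.normal(0, 0.002, 6)) for i in range(10)}
        rows["QUERY"] = er_base
        for i in range(30):
            prof = rng.dirichlet(np.ones(6))
            rows[f"X{i}"] = prof
        maps = {r: pd.DataFrame.from_dict(
            {k: v / np.sum(v) for k, v in rows.items()}, orient="index",
            columns=list(PELLET_FRACTIONS)) for r in (1, 2, 3)}
        report = er_shift_candidates(maps, maps, [f"ER{i}" for i in range(10)],
                                     mr_hits=["QUERY"], post_er=["QUERY"], cfg=cfg)
        row = report.table.loc["QUERY"]
        assert row["delta_correl_er"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(row["candidate"])
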