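"""Synthetic clone trees, bulk counts, and plate error structure."""

import numpy as np
import pytest

import mfclone as m
from mfclone.simulate import LEGAL_EVENTS


class TestCloneTree:
    def test_smallest_tree_is_linear_chain(self):
        tree = m.simulate_clone_tree(2, 0, seed=1)
        assert [tuple(c.genotype) for c in tree.clones] == [(1, 0), (1, 1)]
        assert tree.clones[1].parent_id == tree.clones[0].id

    def test_requested_loh_events_present(self):
        tree = m.simulate_clone_tree(4, 1, seed=7)
        loh = [(a, x, y) for a, x, y in tree.all_events() if (x, y) in {(1, 2), (1, 0)}]
        assert len(loh) == 1

    def test_same_seed_same_tree(self):
        a = m.simulate_clone_tree(6, 2, seed=5)
        b = m.simulate_clone_tree(6, 2, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_all_edges_are_legal_events(self):
        for seed in range(10):
            tree = m.simulate_clone_tree(6, 1, seed=seed)
            for _, a, b in tree.all_events():
                assert (a, b) in LEGAL_EVENTS

    def test_prevalences_leave_wild_type_remainder(self):
        tree = m.simulate_clone_tree(5, 1, seed=3)
        for tp in tree.time_points:
            total = sum(tree.prevalence[tp].values())
            assert 0.0 < total <= 1.0
            assert tree.wt_fraction(tp) == pytest.approx(1.0 - total)

    def test_wt_root_carries_no_mutation(self):
        tree = m.simulate_clone_tree(4, 0, seed=2, root="wt")
        root = next(c for c in tree.clones if c.parent_id is None)
        assert tuple(root.genotype) == (0, 0, 0, 0)

    @pytest.mark.parametrize("n_assays,n_loh", [(1, 0), (13, 0), (4, 5)])
    def test_invalid_budget_rejected(self, n_assays, n_loh):
        with pytest.raises(ValueError):
            m.simulate_clone_tree(n_assays, n_loh, seed=0)


class TestBulk:
    def _one_clone_tree(self, code):
        assays = [m.Assay("JAK2", True), m.Assay("TET2")]
        clones = [m.Clone("C1", None, (1, 0))]
        if code == 2:
            clones.append(m.Clone("C2", "C1", (2, 0)))
            prev = {"t1": {"C1": 0.0, "C2": 1.0}}
        else:
            prev = {"t1": {"C1": 1.0}}
        return m.CloneTreeSpec(assays=assays, clones=clones, prevalence=prev)

    def test_clonal_heterozygous_vaf_near_half(self):
        tree = self._one_clone_tree(1)
        cfg = m.SimulationConfig(bulk_depth=10_000, seed=0)
        vaf = m.simulate_bulk(tree, "t1", cfg)["vaf"].iloc[0]
        assert vaf == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 10_000))

    def test_homozygous_clone_vaf_near_one(self):
        tree = self._one_clone_tree(2)
        cfg = m.SimulationConfig(bulk_depth=10_000, seed=1)
        assert m.simulate_bulk(tree, "t1", cfg)["vaf"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_mixture_arithmetic(self):
        # two clones at 0.5/0.5, genotypes het and wt at the second assay -> VAF 0.25
        assays = [m.Assay("JAK2", True), m.Assay("TET2")]
        clones = [m.Clone("C1", None, (1, 0)), m.Clone("C2", "C1", (1, 1))]
        tree = m.CloneTreeSpec(assays=assays, clones=clones,
                               prevalence={"t1": {"C1": 0.5, "C2": 0.5}})
        assert tree.expected_vaf("t1")[1] == pytest.approx(0.25)

    def test_missing_time_point_errors(self, small_tree, default_config):
        with pytest.raises(ValueError, match="time point"):
            m.simulate_bulk(small_tree, "t99", default_config)

    def test_analytic_vaf_matches_replicate_mean(self, small_tree):
        expected = small_tree.expected_vaf("t1")
        depth, reps = 1000, 1000
        rng = np.random.default_rng(0)
        sims = rng.binomial(depth, expected, size=(reps, len(expected))) / depth
        se = np.sqrt(expected * (1 - expected) / depth / reps)
        assert np.all(np.abs(sims.mean(axis=0) - expected) <= 3 * se + 1e-12)


class TestPlate:
    def test_all_empty_when_empty_rate_one(self, small_tree):
        cfg = m.SimulationConfig(n_wells=20, empty_rate=1.0, seed=0)
        plate = m.simulate_plate(small_tree, "t1", cfg)
        for w in plate.wells:
            assert not any(s.amplified for s in w.controls.values())
            assert all(not wt.amplified and not mut.amplified for wt, mut in w.reactions.values())

    def test_noise_free_wells_match_clone_genotypes(self, small_tree):
        cfg = m.SimulationConfig(n_wells=100, empty_rate=0, doublet_rate=0,
                                 fpr_per_assay=0.0, seed=4)
        plate = m.simulate_plate(small_tree, "t1", cfg)
        valid = {small_tree.genotype_of(c.id) for c in small_tree.clones}
        valid.add(tuple([0] * len(small_tree.assays)))
        for w in plate.wells:
            codes = m.genotype_cell(w, plate.assays)
            assert tuple(codes) in valid

    def test_empty_fraction_converges(self, small_tree):
        cfg = m.SimulationConfig(n_wells=10_000, empty_rate=0.09, seed=9)
        plate = m.simulate_plate(small_tree, "t1", cfg)
        frac = np.mean([w.truth["status"] == "empty" for w in plate.wells])
        assert abs(frac - 0.09) <= 3 * np.sqrt(0.09 * 0.91 / 10_000)

    def test_doublet_controls_shift_one_cycle(self, small_tree):
        cfg = m.SimulationConfig(n_wells=2000, empty_rate=0, doublet_rate=0.5, seed=2)
        plate = m.simulate_plate(small_tree, "t1", cfg)
        cts = {"singlet": [], "doublet": []}
        for w in plate.wells:
            cts[w.truth["status"]].append(w.controls[plate.control_probes[0]].ct)
        shift = np.mean(cts["singlet"]) - np.mean(cts["doublet"])
        assert shift == pytest.approx(1.0, abs=0.05)

    def test_seed_reproducibility_byte_identical(self, small_tree, tmp_path):
        import mfclone.io as mfio

        cfg = m.SimulationConfig(n_wells=50, seed=77)
        for name in ("a.csv", "b.csv"):
            mfio.write_plate_csv(m.simulate_plate(small_tree, "t1", cfg), tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestControlPlate:
    def test_zero_fpr_means_zero_mutant_positives(self):
        plate = m.simulate_control_plate(0.0, 200, seed=1)
        for w in plate.wells:
            assert not any(mut.amplified for _, mut in w.reactions.values())

    def test_fpr_converges(self):
        plate = m.simulate_control_plate({"A1": 0.05}, 1000, seed=3)
        hits = np.mean([w.reactions["A1"][1].amplified for w in plate.wells])
        assert abs(hits - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_reproducible(self):
        a = m.simulate_control_plate(0.02, 50, seed=5)
        b = m.simulate_control_plate(0.02, 50, seed=5)
        for wa, wb in zip(a.wells, b.wells):
            assert wa.reactions == wb.reactions and wa.controls == wb.controls
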