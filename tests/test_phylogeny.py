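"""Finite-sites likelihood, exhaustive/heuristic tree search, Newick, event census."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mfclone as m
from mfclone.phylogeny import ErrorModel, PhyloTree, event_path

from conftest import simulate_and_call, topology_recovered


def event_score(tree, model=None):
    model = model or ErrorModel()
    return -sum(model.weight(e.from_code, e.to_code) for e in tree.all_events())


class TestEventAlphabet:
    def test_legal_paths(self):
        assert event_path(0, 1) == ((0, 1),)
        assert event_path(1, 2) == ((1, 2),)
        assert event_path(1, 0) == ((1, 0),)
        assert event_path(0, 2) == ((0, 1), (1, 2))

    @pytest.mark.parametrize("a,b", [(2, 1), (2, 0)])
    def test_homozygous_state_cannot_revert(self, a, b):
        assert event_path(a, b) is None

    def test_illegal_edge_rejected_at_construction(self):
        with pytest.raises(ValueError, match="illegal"):
            PhyloTree(assays=["A"], names=["root", "G1"], genotypes=[(2,), (0,)],
                      parent=[None, 0])


class TestLikelihood:
    def _single_node_tree(self, genotype):
        return PhyloTree(assays=[f"A{i+1}" for i in range(len(genotype))],
                         names=["root"], genotypes=[tuple(genotype)], parent=[None])

    def test_perfect_match_zero_error_zero_prior(self):
        tree = m.exhaustive_ml([(1, 0), (1, 1)],
                               ErrorModel(event_weight=0.0, loh_weight=0.0))
        matrix = pd.DataFrame([[1, 0], [1, 1]], columns=tree.assays)
        model = ErrorModel(alpha=0.0, beta=0.0, event_weight=0.0, loh_weight=0.0)
        assert m.tree_log_likelihood(tree, matrix, model) == pytest.approx(0.0)

    def test_false_positive_emission(self):
        tree = self._single_node_tree((0,))
        model = ErrorModel(alpha=0.05, event_weight=0.0, loh_weight=0.0)
        ll = m.tree_log_likelihood(tree, [[1]], model)
        assert ll == pytest.approx(math.log(0.05))

    def test_unexplainable_cell_raises(self):
        tree = self._single_node_tree((0,))
        with pytest.raises(ValueError, match="assignable"):
            m.tree_log_likelihood(tree, [[2]], ErrorModel(alpha=0.05))

    def test_invariance_to_node_order_and_cell_order(self):
        assays = ["JAK2", "TET2", "ASXL1"]
        genos = [(1, 0, 0), (1, 1, 0), (1, 0, 1)]
        t1 = PhyloTree(assays=assays, names=["root", "a", "b"],
                       genotypes=[genos[0], genos[1], genos[2]], parent=[None, 0, 0])
        t2 = PhyloTree(assays=assays, names=["root", "b", "a"],
                       genotypes=[genos[0], genos[2], genos[1]], parent=[None, 0, 0])
        rng = np.random.default_rng(0)
        cells = [genos[rng.integers(3)] for _ in range(30)]
        model = ErrorModel(alpha=0.01)
        matrix = pd.DataFrame(cells, columns=assays)
        shuffled = matrix.sample(frac=1.0, random_state=1)
        assert m.tree_log_likelihood(t1, matrix, model) == pytest.approx(
            m.tree_log_likelihood(t2, shuffled, model))


class TestExhaustive:
    def test_unique_minimal_chain(self):
        tree = m.exhaustive_ml([(0, 0), (1, 0), (1, 1)])
        by_geno = {tuple(g): i for i, g in enumerate(tree.genotypes)}
        assert tree.parent[by_geno[(1, 0)]] == by_geno[(0, 0)]
        assert tree.parent[by_geno[(1, 1)]] == by_geno[(1, 0)]

    def test_parallel_loh_of_disease_assay(self):
        # two subclones independently driving the disease mutation homozygous
        tree = m.exhaustive_ml([(1, 0, 0), (2, 1, 0), (2, 0, 1)],
                               assays=["JAK2", "SERPINA1", "ARID2"])
        events = m.report_events(tree)
        assert events.loc["JAK2", "n_loh_homozygous"] == 2
        assert bool(events.loc["JAK2", "homoplasy"])

    def test_loh_reversion_to_wild_type(self):
        # a child sharing its parent's homozygous disease LOH but reverting a
        # passenger mutation: reversion beats re-deriving the shared events
        tree = m.exhaustive_ml(
            [((2, 1, 1, 0), 30), ((2, 0, 1, 1), 20)],
            assays=["CALR", "FGF1", "SUZ12", "NRAS"])
        events = m.report_events(tree)
        assert events["n_loh_reversion"].sum() >= 1

    def test_refuses_more_than_six_genotypes(self):
        genos = [tuple(1 if j <= i else 0 for j in range(7)) for i in range(7)]
        with pytest.raises(ValueError, match="refuses"):
            m.exhaustive_ml(genos)

    def test_root_constraint_respected(self):
        for seed in range(5):
            tree = m.simulate_clone_tree(4, 1, seed=seed)
            fitted = m.exhaustive_ml([(c.genotype, 10) for c in tree.clones][:5])
            root_geno = fitted.genotypes[0]
            assert sum(root_geno) <= 1 and all(c in (0, 1) for c in root_geno)


class TestHeuristic:
    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(7)
        for i in range(25):
            tree = m.simulate_clone_tree(int(rng.integers(3, 6)), int(rng.integers(0, 2)),
                                         seed=500 + i)
            subs = [(c.genotype, int(rng.integers(5, 50))) for c in tree.clones][:5]
            merged = {}
            for g, n in subs:
                merged[tuple(g)] = merged.get(tuple(g), 0) + n
            subs = list(merged.items())
            e = m.exhaustive_ml(subs)
            h = m.heuristic_ml_search(subs, n_restarts=20, seed=i)
            assert event_score(h) == pytest.approx(event_score(e))

    def test_two_genotypes_only_legal_tree(self):
        tree = m.heuristic_ml_search([(1, 0), (1, 1)])
        # (1,0) qualifies as the disease-only root; (1,1) is its child
        assert tree.genotypes == [(1, 0), (1, 1)]
        assert tree.parent == [None, 0]

    def test_deterministic_given_seed(self):
        subs = [((1, 0, 0), 40), ((1, 1, 0), 30), ((2, 1, 0), 10), ((1, 1, 1), 8)]
        a = m.heuristic_ml_search(subs, seed=3)
        b = m.heuristic_ml_search(subs, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_never_worse_than_star_or_chain(self):
        for seed in range(5):
            planted = m.simulate_clone_tree(6, 1, seed=seed)
            subs = [(c.genotype, 10 + i) for i, c in enumerate(planted.clones)]
            h = m.heuristic_ml_search(subs, seed=seed)
            # star baseline: every genotype hangs off the fitted root
            root_geno = h.genotypes[0]
            others = [g for g in h.genotypes[1:]]
            star_cost = 0.0
            model = ErrorModel()
            legal = True
            for g in others:
                for a, b in zip(root_geno, g):
                    path = event_path(a, b)
                    if path is None:
                        legal = False
                        break
                    star_cost += sum(model.weight(*s) for s in path)
            if legal:
                assert event_score(h) >= -star_cost - 1e-9


class TestNewick:
    def test_chain_format(self):
        tree = PhyloTree(assays=["A"], names=["root", "C1"], genotypes=[(0,), (1,)],
                         parent=[None, 0])
        assert m.to_newick(tree) == "(C1:1)root;"

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        planted = m.simulate_clone_tree(int(3 + seed % 4), seed % 2, seed=seed)
        subs = [(c.genotype, 10 + i) for i, c in enumerate(planted.clones)]
        tree = m.heuristic_ml_search(subs, seed=seed)
        back = m.from_newick(m.to_newick(tree))
        assert sorted(back.names) == sorted(tree.names)
        orig = {tree.names[i]: (tree.names[p] if p is not None else None,
                                float(tree.branch_length(i)) if p is not None else None)
                for i, p in enumerate(tree.parent)}
        parsed = {back.names[i]: (back.names[p] if p is not None else None,
                                  back.edge_lengths[i])
                  for i, p in enumerate(back.parent)}
        assert parsed == orig

    def test_sibling_order_stable(self):
        subs = [((1, 0, 0), 30), ((1, 1, 0), 20), ((1, 0, 1), 10)]
        assert m.to_newick(m.exhaustive_ml(subs)) == m.to_newick(m.exhaustive_ml(subs))


class TestEventReport:
    def test_linear_chain_no_homoplasy(self):
        tree = m.exhaustive_ml([(1, 0), (1, 1)])
        events = m.report_events(tree)
        assert not events["homoplasy"].any()
        assert events["n_events"].sum() == tree.total_events()

    def test_all_inferred_edges_legal(self):
        for seed in range(5):
            _, _, _, est = simulate_and_call(seed)
            for ev in est.tree_.all_events():
                assert (ev.from_code, ev.to_code) in {(0, 1), (1, 2), (1, 0)}


class TestTopologyRecovery:
    def test_planted_tree_recovered_with_ample_cells(self):
        hits = 0
        for seed in range(20):
            truth, _, _, est = simulate_and_call(seed)
            hits += topology_recovered(truth, est.tree_)
        assert hits >= 17


class TestEstimator:
    def test_sklearn_surface(self):
        est = m.FiniteSitesTreeML(n_restarts=5, random_state=1)
        params = est.get_params()
        assert params["n_restarts"] == 5
        est.set_params(n_restarts=10)
        est.fit([((1, 0), 30), ((1, 1), 10)])
        assert isinstance(est.tree_, PhyloTree)
        assert est.events_.shape[0] == 2
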