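"""The adjacency-evolution dynamic program and its backtracking."""

import math

import pytest

import adjscaff as A
from adjscaff.dp import AdjacencyDP, GAIN, ADJ_EXTANT, leaf_costs
from helpers import enum_class_min, random_small_classes, two_species_world


PARAMS = A.CostParameters()


def run_class(dataset, params=PARAMS, **kw):
    classes = A.partition(dataset.observed_adjacencies(), dataset.forest)
    assert len(classes) == 1
    dp = AdjacencyDP(classes[0], dataset.assemblies,
                     dataset.profiles(params), params, **kw)
    return dp


class TestLeafCosts:
    def test_observed_pair_is_free(self):
        asm = A.build_assembly("X", "ab", [("a", "b")], 1)
        prof = A.FragmentationProfile.from_assembly(asm, 1.0)
        assert leaf_costs("a", "b", asm, prof) == (0.0, math.inf)

    def test_ineligible_pair_is_forbidden(self):
        asm = A.build_assembly("X", "abcd",
                               [("a", "b"), ("b", "c"), ("c", "d")], 1)
        prof = A.FragmentationProfile.from_assembly(asm, 1.0)
        assert leaf_costs("a", "d", asm, prof) == (math.inf, 0.0)

    def test_probabilistic_pair(self):
        # P = 1/6, b = 5.25: c1 = -ln(1/6)/ln 5.25, c0 = -ln(5/6)/ln 5.25
        asm = A.build_assembly("X", "abcdef",
                               [("a", "b"), ("b", "c"), ("d", "e")], 1)
        prof = A.FragmentationProfile.from_assembly(asm, 1.0)
        c1, c0 = leaf_costs("a", "d", asm, prof)
        assert c1 == pytest.approx(-math.log(1 / 6) / math.log(5.25))
        assert c0 == pytest.approx(-math.log(5 / 6) / math.log(5.25))
        assert c1 == pytest.approx(1.0808, abs=5e-4)
        assert c0 == pytest.approx(0.1100, abs=5e-4)
        assert c1 < c0 + PARAMS.breakage  # the systematic-proposal condition


class TestCostTables:
    def test_singleton_observed_class_costs_one_gain(self):
        st = A.SpeciesTree.from_newick("(X,O)R;")
        from adjscaff.trees import lca_reconcile, parse_plain_gene_tree
        F = lca_reconcile(parse_plain_gene_tree("f_X;"), st, "F",
                          lambda g: g.split("_")[1])
        G = lca_reconcile(parse_plain_gene_tree("g_X;"), st, "G",
                          lambda g: g.split("_")[1])
        forest = A.GeneForest([F, G])
        asm = A.GenomeAssembly("X", ["f_X", "g_X"], [("f_X", "g_X")], 1)
        ds = A.Dataset(st, forest, {"X": asm})
        dp = run_class(ds)
        assert dp.total_cost() == pytest.approx(PARAMS.gain)

    def test_shared_ancestor_beats_two_gains(self):
        # adjacency in both sister species: one gain at the ancestor (3)
        # beats two independent leaf gains (6)
        ds, _ = two_species_world(observed_y=True)
        dp = run_class(ds)
        assert dp.total_cost() == pytest.approx(PARAMS.gain)
        c1_root = dp.cost(dp.acls.root_a, dp.acls.root_b, 1)
        assert c1_root == pytest.approx(0.0)

    def test_parent_inferred_adjacency_propagates_to_fragmented_leaf(self):
        # only X observed; Y fragmented with both genes free: the optimal
        # history keeps the adjacency at Z and proposes it in Y
        ds, (f_x, g_x, f_y, g_y) = two_species_world(fragment_y=True)
        dp = run_class(ds)
        hist = dp.backtrack()
        extant = {(a.name, b.name) for a, b in hist.extant_adjacencies()}
        assert (f_y, g_y) in extant or (g_y, f_y) in extant

    def test_deco_reduction_no_proposals_when_fully_assembled(self):
        # Y fully assembled without the adjacency: a single gain in the X
        # leaves (3) beats gain-at-ancestor plus a break in Y (4); no
        # proposal in Y either way
        ds, (f_x, g_x, f_y, g_y) = two_species_world(observed_y=False)
        dp = run_class(ds)
        hist = dp.backtrack()
        extant = {frozenset((a.name, b.name))
                  for a, b in hist.extant_adjacencies()}
        assert frozenset((f_y, g_y)) not in extant
        assert frozenset((f_x, g_x)) in extant
        assert dp.total_cost() == pytest.approx(PARAMS.gain)

    def test_matches_exhaustive_enumeration_on_random_classes(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(60):
            dp = AdjacencyDP(acls, ds.assemblies, profiles, params)
            assert dp.total_cost() == pytest.approx(enum_class_min(dp),
                                                    abs=1e-9)

    def test_adding_an_observed_adjacency_costs_at_most_gain(self):
        # singleton class: total 3; the two-species class with both
        # observed is still 3, with one observed it is 3 + small leaf cost
        ds_full, _ = two_species_world(observed_y=True)
        ds_frag, _ = two_species_world(fragment_y=True)
        full = run_class(ds_full).total_cost()
        frag = run_class(ds_frag).total_cost()
        assert full <= frag + PARAMS.gain

    def test_total_cost_finite_and_nonnegative(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(60):
            total = AdjacencyDP(acls, ds.assemblies, profiles,
                                params).total_cost()
            assert 0.0 <= total < math.inf

    def test_pairs_examined_is_quadratic_bounded(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(60):
            dp = AdjacencyDP(acls, ds.assemblies, profiles, params)
            dp.total_cost()
            size_a = sum(1 for _ in acls.root_a.walk())
            size_b = sum(1 for _ in acls.root_b.walk())
            assert dp.pairs_examined <= size_a * size_b

    def test_cross_species_pair_rejected(self):
        ds, _ = two_species_world()
        dp = run_class(ds)
        x_leaf = ds.forest.find("f_X")[1]
        y_leaf = ds.forest.find("g_Y")[1]
        with pytest.raises(RuntimeError, match="cross-species"):
            dp.derivations(x_leaf, y_leaf, 0)


class TestBacktrack:
    def test_singleton_history(self):
        st = A.SpeciesTree.from_newick("(X,O)R;")
        from adjscaff.trees import lca_reconcile, parse_plain_gene_tree
        F = lca_reconcile(parse_plain_gene_tree("f_X;"), st, "F",
                          lambda g: g.split("_")[1])
        G = lca_reconcile(parse_plain_gene_tree("g_X;"), st, "G",
                          lambda g: g.split("_")[1])
        forest = A.GeneForest([F, G])
        asm = A.GenomeAssembly("X", ["f_X", "g_X"], [("f_X", "g_X")], 1)
        ds = A.Dataset(st, forest, {"X": asm})
        hist = run_class(ds).backtrack()
        kinds = sorted(e[0] for e in hist.events)
        assert kinds == [ADJ_EXTANT, GAIN]

    def test_two_species_history(self):
        ds, _ = two_species_world(observed_y=True)
        hist = run_class(ds).backtrack()
        kinds = [e[0] for e in hist.events]
        assert kinds.count(GAIN) == 1
        assert kinds.count(ADJ_EXTANT) == 2
        assert hist.score == pytest.approx(PARAMS.gain)
        anc = hist.ancestral_adjacencies()
        assert len(anc) == 1 and anc[0].species == "Z"

    def test_backtrack_deterministic(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(20):
            dp = AdjacencyDP(acls, ds.assemblies, profiles, params)
            h1 = dp.backtrack()
            h2 = dp.backtrack()
            assert [(e.v1.name, e.v2.name, e.state) for e in h1.entries] == \
                [(e.v1.name, e.v2.name, e.state) for e in h2.entries]
            assert h1.events == h2.events

    def test_backtrack_score_matches_table(self):
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(40):
            dp = AdjacencyDP(acls, ds.assemblies, profiles, params)
            hist = dp.backtrack()
            assert hist.score == pytest.approx(dp.total_cost(), abs=1e-9)

    def test_observed_adjacencies_covered(self):
        # every observed adjacency of a class appears as a state-1 leaf
        # pair of the backtracked history
        params = A.CostParameters()
        for acls, ds, profiles in random_small_classes(40):
            dp = AdjacencyDP(acls, ds.assemblies, profiles, params)
            extant = {frozenset((a.name, b.name))
                      for a, b in dp.backtrack().extant_adjacencies()}
            for adj in acls.adjacencies:
                assert frozenset((adj.gene1, adj.gene2)) in extant


class TestPipeline:
    def test_fully_assembled_world_predicts_nothing(self):
        ds, _ = two_species_world(observed_y=True)
        res = A.run_pipeline(ds)
        assert res.predicted == []
        assert len(res.ancestral) == 1

    def test_empty_adjacency_input(self):
        ds, _ = two_species_world(observed_y=True)
        empty = {
            s: A.GenomeAssembly(s, a.genes, [], len(a.genes))
            for s, a in ds.assemblies.items()
        }
        res = A.run_pipeline(A.Dataset(ds.species_tree, ds.forest, empty))
        assert res.classes == [] and res.ancestral == [] \
            and res.predicted == []

    def test_output_sorted_and_deterministic(self):
        ds, _ = two_species_world(fragment_y=True)
        r1 = A.run_pipeline(ds, compute_supports="exact")
        r2 = A.run_pipeline(ds, compute_supports="exact")
        key = lambda adjs: [(a.species, a.key, a.support) for a in adjs]
        assert key(r1.ancestral) == key(r2.ancestral)
        assert key(r1.predicted) == key(r2.predicted)
        assert key(r1.ancestral) == sorted(key(r1.ancestral))
        assert key(r1.predicted) == sorted(key(r1.predicted))
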