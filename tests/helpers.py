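"""Shared independent oracles and fixture builders for the test suite."""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

import adjscaff as A
from adjscaff.io import dataset_from_ground_truth
from adjscaff.trees import DUP, EXTANT, LOSS, SPEC


# ---------------------------------------------------------------------------
# Scaffolding-count oracle: enumerate concrete solutions
# ---------------------------------------------------------------------------

def enumerate_scaffolding_solutions(n: int, p: int) -> int:
    """Count distinct extremity-adjacency sets joining n contigs into p
    linear chromosomes, by generating every arrangement and deduplicating.

    Contigs are labeled 1..n with extremities (i, 'L') and (i, 'R'); a
    chromosome is an ordered sequence of oriented contigs, identical when
    read in either direction; a solution is the set of adjacencies
    between consecutive contig extremities.
    """
    if p <= 0 or p > n:
        return 0
    contigs = list(range(1, n + 1))
    solutions = set()

    def chromosome_adjacencies(block_order, orientations):
        adjacencies = []
        for (c1, o1), (c2, o2) in zip(zip(block_order, orientations),
                                      zip(block_order[1:], orientations[1:])):
            left = (c1, "R" if o1 else "L")   # trailing extremity of c1
            right = (c2, "L" if o2 else "R")  # leading extremity of c2
            adjacencies.append(frozenset((left, right)))
        return adjacencies

    def partitions(items, k):
        if k == 1:
            yield [items]
            return
        first = items[0]
        for size in range(1, len(items) - k + 2):
            for rest in itertools.combinations(items[1:], size - 1):
                block = [first, *rest]
                remaining = [x for x in items[1:] if x not in rest]
                for more in partitions(remaining, k - 1):
                    yield [block, *more]

    for blocks in partitions(contigs, p):
        per_block_options = []
        for block in blocks:
            opts = []
            for perm in itertools.permutations(block):
                for bits in itertools.product((False, True), repeat=len(block)):
                    opts.append(frozenset(chromosome_adjacencies(perm, bits)))
            per_block_options.append(set(opts))
        for combo in itertools.product(*per_block_options):
            solutions.add(frozenset().union(*combo))
    return len(solutions)


# ---------------------------------------------------------------------------
# Reconciliation oracle: brute force over species mappings
# ---------------------------------------------------------------------------

def brute_force_reconciliation_cost(gene_root, species_tree) -> int:
    """Minimum duplications + losses over every valid node->species map.

    Leaves are fixed to their species; an internal node may map to any
    ancestor-or-equal of both child images.  Losses are counted from the
    species-path lengths of the edges (one per intermediate speciation,
    the parent species included when the parent is a duplication).
    """
    internal = [v for v in gene_root.walk() if v.children]
    best = math.inf
    for assignment in itertools.product(species_tree.nodes, repeat=len(internal)):
        smap = {id(v): sp for v, sp in zip(internal, assignment)}
        for v in gene_root.walk():
            if not v.children:
                smap[id(v)] = v.species
        ok = True
        cost = 0
        for v in internal:
            sv = smap[id(v)]
            child_imgs = [smap[id(c)] for c in v.children]
            if not all(A.SpeciesTree.is_ancestor_or_equal(sv, ci)
                       for ci in child_imgs):
                ok = False
                break
            is_dup = any(ci is sv for ci in child_imgs)
            if not is_dup:
                # a speciation separates its children into the two child
                # species; both mapping into one child subtree is invalid
                sides = set()
                for ci in child_imgs:
                    for k, sp_child in enumerate(sv.children):
                        if A.SpeciesTree.is_ancestor_or_equal(sp_child, ci):
                            sides.add(k)
                if len(sides) != 2:
                    ok = False
                    break
                cost += sum(ci.depth - sv.depth - 1 for ci in child_imgs)
            else:
                cost += 1 + sum(ci.depth - sv.depth for ci in child_imgs)
        if ok:
            best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# DP oracles: full expansion of the derivation grammar, no memoization
# ---------------------------------------------------------------------------

def enum_min_cost(dp, v1, v2, state) -> float:
    best = math.inf
    for d in dp.derivations(v1, v2, state):
        total = d.local
        for a, b, s in d.children:
            total += enum_min_cost(dp, a, b, s)
            if total == math.inf:
                break
        best = min(best, total)
    return best


def enum_class_min(dp) -> float:
    a, b = dp.acls.root_a, dp.acls.root_b
    return min(enum_min_cost(dp, a, b, 0),
               enum_min_cost(dp, a, b, 1) + dp.params.gain)


def enum_histories(dp, v1, v2, state):
    """All complete derivations below (v1, v2, state) in Boltzmann mode:
    list of (score, frozenset of state-1 pair names)."""
    out = []
    for d in dp.derivations(v1, v2, state):
        if d.local == math.inf:
            continue
        present = {(v1.name, v2.name)} if state == 1 else set()
        combos = [(d.local, frozenset(present))]
        for a, b, s in d.children:
            subs = enum_histories(dp, a, b, s)
            combos = [(c + sc, ps | qs) for c, ps in combos for sc, qs in subs]
            if not combos:
                break
        out.extend(combos)
    return out


def enum_class_histories(dp):
    """All histories of a class, with the root-gain charge applied."""
    a, b = dp.acls.root_a, dp.acls.root_b
    out = list(enum_histories(dp, a, b, 0))
    out += [(s + dp.params.gain, ps) for s, ps in enum_histories(dp, a, b, 1)]
    return out


# ---------------------------------------------------------------------------
# Random class fixtures (via the forward simulator)
# ---------------------------------------------------------------------------

def _extant_count(node) -> int:
    return sum(1 for x in node.walk() if x.event == EXTANT)


@lru_cache(maxsize=4)
def random_small_classes(n_classes: int, max_leaves: int = 3,
                         seed_base: int = 0):
    """Collect random adjacency classes with small subtrees.

    Simulates small 4-species worlds with elevated duplication/loss/
    breakage rates (to exercise the Dup and Loss DP cases), fragments one
    genome (to make leaf priors non-degenerate), and keeps classes whose
    root subtrees have at most ``max_leaves`` extant leaves each.
    Returns tuples (class, dataset, profiles).
    """
    params = A.CostParameters()
    out = []
    for seed in itertools.count(seed_base):
        gt = A.simulate(A.SimulationParams(
            n_species=4, root_genome_size=12, chromosomes=1,
            dup_rate=0.15, loss_rate=0.1, break_prob=0.1), seed=seed)
        ds = dataset_from_ground_truth(gt)
        rng = np.random.default_rng(seed)
        target = sorted(ds.assemblies)[0]
        frag, _ = A.fragment_fraction(ds.assemblies[target], 0.3, rng)
        assemblies = dict(ds.assemblies)
        assemblies[target] = frag
        ds = A.Dataset(ds.species_tree, ds.forest, assemblies)
        profiles = ds.profiles(params)
        for acls in A.partition(ds.observed_adjacencies(), ds.forest):
            if (_extant_count(acls.root_a) <= max_leaves
                    and _extant_count(acls.root_b) <= max_leaves):
                out.append((acls, ds, profiles))
        if len(out) >= n_classes:
            return tuple(out[:n_classes])


# ---------------------------------------------------------------------------
# Tiny hand-built worlds
# ---------------------------------------------------------------------------

def two_species_world(observed_y: bool = True, fragment_y: bool = False):
    """Two sister species X, Y (ancestor Z, outgroup O), unicopy families
    F and G; the F-G adjacency observed in X and optionally Y.

    Returns (dataset, names) where names = (f_x, g_x, f_y, g_y).
    """
    st = A.SpeciesTree.from_newick("((X,Y)Z,O)R;")
    sp = lambda g: g.split("_")[1]
    from adjscaff.trees import parse_plain_gene_tree, lca_reconcile
    F = lca_reconcile(parse_plain_gene_tree("(f_X,f_Y);"), st, "F", sp)
    G = lca_reconcile(parse_plain_gene_tree("(g_X,g_Y);"), st, "G", sp)
    forest = A.GeneForest([F, G])
    asm_x = A.GenomeAssembly("X", ["f_X", "g_X"], [("f_X", "g_X")], 1)
    if fragment_y:
        asm_y = A.GenomeAssembly("Y", ["f_Y", "g_Y"], [], 1)
    elif observed_y:
        asm_y = A.GenomeAssembly("Y", ["f_Y", "g_Y"], [("f_Y", "g_Y")], 1)
    else:
        asm_y = A.GenomeAssembly("Y", ["f_Y", "g_Y"], [], 2)
    dataset = A.Dataset(st, forest, {"X": asm_x, "Y": asm_y})
    return dataset, ("f_X", "g_X", "f_Y", "g_Y")
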