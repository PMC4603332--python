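"""Partition of observed extant adjacencies into independent classes.

Two observed adjacencies A1B1 and A2B2 may descend from one ancestral
adjacency AB only if (for some assignment of extremities to sides) A1 and
A2 share an ancestor A, B1 and B2 share an ancestor B, and A and B map to
the same (ancestral or extant) species.  This is an equivalence relation;
its classes are the units of the dynamic program.  Each class carries a
root pair (A, B): the most ancient pair of disjoint gene-tree nodes in a
common species that covers all of the class's extremities.  Lifting the
roots as high as the two species chains allow is what lets the DP
propagate an adjacency inferred in an ancestor down into fragmented
sister genomes where it was never observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome import Adjacency
from .trees import GeneNode, ReconciledGeneTree, SpeciesNode, SpeciesTree, InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Forest indexing
# ---------------------------------------------------------------------------

class GeneForest:
    """A collection of reconciled gene trees with a global leaf index."""

    def __init__(self, trees: Sequence[ReconciledGeneTree]):
        self.trees = list(trees)
        self.by_family = {t.family: t for t in self.trees}
        if len(self.by_family) != len(self.trees):
            raise InputError("duplicate family identifiers in the gene forest")
        self.leaf_index: dict[str, tuple[ReconciledGeneTree, GeneNode]] = {}
        for tree in self.trees:
            for gene, node in tree.leaf_by_gene.items():
                if gene in self.leaf_index:
                    raise InputError(f"gene {gene!r} occurs in more than one tree")
                self.leaf_index[gene] = (tree, node)

    def find(self, gene: str) -> tuple[ReconciledGeneTree, GeneNode]:
        try:
            return self.leaf_index[gene]
        except KeyError:
            raise InputError(f"gene {gene!r} not found in any gene tree") from None


# ---------------------------------------------------------------------------
# Lineage species chains
# ---------------------------------------------------------------------------

def _lineage_chain(node: GeneNode) -> dict[int, list[GeneNode]]:
    """Map id(species) -> nodes of that species on the root-ward path.

    Several nodes can map to one species when duplications occurred there;
    the list is ordered deepest first.
    """
    chain: dict[int, list[GeneNode]] = {}
    x: Optional[GeneNode] = node
    while x is not None:
        chain.setdefault(id(x.species), []).append(x)
        x = x.parent
    return chain


def _gene_lca(a: GeneNode, b: GeneNode) -> GeneNode:
    seen = set()
    x: Optional[GeneNode] = a
    while x is not None:
        seen.add(id(x))
        x = x.parent
    y: Optional[GeneNode] = b
    while y is not None:
        if id(y) in seen:
            return y
        y = y.parent
    raise InputError("gene nodes are not in the same tree")


def _is_gene_ancestor_or_equal(anc: GeneNode, desc: GeneNode) -> bool:
    x: Optional[GeneNode] = desc
    while x is not None:
        if x is anc:
            return True
        x = x.parent
    return False


def _common_species(n1: GeneNode, n2: GeneNode) -> list[SpeciesNode]:
    """Species present on both root-ward lineages, deepest first."""
    species1 = []
    seen1 = set()
    x: Optional[GeneNode] = n1
    while x is not None:
        if id(x.species) not in seen1:
            seen1.add(id(x.species))
            species1.append(x.species)
        x = x.parent
    seen2 = set()
    y: Optional[GeneNode] = n2
    while y is not None:
        seen2.add(id(y.species))
        y = y.parent
    return [sp for sp in species1 if id(sp) in seen2]


def sides_can_pair(a1: GeneNode, a2: GeneNode, b1: GeneNode, b2: GeneNode) -> bool:
    """Can ancestors A of {a1,a2} and B of {b1,b2} exist in one species?"""
    lca_a = _gene_lca(a1, a2)
    lca_b = _gene_lca(b1, b2)
    return bool(_common_species(lca_a, lca_b))


def equivalent(adj1: Adjacency, adj2: Adjacency, forest: GeneForest) -> bool:
    """True iff the two observed adjacencies may share an ancestral adjacency.

    Both extremity-to-side assignments of ``adj2`` relative to ``adj1``
    are tried; within one gene family a side must still be a coherent
    subtree, which :func:`partition` enforces when it builds classes.
    """
    t1a, a1 = forest.find(adj1.gene1)
    t1b, b1 = forest.find(adj1.gene2)
    t2a, a2 = forest.find(adj2.gene1)
    t2b, b2 = forest.find(adj2.gene2)
    fams1 = {t1a.family, t1b.family}
    fams2 = {t2a.family, t2b.family}
    if fams1 != fams2:
        return False
    for x2, y2, tx2, ty2 in ((a2, b2, t2a, t2b), (b2, a2, t2b, t2a)):
        if t1a.family != tx2.family or t1b.family != ty2.family:
            continue
        if sides_can_pair(a1, x2, b1, y2):
            return True
    return False


# ---------------------------------------------------------------------------
# Classes
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyClass:
    """One independent DP instance.

    ``root_a``/``root_b`` are disjoint gene-tree nodes in the same species
    whose subtrees contain, respectively, the A-side and B-side extremity
    of every class adjacency.
    """

    class_id: int
    family_a: str
    family_b: str
    root_a: GeneNode
    root_b: GeneNode
    adjacencies: list[Adjacency]
    #: per adjacency, (A-side leaf node, B-side leaf node)
    oriented_leaves: list[tuple[GeneNode, GeneNode]] = field(default_factory=list)

    @property
    def species(self) -> SpeciesNode:
        return self.root_a.species

    def describe(self) -> str:
        return (f"class {self.class_id}: families ({self.family_a}, {self.family_b}) "
                f"roots ({self.root_a.name}, {self.root_b.name}) "
                f"species {self.species.name} #adjacencies {len(self.adjacencies)}")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _node_sort_key(node: GeneNode) -> str:
    return node.name


def _orient(adj: Adjacency, forest: GeneForest, fam_a: str, fam_b: str,
            flip: bool) -> tuple[GeneNode, GeneNode]:
    _, x = forest.find(adj.gene1)
    _, y = forest.find(adj.gene2)
    return (y, x) if flip else (x, y)


def _root_pair(leaves_a: list[GeneNode], leaves_b: list[GeneNode],
               same_tree: bool) -> Optional[tuple[GeneNode, GeneNode]]:
    """Most ancient disjoint ancestor pair in a common species, or None."""
    lca_a = leaves_a[0]
    for leaf in leaves_a[1:]:
        lca_a = _gene_lca(lca_a, leaf)
    lca_b = leaves_b[0]
    for leaf in leaves_b[1:]:
        lca_b = _gene_lca(lca_b, leaf)
    chain_a = _lineage_chain(lca_a)
    chain_b = _lineage_chain(lca_b)
    common = _common_species(lca_a, lca_b)  # deepest first
    best: Optional[tuple[GeneNode, GeneNode]] = None
    for sp in common:  # walk toward the root, keep the last valid pair
        found = None
        # prefer the highest (most ancient) disjoint pair within this species
        for node_a in reversed(chain_a[id(sp)]):
            for node_b in reversed(chain_b[id(sp)]):
                if node_a is node_b:
                    continue
                if same_tree and (_is_gene_ancestor_or_equal(node_a, node_b)
                                  or _is_gene_ancestor_or_equal(node_b, node_a)):
                    continue
                found = (node_a, node_b)
                break
            if found:
                break
        if found is None:
            break
        best = found
    return best


def partition(adjacencies: Sequence[Adjacency], forest: GeneForest,
              ) -> list[AdjacencyClass]:
    """Group observed adjacencies into equivalence classes with root pairs.

    Classes are built per unordered family pair (union-find inside each
    group), then a root pair is computed per class.  Within a single
    family, extremity-to-side orientations are propagated by BFS; a class
    whose sides cannot be made disjoint (e.g. a tandem array sharing a
    leaf between sides) is split back into singleton classes with a
    warning.
    """
    groups: dict[tuple[str, str], list[Adjacency]] = {}
    for adj in sorted(adjacencies, key=lambda a: (a.species, a.key)):
        ta, _ = forest.find(adj.gene1)
        tb, _ = forest.find(adj.gene2)
        fam_pair = tuple(sorted((ta.family, tb.family)))
        groups.setdefault(fam_pair, []).append(adj)

    classes: list[AdjacencyClass] = []
    for (fam_a, fam_b), group in sorted(groups.items()):
        same_family = fam_a == fam_b
        uf = _UnionFind(len(group))
        # relative orientation constraints: edges (i, j, flip_ij)
        edges: list[tuple[int, int, bool]] = []
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if not same_family:
                    # orientation fixed by family: A side = fam_a
                    ti, _ = forest.find(group[i].gene1)
                    tj, _ = forest.find(group[j].gene1)
                    xi, yi = _orient(group[i], forest, fam_a, fam_b,
                                     ti.family != fam_a)
                    xj, yj = _orient(group[j], forest, fam_a, fam_b,
                                     tj.family != fam_a)
                    if sides_can_pair(xi, xj, yi, yj):
                        uf.union(i, j)
                    continue
                xi, yi = _orient(group[i], forest, fam_a, fam_b, False)
                for flip in (False, True):
                    xj, yj = _orient(group[j], forest, fam_a, fam_b, flip)
                    if sides_can_pair(xi, xj, yi, yj):
                        uf.union(i, j)
                        edges.append((i, j, flip))
                        break

        members: dict[int, list[int]] = {}
        for i in range(len(group)):
            members.setdefault(uf.find(i), []).append(i)

        for root_idx in sorted(members):
            idxs = members[root_idx]
            sub = [group[i] for i in idxs]
            oriented = _orient_class(sub, idxs, edges, forest, fam_a, fam_b,
                                     same_family)
            pair = _root_pair([a for a, _ in oriented], [b for _, b in oriented],
                              same_family)
            if pair is None:
                logger.warning(
                    "class over families (%s, %s) has no disjoint root pair; "
                    "splitting into %d singleton classes", fam_a, fam_b, len(sub)
                )
                for adj, (la, lb) in zip(sub, oriented):
                    spair = _root_pair([la], [lb], same_family)
                    if spair is None:  # pragma: no cover - leaves are distinct
                        logger.warning("dropping unplaceable adjacency %s", adj.key)
                        continue
                    classes.append(_make_class(len(classes), fam_a, fam_b,
                                               spair, [adj], [(la, lb)]))
                continue
            classes.append(_make_class(len(classes), fam_a, fam_b, pair,
                                       sub, oriented))
    return classes


def _make_class(class_id, fam_a, fam_b, pair, adjacencies, oriented):
    root_a, root_b = pair
    # deterministic side order: smaller root name first
    if _node_sort_key(root_b) < _node_sort_key(root_a):
        root_a, root_b = root_b, root_a
        oriented = [(b, a) for a, b in oriented]
        fam_a, fam_b = fam_b, fam_a
    cls = AdjacencyClass(class_id, fam_a, fam_b, root_a, root_b,
                         list(adjacencies), list(oriented))
    return cls


def _orient_class(sub: list[Adjacency], idxs: list[int],
                  edges: list[tuple[int, int, bool]], forest: GeneForest,
                  fam_a: str, fam_b: str, same_family: bool,
                  ) -> list[tuple[GeneNode, GeneNode]]:
    """Assign each adjacency's extremities to the A/B sides consistently."""
    if not same_family:
        oriented = []
        for adj in sub:
            ta, _ = forest.find(adj.gene1)
            oriented.append(_orient(adj, forest, fam_a, fam_b, ta.family != fam_a))
        return oriented
    # same family: propagate relative flips over the recorded equivalence edges
    pos = {g: k for k, g in enumerate(idxs)}
    flip = [None] * len(idxs)
    flip[0] = False
    adjacency_edges: dict[int, list[tuple[int, bool]]] = {}
    for i, j, fl in edges:
        if i in pos and j in pos:
            adjacency_edges.setdefault(pos[i], []).append((pos[j], fl))
            adjacency_edges.setdefault(pos[j], []).append((pos[i], fl))
    stack = [0]
    while stack:
        k = stack.pop()
        for m, fl in adjacency_edges.get(k, ()):
            want = flip[k] ^ fl
            if flip[m] is None:
                flip[m] = want
                stack.append(m)
            elif flip[m] != want:
                logger.warning("inconsistent side orientation in a same-family "
                               "class; keeping first assignment")
    return [
        _orient(adj, forest, fam_a, fam_b, bool(flip[k]) if flip[k] is not None else False)
        for k, adj in enumerate(sub)
    ]
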