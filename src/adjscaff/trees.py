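"""Species trees, gene trees and duplication/loss reconciliation.

A gene family history is represented as a rooted binary gene tree whose
nodes are mapped into a rooted binary species tree.  Each gene-tree node
carries the species it belongs to and an event label: ``Extant`` (a leaf
gene of a sequenced genome), ``Spec`` (a speciation), ``Dup`` (a gene
duplication) or ``Loss`` (a leaf marking the disappearance of a lineage).
The mapping is the classical LCA (lowest-common-ancestor) reconciliation,
which minimises the total number of duplications plus losses.

After reconciliation, trees are *loss-augmented*: intermediate speciation
nodes and explicit loss leaves are inserted so that every root-to-leaf
lineage visits every species on the corresponding species-tree path.  The
downstream adjacency dynamic program relies on this property: it pairs
gene-tree nodes per species and needs a node at every species a lineage
crosses.
"""

from __future__ import annotations

import io
import itertools
import re
from typing import Callable, Iterator, Optional

import dendropy

EXTANT = "Extant"
SPEC = "Spec"
DUP = "Dup"
LOSS = "Loss"


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesNode:
    __slots__ = ("name", "parent", "children", "depth", "index")

    def __init__(self, name: str):
        self.name = name
        self.parent: Optional[SpeciesNode] = None
        self.children: list[SpeciesNode] = []
        self.depth = 0          # root has depth 0
        self.index = -1         # postorder index

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesNode({self.name})"


class SpeciesTree:
    """Rooted binary species tree with O(depth) ancestor queries."""

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.nodes: list[SpeciesNode] = []
        self.by_name: dict[str, SpeciesNode] = {}
        self._index()

    def _index(self) -> None:
        seen: set[str] = set()
        order: list[SpeciesNode] = []

        def post(node: SpeciesNode, depth: int) -> None:
            node.depth = depth
            if len(node.children) not in (0, 2):
                raise InputError(
                    f"species tree node {node.name!r} has "
                    f"{len(node.children)} children; a rooted binary tree is required"
                )
            for child in node.children:
                child.parent = node
                post(child, depth + 1)
            if node.name in seen:
                raise InputError(f"duplicate species identifier {node.name!r}")
            seen.add(node.name)
            order.append(node)

        post(self.root, 0)
        for i, node in enumerate(order):
            node.index = i
        self.nodes = order
        self.by_name = {n.name: n for n in order}

    # -- queries ------------------------------------------------------------

    def leaves(self) -> list[SpeciesNode]:
        return [n for n in self.nodes if n.is_leaf]

    def node(self, name: str) -> SpeciesNode:
        try:
            return self.by_name[name]
        except KeyError:
            raise InputError(f"unknown species {name!r}") from None

    @staticmethod
    def is_ancestor_or_equal(anc: SpeciesNode, desc: SpeciesNode) -> bool:
        while desc is not None:
            if desc is anc:
                return True
            desc = desc.parent
        return False

    @staticmethod
    def lca(a: SpeciesNode, b: SpeciesNode) -> SpeciesNode:
        seen = set()
        x = a
        while x is not None:
            seen.add(id(x))
            x = x.parent
        y = b
        while y is not None:
            if id(y) in seen:
                return y
            y = y.parent
        raise InputError("species nodes are not in the same tree")

    @staticmethod
    def path_down(anc: SpeciesNode, desc: SpeciesNode) -> list[SpeciesNode]:
        """Species on the path from ``anc`` to ``desc``, both inclusive."""
        path = []
        x = desc
        while x is not anc:
            if x is None:
                raise InputError("path_down called with non-ancestor")
            path.append(x)
            x = x.parent
        path.append(anc)
        path.reverse()
        return path

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dtree = _parse_newick(newick)
        counter = itertools.count()

        def convert(dnode) -> SpeciesNode:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            else:
                name = f"anc{next(counter)}"
            node = SpeciesNode(name)
            for dchild in dnode.child_nodes():
                child = convert(dchild)
                child.parent = node
                node.children.append(child)
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def render(node: SpeciesNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.name}"

        return render(self.root) + ";"


def _parse_newick(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise InputError(f"malformed Newick: {exc}") from exc


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

class GeneNode:
    """Node of a (possibly reconciled) gene tree."""

    __slots__ = ("name", "parent", "children", "species", "event")

    def __init__(self, name: str = "", species: Optional[SpeciesNode] = None,
                 event: Optional[str] = None):
        self.name = name
        self.parent: Optional[GeneNode] = None
        self.children: list[GeneNode] = []
        self.species = species
        self.event = event

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "GeneNode") -> "GeneNode":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self) -> Iterator["GeneNode"]:
        """Postorder traversal."""
        for child in self.children:
            yield from child.walk()
        yield self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sp = self.species.name if self.species else "?"
        return f"GeneNode({self.name or '·'}, {self.event}, {sp})"


class ReconciledGeneTree:
    """A loss-augmented, fully event-labeled gene tree for one family."""

    def __init__(self, family: str, root: GeneNode):
        self.family = family
        self.root = root
        self.leaf_by_gene: dict[str, GeneNode] = {}
        self._validate_and_index()

    def _validate_and_index(self) -> None:
        for node in self.root.walk():
            if node.species is None or node.event is None:
                raise InputError("reconciled tree has unlabeled nodes")
            if node.event == LOSS and node.children:
                raise InputError("Loss node must be a leaf")
            if node.event == EXTANT:
                if node.children:
                    raise InputError("Extant node must be a leaf")
                self.leaf_by_gene[node.name] = node
            if node.event in (SPEC, DUP) and len(node.children) != 2:
                raise InputError(f"{node.event} node must have two children")
            if node.event == SPEC:
                want = {id(c) for c in node.species.children}
                got = {id(c.species) for c in node.children}
                if got != want:
                    raise InputError(
                        "speciation node children must map to the two child species"
                    )
            if node.event == DUP:
                for c in node.children:
                    if c.species is not node.species:
                        raise InputError(
                            "duplication node children must map to the same species"
                        )

    def extant_leaves(self) -> list[GeneNode]:
        return [n for n in self.root.walk() if n.event == EXTANT]

    def events(self) -> tuple[int, int]:
        return count_events(self)

    def to_newick(self) -> str:
        return serialize_nhx(self)


def count_events(tree: ReconciledGeneTree) -> tuple[int, int]:
    """Return (#duplications, #losses) of a reconciled tree."""
    dups = losses = 0
    for node in tree.root.walk():
        if node.event == DUP:
            dups += 1
        elif node.event == LOSS:
            losses += 1
    return dups, losses


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def lca_reconcile(
    gene_root: GeneNode,
    species_tree: SpeciesTree,
    family: str,
    species_of_leaf: Callable[[str], str],
) -> ReconciledGeneTree:
    """LCA-reconcile a plain rooted binary gene tree against the species tree.

    ``gene_root`` carries only leaf names; ``species_of_leaf`` maps a leaf
    gene identifier to a species-tree *leaf* name.  Internal nodes are
    mapped to the LCA of their children's images; a node is a duplication
    iff its image equals the image of one of its children (this mapping
    minimises duplications + losses).  The returned tree is loss-augmented
    and its ancestral nodes are named ``<family>|<postorder index>`` so
    runs are reproducible.
    """
    # map + label (postorder)
    def annotate(node: GeneNode) -> None:
        if node.is_leaf:
            sp_name = species_of_leaf(node.name)
            sp = species_tree.node(sp_name)
            if not sp.is_leaf:
                raise InputError(
                    f"gene {node.name!r} is assigned to non-extant species {sp_name!r}"
                )
            node.species = sp
            node.event = EXTANT
            return
        if len(node.children) != 2:
            raise InputError(
                f"gene tree of family {family!r} has a non-binary node "
                f"({len(node.children)} children)"
            )
        for child in node.children:
            annotate(child)
        left, right = node.children
        node.species = SpeciesTree.lca(left.species, right.species)
        if node.species is left.species or node.species is right.species:
            node.event = DUP
        else:
            node.event = SPEC

    annotate(gene_root)
    root = augment_losses(gene_root, species_tree)
    _name_ancestors(root, family)
    return ReconciledGeneTree(family, root)


def augment_losses(root: GeneNode, species_tree: SpeciesTree) -> GeneNode:
    """Insert intermediate speciation nodes and loss leaves.

    For an edge v -> c, the lineage must visit every species strictly
    between s(v) and s(c); at each, a speciation node is inserted whose
    off-path child is a loss.  A duplication's copies re-enter the
    speciation at s(v) itself, so when a copy maps below s(v) the chain
    starts at s(v).  Idempotent on already-augmented trees.
    """

    def augment_edge(parent: GeneNode, child: GeneNode) -> GeneNode:
        child = augment_node(child)
        # species at which intermediate speciations happen
        if parent.event == DUP:
            top = parent.species            # chain starts at s(v) itself
        else:
            top = None                      # chain starts strictly below s(v)
        path = SpeciesTree.path_down(
            parent.species if top is None else top, child.species
        )
        # intermediate species: exclude s(child); exclude s(parent) unless Dup
        inter = path[:-1] if parent.event == DUP else path[1:-1]
        if not inter:
            return child
        current = child
        for sp in reversed(inter):
            spec = GeneNode(species=sp, event=SPEC)
            on_path_child_sp = current.species
            # find the child species of sp on the path toward current
            for sp_child in sp.children:
                if SpeciesTree.is_ancestor_or_equal(sp_child, on_path_child_sp):
                    off = sp.children[1] if sp_child is sp.children[0] else sp.children[0]
                    break
            else:  # pragma: no cover - guaranteed by path construction
                raise InputError("inconsistent species path during loss augmentation")
            spec.add(current)
            spec.add(GeneNode(species=off, event=LOSS))
            _sort_spec_children(spec)
            current = spec
        return current

    def augment_node(node: GeneNode) -> GeneNode:
        if node.is_leaf:
            return node
        new_children = [augment_edge(node, c) for c in node.children]
        node.children = []
        for c in new_children:
            node.add(c)
        if node.event == SPEC:
            _sort_spec_children(node)
        return node

    return augment_node(root)


def _sort_spec_children(node: GeneNode) -> None:
    """Keep Spec children ordered as (left species, right species)."""
    left_sp = node.species.children[0]
    node.children.sort(
        key=lambda c: 0 if SpeciesTree.is_ancestor_or_equal(left_sp, c.species) else 1
    )


def _name_ancestors(root: GeneNode, family: str) -> None:
    for i, node in enumerate(root.walk()):
        if node.event != EXTANT:
            node.name = f"{family}|{i}"


# ---------------------------------------------------------------------------
# Serialization (NHX)
# ---------------------------------------------------------------------------

def serialize_nhx(tree: ReconciledGeneTree) -> str:
    """Write a reconciled tree as Newick with NHX species/event tags."""

    def render(node: GeneNode) -> str:
        tag = f"[&&NHX:S={node.species.name}:Ev={node.event}]"
        if node.is_leaf:
            return f"{node.name}{tag}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.name}{tag}"

    return render(tree.root) + ";"


_NHX_RE = re.compile(r"&&NHX:S=(?P<S>[^:\]]+):Ev=(?P<Ev>[^:\]]+)")


def parse_nhx(newick: str, species_tree: SpeciesTree, family: str) -> ReconciledGeneTree:
    """Parse a reconciled tree previously written by :func:`serialize_nhx`."""
    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        extract_comment_metadata=False,
    )

    def convert(dnode) -> GeneNode:
        name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        comments = " ".join(dnode.comments or [])
        m = _NHX_RE.search(comments)
        if not m:
            raise InputError(f"node {name!r} lacks an NHX S=/Ev= annotation")
        node = GeneNode(
            name=name,
            species=species_tree.node(m.group("S")),
            event=m.group("Ev"),
        )
        for dchild in dnode.child_nodes():
            node.add(convert(dchild))
        return node

    return ReconciledGeneTree(family, convert(dtree.seed_node))


def parse_plain_gene_tree(newick: str) -> GeneNode:
    """Parse an unannotated rooted gene tree; leaf names are gene ids.

    NHX comments, if present, are ignored: events are always recomputed by
    LCA reconciliation.
    """
    dtree = _parse_newick(newick)

    def convert(dnode) -> GeneNode:
        name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        node = GeneNode(name=name)
        for dchild in dnode.child_nodes():
            node.add(convert(dchild))
        return node

    return convert(dtree.seed_node)
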