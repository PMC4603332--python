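"""Forward simulator of genome evolution with ground truth.

Evolves a root genome (gene families arranged on linear chromosomes) down
a species tree under the same event vocabulary the reconstruction
assumes: gene duplication (tandem by default, with a translocation
probability), gene loss (neighbors rejoin), and adjacency rearrangement
(an adjacency breaks and two free chromosome ends rejoin, so extant
genomes stay disjoint paths with a fixed chromosome count).  The output
is exactly the input the pipeline consumes — species tree, plain gene
trees, gene-to-species map, adjacencies, chromosome counts — plus the
recorded ancestral gene orders.  A separate fragmentation step removes
random adjacencies from an assembled genome to emulate an incomplete
assembly, returning the removed set for recovery scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome import GenomeAssembly, adjacency_key, adjacencies_from_gene_order
from .trees import GeneNode, SpeciesNode, SpeciesTree, InputError


@dataclass(frozen=True)
class SimulationParams:
    """A stated evolutionary world.

    Defaults describe a small mammal-scale toy: 8 species, 200 families
    at the root on 2 chromosomes, and low per-branch event probabilities
    (2% duplication and loss per gene, 2% breakage per adjacency) so
    adjacency histories stay mostly conserved — the regime in which
    phylogenetic scaffolding is informative.
    """

    n_species: int = 8
    species_newick: Optional[str] = None
    root_genome_size: int = 200
    chromosomes: int = 2
    dup_rate: float = 0.02
    loss_rate: float = 0.02
    break_prob: float = 0.02
    translocation_prob: float = 0.2

    def __post_init__(self):
        if self.root_genome_size < self.chromosomes:
            raise InputError("root genome smaller than its chromosome count")
        for rate in (self.dup_rate, self.loss_rate, self.break_prob,
                     self.translocation_prob):
            if not 0.0 <= rate <= 1.0:
                raise InputError("rates must be probabilities in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the simulator knows about the generated history."""

    params: SimulationParams
    seed: int
    species_tree: SpeciesTree
    #: family id -> plain rooted gene tree (leaf names are gene ids)
    gene_trees: dict[str, GeneNode]
    gene_species: dict[str, str]
    #: extant species -> gene orders (one list per chromosome)
    genomes: dict[str, list[list[str]]]
    #: ancestral species -> gene orders over simulation lineage ids
    ancestral_orders: dict[str, list[list[str]]]
    event_counts: dict[str, int] = field(default_factory=dict)

    def extant_adjacencies(self, species: str) -> set[tuple[str, str]]:
        return adjacencies_from_gene_order(self.genomes[species], species)

    def assembly(self, species: str) -> GenomeAssembly:
        genes = [g for order in self.genomes[species] for g in order]
        return GenomeAssembly(species, genes,
                              self.extant_adjacencies(species),
                              len(self.genomes[species]))


# ---------------------------------------------------------------------------
# Species tree generation
# ---------------------------------------------------------------------------

def random_species_tree(n_species: int, rng: np.random.Generator) -> SpeciesTree:
    """Yule-style topology: split a uniformly chosen leaf until n leaves."""
    if n_species < 2:
        raise InputError("need at least 2 species")
    root = SpeciesNode("tmp")
    leaves = [root]
    while len(leaves) < n_species:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        left, right = SpeciesNode("tmp"), SpeciesNode("tmp")
        left.parent = right.parent = node
        node.children = [left, right]
        leaves.extend([node.children[0], node.children[1]])
    leaf_counter = itertools.count(1)
    anc_counter = itertools.count(1)

    def name(node: SpeciesNode) -> None:
        if not node.children:
            node.name = f"S{next(leaf_counter)}"
            return
        for child in node.children:
            name(child)
        node.name = f"A{next(anc_counter)}"

    name(root)
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class _Sim:
    def __init__(self, params: SimulationParams, seed: int):
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.serial = itertools.count()
        self.events = {"duplication": 0, "loss": 0, "breakage": 0, "join": 0}
        self.genomes: dict[str, list[list[str]]] = {}
        self.ancestral: dict[str, list[list[str]]] = {}
        self.gene_species: dict[str, str] = {}
        self.family_of: dict[int, str] = {}  # id(node) -> family

    def new_node(self, family: str) -> GeneNode:
        node = GeneNode(name=f"{family}.{next(self.serial)}")
        self.family_of[id(node)] = family
        return node

    def run(self) -> GroundTruth:
        p = self.params
        if p.species_newick is not None:
            stree = SpeciesTree.from_newick(p.species_newick)
        else:
            stree = random_species_tree(p.n_species, self.rng)
        families = [f"F{i:04d}" for i in range(p.root_genome_size)]
        roots = {fam: self.new_node(fam) for fam in families}
        # root genome: families distributed over p.chromosomes paths
        order = list(families)
        genome: list[list[GeneNode]] = []
        per = len(order) // p.chromosomes
        for c in range(p.chromosomes):
            chunk = order[c * per: (c + 1) * per if c < p.chromosomes - 1 else None]
            genome.append([roots[fam] for fam in chunk])
        self._recurse(stree.root, genome)
        gene_trees = {}
        for fam in families:
            pruned = _prune(roots[fam])
            if pruned is not None:
                gene_trees[fam] = pruned
        return GroundTruth(p, self.seed, stree, gene_trees, self.gene_species,
                           self.genomes, self.ancestral, dict(self.events))

    # -- branch evolution ---------------------------------------------------

    def _recurse(self, species: SpeciesNode, genome: list[list[GeneNode]]) -> None:
        if species.is_leaf:
            self._finalize(species, genome)
            return
        self.ancestral[species.name] = [[n.name for n in path] for path in genome]
        for child_sp in species.children:
            branch = []
            for path in genome:
                new_path = []
                for tip in path:
                    cont = self.new_node(self.family_of[id(tip)])
                    tip.add(cont)
                    new_path.append(cont)
                branch.append(new_path)
            self._evolve_branch(branch)
            self._recurse(child_sp, branch)

    def _evolve_branch(self, genome: list[list[GeneNode]]) -> None:
        p = self.params
        rng = self.rng
        # losses
        for path in genome:
            kept = []
            for tip in path:
                if rng.random() < p.loss_rate:
                    self.events["loss"] += 1
                else:
                    kept.append(tip)
            path[:] = kept
        genome[:] = [path for path in genome if path]
        # duplications
        for path in list(genome):
            i = 0
            while i < len(path):
                tip = path[i]
                if rng.random() < p.dup_rate:
                    self.events["duplication"] += 1
                    fam = self.family_of[id(tip)]
                    cont = self.new_node(fam)
                    copy = self.new_node(fam)
                    tip.add(cont)
                    tip.add(copy)
                    path[i] = cont
                    if rng.random() < p.translocation_prob:
                        target = genome[int(rng.integers(len(genome)))]
                        pos = int(rng.integers(len(target) + 1))
                        target.insert(pos, copy)
                        if target is path and pos <= i:
                            i += 1
                    else:
                        path.insert(i + 1, copy)
                        i += 1
                i += 1
        # rearrangements: break adjacencies, then rejoin to the target count
        target_paths = self.params.chromosomes
        pieces: list[list[GeneNode]] = []
        for path in genome:
            cuts = [j for j in range(len(path) - 1)
                    if rng.random() < p.break_prob]
            self.events["breakage"] += len(cuts)
            prev = 0
            for j in cuts:
                pieces.append(path[prev:j + 1])
                prev = j + 1
            pieces.append(path[prev:])
        pieces = [piece for piece in pieces if piece]
        if len(pieces) < target_paths:
            raise InputError(
                "simulation produced fewer gene paths than chromosomes; "
                "lower the loss rate or enlarge the root genome"
            )
        while len(pieces) > target_paths:
            i, j = rng.choice(len(pieces), size=2, replace=False)
            i, j = int(i), int(j)
            a = pieces.pop(max(i, j))
            b = pieces.pop(min(i, j))
            if rng.random() < 0.5:
                a.reverse()
            if rng.random() < 0.5:
                b.reverse()
            pieces.append(b + a)
            self.events["join"] += 1
        genome[:] = pieces

    def _finalize(self, species: SpeciesNode, genome: list[list[GeneNode]]) -> None:
        per_family: dict[str, int] = {}
        orders = []
        for path in genome:
            row = []
            for tip in path:
                fam = self.family_of[id(tip)]
                k = per_family.get(fam, 0)
                per_family[fam] = k + 1
                name = f"{fam}_{species.name}" + (f"_{k}" if k else "")
                tip.name = name
                tip.children = []  # extant: terminal
                self.gene_species[name] = species.name
                row.append(name)
            orders.append(row)
        self.genomes[species.name] = orders


def _prune(node: GeneNode) -> Optional[GeneNode]:
    """Keep only lineages with extant descendants; splice unary nodes."""
    if not node.children:
        # extant tips were renamed in _finalize; internal dead tips were not
        is_extant = "." not in node.name
        if is_extant:
            return GeneNode(name=node.name)
        return None
    kept = [_prune(c) for c in node.children]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    out = GeneNode(name="")
    for c in kept:
        out.add(c)
    return out


def simulate(params: SimulationParams = SimulationParams(),
             seed: int = 0) -> GroundTruth:
    """Run one forward simulation; bit-reproducible for a fixed seed."""
    return _Sim(params, seed).run()


# ---------------------------------------------------------------------------
# Fragmentation ("fission" protocol)
# ---------------------------------------------------------------------------

def default_fragmentation_target(species_tree: SpeciesTree) -> str:
    """A species whose removed adjacencies are recoverable: a cherry leaf.

    A rooted parsimony method cannot scaffold an outgroup — an adjacency
    absent from a basal species is more parsimoniously gained once in the
    ingroup ancestor than broken in the outgroup — so fission experiments
    target a leaf whose sister is also a leaf.  Deterministic: the
    lexicographically first such leaf.
    """
    leaves = sorted(species_tree.leaves(), key=lambda n: n.name)
    for leaf in leaves:
        sibling = [c for c in leaf.parent.children if c is not leaf][0]
        if sibling.is_leaf:
            return leaf.name
    return leaves[0].name

def fragment_assembly(assembly: GenomeAssembly, k: int,
                      rng: np.random.Generator,
                      ) -> tuple[GenomeAssembly, set[tuple[str, str]]]:
    """Remove ``k`` uniformly chosen adjacencies from an assembly.

    Returns the fragmented assembly and the removed adjacency set.  Gene
    content is untouched; for a path-shaped input the contig count grows
    by exactly ``k``.
    """
    adjacencies = sorted(assembly.adjacencies)
    if k < 0 or k > len(adjacencies):
        raise InputError(
            f"cannot remove {k} of {len(adjacencies)} adjacencies")
    idx = rng.choice(len(adjacencies), size=k, replace=False) if k else []
    removed = {adjacencies[int(i)] for i in idx}
    fragmented = GenomeAssembly(assembly.species, assembly.genes,
                                assembly.adjacencies - removed, assembly.p)
    return fragmented, removed


def fragment_fraction(assembly: GenomeAssembly, fraction: float,
                      rng: np.random.Generator,
                      ) -> tuple[GenomeAssembly, set[tuple[str, str]]]:
    """Fraction-based variant: removes ceil(fraction * #adjacencies)."""
    if not 0.0 <= fraction <= 1.0:
        raise InputError("fraction must be in [0, 1]")
    k = int(np.ceil(fraction * len(assembly.adjacencies)))
    return fragment_assembly(assembly, k, rng)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export(gt: GroundTruth, outdir) -> dict[str, Path]:
    """Write the simulated dataset in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species_tree": outdir / "species.nwk",
        "gene_trees": outdir / "gene_trees.tsv",
        "gene_map": outdir / "gene_map.tsv",
        "adjacencies": outdir / "adjacencies.tsv",
        "chromosome_counts": outdir / "chromosome_counts.tsv",
    }
    paths["species_tree"].write_text(gt.species_tree.to_newick() + "\n")
    with paths["gene_trees"].open("w") as fh:
        for fam in sorted(gt.gene_trees):
            fh.write(f"{fam}\t{_plain_newick(gt.gene_trees[fam])};\n")
    with paths["gene_map"].open("w") as fh:
        for gene in sorted(gt.gene_species):
            fh.write(f"{gene}\t{gt.gene_species[gene]}\n")
    with paths["adjacencies"].open("w") as fh:
        for species in sorted(gt.genomes):
            for g1, g2 in sorted(gt.extant_adjacencies(species)):
                fh.write(f"{species}\t{g1}\t{g2}\n")
    with paths["chromosome_counts"].open("w") as fh:
        for species in sorted(gt.genomes):
            fh.write(f"{species}\t{len(gt.genomes[species])}\n")
    return paths


def _plain_newick(node: GeneNode) -> str:
    if not node.children:
        return node.name
    return "(" + ",".join(_plain_newick(c) for c in node.children) + ")"
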