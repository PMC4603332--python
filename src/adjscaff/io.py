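"""Input loading, cross-validation and output writing.

All formats are plain text: Newick for trees, TSV for the gene-to-species
map (columns gene, species), observed adjacencies (species, gene1,
gene2), chromosome counts (species, count) and gene orders (species, then
a comma-separated gene list per contig).  Gene trees live in a TSV of
``family<TAB>newick``; a file of bare Newick strings (one per line) is
also accepted, with families auto-named G0, G1, ...
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

from . import __version__
from .classes import GeneForest
from .dp import CostParameters
from .genome import Adjacency, GenomeAssembly, adjacency_key
from .pipeline import Dataset, RunResult
from .simulate import GroundTruth
from .trees import (GeneNode, InputError, ReconciledGeneTree, SpeciesTree,
                    lca_reconcile, parse_plain_gene_tree)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_species_tree(path) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text())


def read_gene_trees(path) -> dict[str, GeneNode]:
    """family -> plain gene tree; accepts ``family\\tnewick`` or bare Newick."""
    trees: dict[str, GeneNode] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            family, newick = line.split("\t", 1)
        else:
            family, newick = f"G{i}", line
        if family in trees:
            raise InputError(f"{path}: duplicate family {family!r} (line {i + 1})")
        try:
            trees[family] = parse_plain_gene_tree(newick)
        except InputError as exc:
            raise InputError(f"{path} line {i + 1}: {exc}") from exc
    return trees


def _read_tsv(path, n_cols: int, what: str) -> list[list[str]]:
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise InputError(
                f"{path} line {i + 1}: expected {n_cols} columns for {what}, "
                f"got {len(parts)}")
        rows.append(parts)
    return rows


def read_gene_map(path) -> dict[str, str]:
    mapping = {}
    for gene, species in _read_tsv(path, 2, "gene map"):
        if gene in mapping and mapping[gene] != species:
            raise InputError(f"gene {gene!r} mapped to two species")
        mapping[gene] = species
    return mapping


def read_adjacencies(path) -> list[tuple[str, str, str]]:
    return [(sp, g1, g2) for sp, g1, g2 in _read_tsv(path, 3, "adjacencies")]


def read_chromosome_counts(path) -> dict[str, int]:
    counts = {}
    for species, value in _read_tsv(path, 2, "chromosome counts"):
        try:
            counts[species] = int(value)
        except ValueError:
            raise InputError(f"bad chromosome count {value!r} for {species}") from None
    return counts


def read_gene_orders(path) -> dict[str, list[list[str]]]:
    """species -> list of contigs, each a comma-separated gene list."""
    orders: dict[str, list[list[str]]] = {}
    for species, genes in _read_tsv(path, 2, "gene orders"):
        orders.setdefault(species, []).append(
            [g for g in genes.split(",") if g])
    return orders


def species_from_gene_name(gene: str) -> str:
    """'SPECIES_GENE' prefix rule: species = text before the first '_'."""
    if "_" not in gene:
        raise InputError(f"gene {gene!r} does not follow the SPECIES_GENE rule")
    return gene.split("_", 1)[0]


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(species_tree: SpeciesTree,
                  gene_trees: dict[str, GeneNode],
                  gene_species: dict[str, str],
                  adjacencies: Iterable[tuple[str, str, str]],
                  chromosome_counts: dict[str, int]) -> Dataset:
    """Reconcile, cross-validate, and assemble a runnable dataset.

    Adjacencies naming genes absent from every gene tree are excluded
    with a warning; a species hosting genes but lacking a chromosome
    count is an error.
    """
    reconciled = []
    for family in sorted(gene_trees):
        def lookup(gene: str, _family=family) -> str:
            try:
                return gene_species[gene]
            except KeyError:
                raise InputError(
                    f"gene {gene!r} of family {_family!r} missing from the "
                    "gene-to-species map") from None
        reconciled.append(
            lca_reconcile(gene_trees[family], species_tree, family, lookup))
    forest = GeneForest(reconciled)

    genes_by_species: dict[str, set[str]] = {}
    for gene in forest.leaf_index:
        genes_by_species.setdefault(gene_species[gene], set()).add(gene)

    adj_by_species: dict[str, set[tuple[str, str]]] = {}
    for species, g1, g2 in adjacencies:
        if g1 not in forest.leaf_index or g2 not in forest.leaf_index:
            logger.warning("adjacency %s-%s in %s names a gene absent from "
                           "the gene trees; excluded", g1, g2, species)
            continue
        for g in (g1, g2):
            if gene_species.get(g) != species:
                raise InputError(
                    f"adjacency {g1}-{g2}: gene {g!r} is not in species {species!r}")
        adj_by_species.setdefault(species, set()).add(adjacency_key(g1, g2))

    assemblies = {}
    for species, genes in sorted(genes_by_species.items()):
        node = species_tree.node(species)
        if not node.is_leaf:
            raise InputError(f"genes assigned to ancestral species {species!r}")
        if species not in chromosome_counts:
            raise InputError(f"missing chromosome count for species {species!r}")
        assembly = GenomeAssembly(species, genes,
                                  adj_by_species.get(species, set()),
                                  chromosome_counts[species])
        if assembly.fully_assembled:
            logger.info("species %s is fully assembled (n = p = %d): no new "
                        "adjacencies will be proposed", species, assembly.n)
        assemblies[species] = assembly
    return Dataset(species_tree, forest, assemblies)


def load_input(species_tree_path, gene_trees_path, gene_map_path,
               adjacencies_path, chromosome_counts_path,
               use_prefix_rule: bool = False) -> Dataset:
    """Load and cross-validate a dataset from the five input files."""
    species_tree = read_species_tree(species_tree_path)
    gene_trees = read_gene_trees(gene_trees_path)
    if use_prefix_rule:
        gene_species = {}
        for family, root in gene_trees.items():
            for node in root.walk():
                if node.is_leaf:
                    gene_species[node.name] = species_from_gene_name(node.name)
    else:
        gene_species = read_gene_map(gene_map_path)
    adjacencies = read_adjacencies(adjacencies_path)
    counts = read_chromosome_counts(chromosome_counts_path)
    dataset = build_dataset(species_tree, gene_trees, gene_species,
                            adjacencies, counts)
    for species, asm in sorted(dataset.assemblies.items()):
        logger.info("loaded %s: %d genes, %d adjacencies, n=%d contigs, p=%d",
                    species, len(asm.genes), len(asm.adjacencies), asm.n, asm.p)
    return dataset


def dataset_from_ground_truth(gt: GroundTruth) -> Dataset:
    """Build a runnable dataset directly from a simulation."""
    species_tree = SpeciesTree.from_newick(gt.species_tree.to_newick())
    adjacencies = [(sp, g1, g2) for sp in sorted(gt.genomes)
                   for g1, g2 in sorted(gt.extant_adjacencies(sp))]
    counts = {sp: len(orders) for sp, orders in gt.genomes.items()}
    return build_dataset(species_tree, gt.gene_trees, gt.gene_species,
                         adjacencies, counts)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_adjacencies(result: RunResult, path, seed: Optional[int] = None) -> None:
    """Output TSV: species/ancestor, gene1, gene2, origin, class id, support."""
    p = result.params
    by_key = {}
    for hist in result.histories:
        for v1, v2 in hist.present_pairs():
            by_key[(v1.name, v2.name)] = hist.class_id
            by_key[(v2.name, v1.name)] = hist.class_id
    with Path(path).open("w") as fh:
        fh.write(f"# adjscaff {__version__} gain={p.gain} br={p.breakage} "
                 f"multiplier={p.base_multiplier} kT={p.kT} seed={seed}\n")
        fh.write("# species\tgene1\tgene2\torigin\tclass\tsupport\n")
        for adj in result.ancestral + result.predicted:
            cls = by_key.get((adj.gene1, adj.gene2), "")
            support = "" if adj.support is None else f"{adj.support:.6f}"
            fh.write(f"{adj.species}\t{adj.gene1}\t{adj.gene2}\t{adj.origin}"
                     f"\t{cls}\t{support}\n")


def write_class_dump(classes, path) -> None:
    """Debug dump: one line per adjacency class."""
    with Path(path).open("w") as fh:
        for acls in classes:
            fh.write(acls.describe() + "\n")
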