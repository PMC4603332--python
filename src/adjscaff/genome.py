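"""Extant genomes as gene sets plus observed adjacencies.

A genome assembly is modeled purely combinatorially: a set of genes and a
set of unordered neighbor relations (adjacencies) between them.  Contigs
are the connected components of the adjacency graph; ideally each is a
simple path.  ``n`` denotes the contig count and ``p`` the (expected)
chromosome count of the species; scaffolding asks for the n - p joins that
turn the contigs into p linear chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .trees import InputError

logger = logging.getLogger(__name__)

OBSERVED = "observed"
PREDICTED = "predicted"
ANCESTRAL = "ancestral"


def adjacency_key(g1: str, g2: str) -> tuple[str, str]:
    """Canonical unordered representation of a gene pair."""
    return (g1, g2) if g1 <= g2 else (g2, g1)


@dataclass(frozen=True)
class Adjacency:
    """Unordered neighbor relation between two genes of one species."""

    gene1: str
    gene2: str
    species: str
    origin: str = OBSERVED
    support: Optional[float] = None

    def __post_init__(self):
        if self.gene1 == self.gene2:
            raise InputError(f"self-adjacency on gene {self.gene1!r}")
        if self.gene1 > self.gene2:
            g1, g2 = self.gene2, self.gene1
            object.__setattr__(self, "gene1", g1)
            object.__setattr__(self, "gene2", g2)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


class GenomeAssembly:
    """Genes + observed adjacencies of one extant species.

    Derived quantities (contigs, degrees, free ends) are computed once at
    construction from the observed adjacency graph; predicted adjacencies
    never feed back into them.
    """

    def __init__(self, species: str, genes: Iterable[str],
                 adjacencies: Iterable[tuple[str, str]], p: int):
        if p < 1:
            raise InputError(f"species {species!r}: chromosome count must be >= 1")
        self.species = species
        self.genes = set(genes)
        self.adjacencies: set[tuple[str, str]] = set()
        graph = nx.Graph()
        graph.add_nodes_from(self.genes)
        for g1, g2 in adjacencies:
            if g1 not in self.genes or g2 not in self.genes:
                raise InputError(
                    f"species {species!r}: adjacency {g1}-{g2} references unknown gene"
                )
            self.adjacencies.add(adjacency_key(g1, g2))
        graph.add_edges_from(self.adjacencies)
        self.graph = graph
        self.contigs: list[frozenset[str]] = [
            frozenset(c) for c in nx.connected_components(graph)
        ]
        self.contigs.sort(key=lambda c: min(c))
        self.n = len(self.contigs)
        self.p = p
        if self.genes and self.n < p:
            raise InputError(
                f"species {species!r}: {self.n} contigs but {p} chromosomes expected"
            )
        self._contig_of = {g: i for i, c in enumerate(self.contigs) for g in c}
        self.degree = {g: graph.degree(g) for g in self.genes}
        if any(d > 2 for d in self.degree.values()) or self._has_cycle():
            logger.warning(
                "species %s: observed adjacency graph is not a disjoint union "
                "of paths; contigs are still its connected components", species
            )

    def _has_cycle(self) -> bool:
        return len(self.adjacencies) > len(self.genes) - self.n

    # -- queries ------------------------------------------------------------

    def is_free_end(self, gene: str) -> bool:
        return self.degree[gene] <= 1

    def contig_index(self, gene: str) -> int:
        return self._contig_of[gene]

    def contig_of(self, gene: str) -> frozenset[str]:
        return self.contigs[self._contig_of[gene]]

    def same_contig(self, g1: str, g2: str) -> bool:
        return self._contig_of[g1] == self._contig_of[g2]

    def is_observed(self, g1: str, g2: str) -> bool:
        return adjacency_key(g1, g2) in self.adjacencies

    @property
    def fully_assembled(self) -> bool:
        return self.n == self.p

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GenomeAssembly({self.species}, genes={len(self.genes)}, "
                f"adjacencies={len(self.adjacencies)}, n={self.n}, p={self.p})")


def adjacencies_from_gene_order(orders: Iterable[list[str]],
                                species: str = "") -> set[tuple[str, str]]:
    """Adjacency set from ordered gene lists (one list per contig/chromosome).

    A list of length L yields L - 1 adjacencies; every gene must occur in
    exactly one list.
    """
    seen: set[str] = set()
    adjacencies: set[tuple[str, str]] = set()
    for order in orders:
        for gene in order:
            if gene in seen:
                raise InputError(
                    f"gene {gene!r} appears more than once in the gene order"
                    + (f" of {species}" if species else "")
                )
            seen.add(gene)
        for g1, g2 in zip(order, order[1:]):
            adjacencies.add(adjacency_key(g1, g2))
    return adjacencies


def build_assembly(species: str, genes: Iterable[str],
                   adjacencies: Iterable[tuple[str, str]], p: int) -> GenomeAssembly:
    """Construct a :class:`GenomeAssembly` (thin validated constructor)."""
    return GenomeAssembly(species, genes, adjacencies, p)
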