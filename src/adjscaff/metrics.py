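"""Assembly and prediction quality statistics.

Implements the fission-experiment recovery rates (TP / FP over removed
adjacencies), the degree of non-linearity of contig graphs, the
scaffolding improvement percentage, and gene neighborhood (degree /
support-weighted) distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dp import CostParameters
from .genome import Adjacency, GenomeAssembly, adjacency_key
from .pipeline import Dataset, run_pipeline
from .trees import InputError

AdjKey = tuple[str, str, str]  # (species, gene1, gene2) canonical


def _normalize(adjacencies: Iterable) -> set[AdjKey]:
    out = set()
    for adj in adjacencies:
        if isinstance(adj, Adjacency):
            out.add((adj.species, adj.gene1, adj.gene2))
        else:
            species, g1, g2 = adj
            out.add((species, *adjacency_key(g1, g2)))
    return out


# ---------------------------------------------------------------------------
# Recovery (fission experiments)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryStats:
    """TP/FP accounting of a fission experiment.

    ``k_removed`` is the number of adjacencies removed from the input
    (the experiment's break count); rates follow the convention
    TP/(k + FP) and FP/(k + FP).
    """

    k_removed: int
    tp: int
    fp: int

    @property
    def true_positive_rate(self) -> float:
        denom = self.k_removed + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def false_positive_rate(self) -> float:
        denom = self.k_removed + self.fp
        return self.fp / denom if denom else 0.0

    @property
    def precision(self) -> float:
        """TP / #predicted (1.0 for an empty prediction set)."""
        total = self.tp + self.fp
        return self.tp / total if total else 1.0


def recovery_stats(removed: Iterable, predicted: Iterable) -> RecoveryStats:
    removed_set = _normalize(removed)
    predicted_set = _normalize(predicted)
    tp = len(removed_set & predicted_set)
    fp = len(predicted_set - removed_set)
    return RecoveryStats(len(removed_set), tp, fp)


# ---------------------------------------------------------------------------
# Non-linearity
# ---------------------------------------------------------------------------

def degree_of_nonlinearity(contig: nx.Graph) -> float:
    """Excess branching of one connected contig graph.

    D_nl = sum over genes of degree > 2 of (degree - 2), plus (m - 2)
    where m is the number of degree-1 genes.  A simple path scores 0; a
    cycle would score -2 by the raw formula and is clamped to 0 (and is
    detected separately by :func:`nonlinearity_stats`).  A single-gene
    contig scores 0.
    """
    if contig.number_of_nodes() <= 1:
        return 0.0
    degrees = [d for _, d in contig.degree()]
    excess = sum(d - 2 for d in degrees if d > 2)
    m = sum(1 for d in degrees if d == 1)
    return float(max(excess + (m - 2), 0))


def is_linear(contig: nx.Graph) -> bool:
    """True iff the contig is a simple path (or a single gene)."""
    if contig.number_of_nodes() <= 1:
        return True
    degrees = [d for _, d in contig.degree()]
    return max(degrees) <= 2 and sum(1 for d in degrees if d == 1) == 2


@dataclass(frozen=True)
class NonLinearityStats:
    species: str
    n_contigs: int
    n_linear: int
    n_cyclic: int
    mean_dnl_nonlinear: Optional[float]  # None if all contigs are linear

    @property
    def linear_fraction(self) -> float:
        return self.n_linear / self.n_contigs if self.n_contigs else 1.0


def nonlinearity_stats(species: str, graph: nx.Graph) -> NonLinearityStats:
    """Per-species linearity summary over the contigs of ``graph``."""
    n_contigs = n_linear = n_cyclic = 0
    dnls = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        n_contigs += 1
        if is_linear(sub):
            n_linear += 1
            continue
        if sub.number_of_edges() >= sub.number_of_nodes():
            n_cyclic += 1
        dnls.append(degree_of_nonlinearity(sub))
    mean = float(np.mean(dnls)) if dnls else None
    return NonLinearityStats(species, n_contigs, n_linear, n_cyclic, mean)


# ---------------------------------------------------------------------------
# Improvement
# ---------------------------------------------------------------------------

def improvement_percentage(c_initial: int, c_new: int, p: int) -> float:
    """(C_I - C_N) / (C_I - p): 0 = no improvement, 1 = fully scaffolded.

    Only defined for genomes that are not completely assembled (C_I > p).
    """
    if c_initial <= p:
        raise InputError(
            "improvement undefined for a completely assembled genome (C_I <= p)"
        )
    return (c_initial - c_new) / (c_initial - p)


# ---------------------------------------------------------------------------
# Neighborhood distributions
# ---------------------------------------------------------------------------

def neighbor_distribution(graph: nx.Graph) -> dict[int, int]:
    """Counts of genes by number of syntenic neighbors (degree)."""
    counts: dict[int, int] = {}
    for _, d in graph.degree():
        counts[d] = counts.get(d, 0) + 1
    return dict(sorted(counts.items()))


def weighted_neighbor_distribution(
        genes: Iterable[str],
        adjacencies: Iterable[tuple[str, str, float]],
        bins: Sequence[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-gene summed adjacency supports.

    The neighborhood weight of a gene is the sum of the supports of all
    adjacencies involving it.  Returns (counts, bin_edges) as from
    ``numpy.histogram``; default bins are width 0.25 from 0 to the
    ceiling of the maximum weight (so integer peaks stay visible).
    """
    weight = {g: 0.0 for g in genes}
    for g1, g2, s in adjacencies:
        weight[g1] += s
        weight[g2] += s
    values = np.array(sorted(weight.values()), dtype=float)
    if bins is None:
        # extend past the maximum so integer peaks land in their own bin
        top = max(1.0, float(np.ceil(values.max()))) if len(values) else 1.0
        bins = np.arange(0.0, top + 0.5, 0.25)
    counts, edges = np.histogram(values, bins=bins)
    return counts, edges


# ---------------------------------------------------------------------------
# Log-base sweep (phase-change experiment)
# ---------------------------------------------------------------------------

def base_sweep(dataset: Dataset,
               multipliers: Sequence[float],
               k_removed: int,
               replicates: int,
               seed: int,
               params: CostParameters = CostParameters(),
               species: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Fission-and-recover experiment across log-base multipliers.

    For each replicate, ``k_removed`` random adjacencies are removed from
    each targeted genome (default: every fragmentable species); the
    pipeline is rerun per multiplier and the number of removed
    adjacencies recovered is reported.  Expected shape: near-zero
    recovery below multiplier 1.0 (the phase-change threshold), a plateau
    above it.
    """
    from .simulate import fragment_assembly  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    if species is None:
        species = sorted(dataset.assemblies)
    rows = []
    for rep in range(replicates):
        removed: set[AdjKey] = set()
        assemblies = {}
        for name, asm in dataset.assemblies.items():
            if name in species and len(asm.adjacencies) >= k_removed > 0:
                frag, rem = fragment_assembly(asm, k_removed, rng)
                assemblies[name] = frag
                removed |= {(name, *key) for key in rem}
            else:
                assemblies[name] = asm
        frag_dataset = Dataset(dataset.species_tree, dataset.forest, assemblies)
        for mult in multipliers:
            run = run_pipeline(frag_dataset,
                               replace(params, base_multiplier=mult))
            stats = recovery_stats(removed, run.predicted)
            rows.append({"multiplier": mult, "replicate": rep,
                         "k_removed": len(removed), "recovered": stats.tp,
                         "false_positives": stats.fp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-species report
# ---------------------------------------------------------------------------

def species_report(dataset: Dataset, result) -> pd.DataFrame:
    """Per-species metrics table (n, p, p(S), b, C_I, C_N, improvement...)."""
    profiles = dataset.profiles(result.params)
    rows = []
    for name in sorted(dataset.assemblies):
        asm = dataset.assemblies[name]
        prof = profiles[name]
        scaffolded = result.scaffolded_assembly(asm)
        stats = nonlinearity_stats(name, scaffolded.graph)
        improvement = (improvement_percentage(asm.n, scaffolded.n, asm.p)
                       if asm.n > asm.p else None)
        rows.append({
            "species": name, "genes": len(asm.genes),
            "n_contigs": asm.n, "p_chromosomes": asm.p,
            "fragmentation": prof.p_s, "log_base": prof.base,
            "contigs_initial": asm.n, "contigs_after": scaffolded.n,
            "improvement": improvement,
            "linear_fraction": stats.linear_fraction,
            "mean_dnl_nonlinear": stats.mean_dnl_nonlinear,
            "predicted": len(result.predicted_for(name)),
        })
    return pd.DataFrame(rows)
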