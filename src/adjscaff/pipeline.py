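"""End-to-end orchestration: classes -> DP -> histories -> adjacencies.

``run_pipeline`` ties the pieces together: it partitions the observed
extant adjacencies into independent classes, runs the parsimony DP on
each, backtracks one optimal history, and collects ancestral adjacencies
(internal node pairs carrying an adjacency) and predicted extant
adjacencies (extant leaf pairs carrying an adjacency that is not in the
input).  Optionally each reported adjacency receives a Boltzmann support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .boltzmann import BoltzmannDP, empirical_supports
from .classes import AdjacencyClass, GeneForest, partition
from .dp import AdjacencyDP, AdjacencyHistory, CostParameters
from .genome import Adjacency, GenomeAssembly, ANCESTRAL, PREDICTED, adjacency_key
from .prior import FragmentationProfile
from .trees import EXTANT, SpeciesTree

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Validated input: species tree, reconciled forest, extant assemblies."""

    species_tree: SpeciesTree
    forest: GeneForest
    assemblies: dict[str, GenomeAssembly]

    def observed_adjacencies(self) -> list[Adjacency]:
        out = []
        for species in sorted(self.assemblies):
            for g1, g2 in sorted(self.assemblies[species].adjacencies):
                out.append(Adjacency(g1, g2, species))
        return out

    def profiles(self, params: CostParameters) -> dict[str, FragmentationProfile]:
        return {
            s: FragmentationProfile.from_assembly(a, params.breakage,
                                                  params.base_multiplier)
            for s, a in self.assemblies.items()
        }


@dataclass
class RunResult:
    """Everything the pipeline produced."""

    params: CostParameters
    classes: list[AdjacencyClass]
    histories: list[AdjacencyHistory]
    ancestral: list[Adjacency]
    predicted: list[Adjacency]
    #: supplementary pairs with Boltzmann support above the reporting
    #: threshold that are absent from the backtracked solution
    supported_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)

    @property
    def total_cost(self) -> float:
        return sum(h.score for h in self.histories)

    def predicted_for(self, species: str) -> list[Adjacency]:
        return [a for a in self.predicted if a.species == species]

    def scaffolded_adjacencies(self, assembly: GenomeAssembly) -> set[tuple[str, str]]:
        extra = {a.key for a in self.predicted if a.species == assembly.species}
        return assembly.adjacencies | extra

    def scaffolded_assembly(self, assembly: GenomeAssembly) -> GenomeAssembly:
        """Assembly rebuilt with predicted adjacencies added."""
        return GenomeAssembly(assembly.species, assembly.genes,
                              self.scaffolded_adjacencies(assembly), assembly.p)


def run_pipeline(dataset: Dataset,
                 params: CostParameters = CostParameters(),
                 compute_supports: str = "none",
                 n_samples: int = 1000,
                 seed: int = 0,
                 tie_policy: str = "first",
                 report_threshold: float = 0.0) -> RunResult:
    """Run the full adjacency reconstruction and scaffolding pipeline.

    ``compute_supports``: "none", "exact" (inside-outside) or "sampled"
    (stochastic backtracking with ``n_samples`` draws per class).
    """
    if compute_supports not in ("none", "exact", "sampled"):
        raise ValueError(f"unknown support mode {compute_supports!r}")
    observed = dataset.observed_adjacencies()
    classes = partition(observed, dataset.forest)
    profiles = dataset.profiles(params)
    rng = np.random.default_rng(seed)

    histories: list[AdjacencyHistory] = []
    ancestral: list[Adjacency] = []
    predicted: list[Adjacency] = []
    supported_pairs: list[tuple[str, str, str, float]] = []

    for acls in classes:
        dp = AdjacencyDP(acls, dataset.assemblies, profiles, params)
        hist = dp.backtrack(tie_policy=tie_policy,
                            rng=rng if tie_policy == "random" else None)
        histories.append(hist)

        supports: dict[tuple[str, str], float] = {}
        pair_species: dict[tuple[str, str], str] = {}
        if compute_supports != "none":
            bdp = BoltzmannDP(acls, dataset.assemblies, profiles, params)
            pair_species = bdp.pair_species()
            if compute_supports == "exact":
                supports = bdp.all_supports()
            else:
                supports = empirical_supports(
                    bdp.sample_histories(n_samples, rng=rng))

        present = set()
        for v1, v2 in hist.present_pairs():
            present.add((v1.name, v2.name))
        for adj in hist.ancestral_adjacencies():
            support = supports.get((adj.gene1, adj.gene2),
                                   supports.get((adj.gene2, adj.gene1)))
            ancestral.append(Adjacency(adj.gene1, adj.gene2, adj.species,
                                       origin=ANCESTRAL, support=support))
        for v1, v2 in hist.extant_adjacencies():
            species = v1.species.name
            if dataset.assemblies[species].is_observed(v1.name, v2.name):
                continue
            support = supports.get((v1.name, v2.name),
                                   supports.get((v2.name, v1.name)))
            predicted.append(Adjacency(v1.name, v2.name, species,
                                       origin=PREDICTED, support=support))
        if compute_supports != "none":
            for (n1, n2), s in sorted(supports.items()):
                if s > report_threshold and (n1, n2) not in present \
                        and (n2, n1) not in present:
                    sp = pair_species.get((n1, n2), acls.species.name)
                    supported_pairs.append((sp, n1, n2, s))

    ancestral.sort(key=lambda a: (a.species, a.key))
    predicted.sort(key=lambda a: (a.species, a.key))
    return RunResult(params, classes, histories, ancestral, predicted,
                     supported_pairs)
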