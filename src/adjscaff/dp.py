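"""Parsimonious adjacency-evolution dynamic program.

For each adjacency class with root pair (A, B), the DP computes, for every
same-species pair of nodes (v1, v2) with v1 in T(A) and v2 in T(B), two
costs: ``c1`` — the minimum cost of a history of the observed adjacencies
below (v1, v2) given an adjacency is present between v1 and v2 — and
``c0``, the same without.  Adjacency gains cost ``Gain``, breakages
``Br``; gene losses end an adjacency lineage silently (gene-level events
are already charged by the reconciliation).

At extant leaf pairs the costs come from the assembly-aware prior:
c1 = -log_b P(v1~v2), c0 = -log_b(1 - P); for fully assembled genomes
(n = p) this degenerates to the 0/infinity rule of the perfect-assembly
model, and in fragmented genomes the per-species base b guarantees that
an adjacency inferred in the parent species is always proposed between
eligible free contig ends (c1 < c0 + Br).

All modes of use — minimum cost, backtracking one optimal history,
Boltzmann partition functions, inside-outside supports and stochastic
backtracking — are driven by a single derivation grammar: each (pair,
state) expands into a list of alternative derivations, each carrying a
local cost, local events and child (pair, state) requirements.  The
min-cost semiring gives parsimony; the log-sum-exp semiring at
temperature kT gives the Boltzmann ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .classes import AdjacencyClass
from .genome import Adjacency, GenomeAssembly, ANCESTRAL, PREDICTED, adjacency_key
from .prior import FragmentationProfile, prior_probability
from .trees import DUP, EXTANT, LOSS, SPEC, GeneNode

TIE_TOL = 1e-9

# event kinds
GAIN = "AdjGain"
BREAK = "AdjBreak"
ADJ_DUP = "AdjDup"
ADJ_LOSS = "AdjLoss"
ADJ_EXTANT = "AdjExtant"
ADJ_SPEC = "AdjSpec"


@dataclass(frozen=True)
class CostParameters:
    """Weights of the parsimony objective.

    ``gain`` and ``breakage`` default to 3 and 1: gaining a particular
    adjacency is a far rarer event than breaking an existing one, since
    the space of possible adjacencies is quadratic in gene number while
    the space of existing ones is linear.  ``kT`` is the Boltzmann
    temperature (0.1 keeps the ensemble dominated by optimal histories);
    ``base_multiplier`` places the per-genome log base just above the
    phase-change threshold.
    """

    gain: float = 3.0
    breakage: float = 1.0
    base_multiplier: float = 1.05
    kT: float = 0.1

    def __post_init__(self):
        if self.gain <= 0 or self.breakage <= 0 or self.kT <= 0:
            raise ValueError("gain, breakage and kT must be positive")


@dataclass(frozen=True)
class Derivation:
    """One alternative expansion of a (pair, state) DP cell."""

    local: float
    events: tuple[tuple, ...]                       # (kind, v1, v2)
    children: tuple[tuple[GeneNode, GeneNode, int], ...]


@dataclass
class HistoryEntry:
    v1: GeneNode
    v2: GeneNode
    state: int


@dataclass
class AdjacencyHistory:
    """One explicit adjacency history for a class."""

    class_id: int
    score: float
    entries: list[HistoryEntry] = field(default_factory=list)
    events: list[tuple] = field(default_factory=list)

    def present_pairs(self) -> list[tuple[GeneNode, GeneNode]]:
        return [(e.v1, e.v2) for e in self.entries if e.state == 1]

    def ancestral_adjacencies(self) -> list[Adjacency]:
        out = []
        for v1, v2 in self.present_pairs():
            if v1.event not in (EXTANT, LOSS) and v2.event not in (EXTANT, LOSS):
                out.append(Adjacency(v1.name, v2.name, v1.species.name,
                                     origin=ANCESTRAL))
        return out

    def extant_adjacencies(self) -> list[tuple[GeneNode, GeneNode]]:
        return [(v1, v2) for v1, v2 in self.present_pairs()
                if v1.event == EXTANT and v2.event == EXTANT]


def leaf_costs(v1_name: str, v2_name: str, assembly: GenomeAssembly,
               profile: FragmentationProfile) -> tuple[float, float]:
    """(c1, c0) for an extant same-species gene pair.

    Observed pair -> (0, inf); in a fully assembled genome any other pair
    -> (inf, 0); otherwise costs are base-b negative log probabilities.
    """
    prob = prior_probability(v1_name, v2_name, assembly)
    if prob >= 1.0:
        return 0.0, math.inf
    if prob <= 0.0:
        return math.inf, 0.0
    log_b = math.log(profile.base)
    return -math.log(prob) / log_b, -math.log(1.0 - prob) / log_b


class AdjacencyDP:
    """DP over one adjacency class.

    ``mode`` selects the Dup-Dup decomposition: ``"min"`` keeps both
    sequential expansion orders (redundant but harmless for a minimum),
    ``"boltzmann"`` expands only the first tree's duplication plus the
    explicit co-duplication terms so each history is derived exactly once.
    """

    def __init__(self, acls: AdjacencyClass,
                 assemblies: dict[str, GenomeAssembly],
                 profiles: dict[str, FragmentationProfile],
                 params: CostParameters,
                 mode: str = "min"):
        if mode not in ("min", "boltzmann"):
            raise ValueError(f"unknown mode {mode!r}")
        self.acls = acls
        self.assemblies = assemblies
        self.profiles = profiles
        self.params = params
        self.mode = mode
        self._memo: dict[tuple[int, int, int], float] = {}
        self._derivs: dict[tuple[int, int], list[list[Derivation]]] = {}
        self.pairs_examined = 0

    # -- derivation grammar -------------------------------------------------

    def derivations(self, v1: GeneNode, v2: GeneNode, state: int) -> list[Derivation]:
        key = (id(v1), id(v2))
        cached = self._derivs.get(key)
        if cached is None:
            if v1.species is not v2.species:
                raise RuntimeError(
                    f"DP requested a cross-species pair ({v1.name}, {v2.name})"
                )
            self.pairs_examined += 1
            cached = [self._expand(v1, v2, s) for s in (0, 1)]
            self._derivs[key] = cached
        return cached[state]

    def _expand(self, v1: GeneNode, v2: GeneNode, state: int) -> list[Derivation]:
        e1, e2 = v1.event, v2.event
        par = self.params
        if e1 == LOSS or e2 == LOSS:
            events = ((ADJ_LOSS, v1.name, v2.name),) if state == 1 else ()
            return [Derivation(0.0, events, ())]
        if e1 == EXTANT and e2 == EXTANT:
            assembly = self.assemblies[v1.species.name]
            profile = self.profiles[v1.species.name]
            c1, c0 = leaf_costs(v1.name, v2.name, assembly, profile)
            if state == 1:
                return [Derivation(c1, ((ADJ_EXTANT, v1.name, v2.name),), ())]
            return [Derivation(c0, (), ())]
        if e1 == DUP and e2 == DUP:
            return self._expand_dup_dup(v1, v2, state)
        if e1 == DUP:
            return self._expand_one_dup(v1, v2, state, dup_first=True)
        if e2 == DUP:
            return self._expand_one_dup(v1, v2, state, dup_first=False)
        if e1 == SPEC and e2 == SPEC:
            return self._expand_spec(v1, v2, state)
        raise RuntimeError(
            f"unexpected event pair ({e1}, {e2}) at ({v1.name}, {v2.name})"
        )

    def _expand_spec(self, v1: GeneNode, v2: GeneNode, state: int) -> list[Derivation]:
        par = self.params
        # match children by child species
        partner = {id(c.species): c for c in v2.children}
        try:
            pairs = [(c, partner[id(c.species)]) for c in v1.children]
        except KeyError:  # pragma: no cover - guaranteed by augmentation
            raise RuntimeError("speciation children do not match by species")
        out = []
        if state == 1:
            options = [
                [(0.0, (), (a, b, 1)),
                 (par.breakage, ((BREAK, a.name, b.name),), (a, b, 0))]
                for a, b in pairs
            ]
        else:
            options = [
                [(0.0, (), (a, b, 0)),
                 (par.gain, ((GAIN, a.name, b.name),), (a, b, 1))]
                for a, b in pairs
            ]
        for first in options[0]:
            for second in options[1]:
                out.append(Derivation(first[0] + second[0],
                                      first[1] + second[1],
                                      (first[2], second[2])))
        return out

    def _one_dup_derivs(self, u: GeneNode, w: GeneNode, other: GeneNode,
                        state: int, other_first: bool) -> list[Derivation]:
        """Case: one node is a duplication with copies u, w."""
        par = self.params

        def pair(x):
            return (other, x, ) if other_first else (x, other)

        def child(x, s):
            a, b = pair(x)
            return (a, b, s)

        def names(x):
            a, b = pair(x)
            return a.name, b.name

        if state == 1:
            return [
                Derivation(0.0, (), (child(u, 1), child(w, 1))),
                Derivation(0.0, (), (child(u, 1), child(w, 0))),
                Derivation(0.0, (), (child(u, 0), child(w, 1))),
                Derivation(par.breakage,
                           ((BREAK, *names(u)),),
                           (child(u, 0), child(w, 0))),
            ]
        return [
            Derivation(0.0, (), (child(u, 0), child(w, 0))),
            Derivation(par.gain, ((GAIN, *names(u)),),
                       (child(u, 1), child(w, 0))),
            Derivation(par.gain, ((GAIN, *names(w)),),
                       (child(u, 0), child(w, 1))),
            Derivation(2 * par.gain,
                       ((GAIN, *names(u)), (GAIN, *names(w))),
                       (child(u, 1), child(w, 1))),
        ]

    def _expand_one_dup(self, v1: GeneNode, v2: GeneNode, state: int,
                        dup_first: bool) -> list[Derivation]:
        dup = v1 if dup_first else v2
        other = v2 if dup_first else v1
        u, w = dup.children
        return self._one_dup_derivs(u, w, other, state, other_first=not dup_first)

    def _expand_dup_dup(self, v1: GeneNode, v2: GeneNode, state: int) -> list[Derivation]:
        par = self.params
        u1, w1 = v1.children
        u2, w2 = v2.children
        out = self._one_dup_derivs(u1, w1, v2, state, other_first=False)
        if self.mode == "min":
            out = out + self._one_dup_derivs(u2, w2, v1, state, other_first=True)
        if state == 1:
            for pairing in (((u1, u2), (w1, w2)), ((u1, w2), (w1, u2))):
                (a1, a2), (b1, b2) = pairing
                options_a = [
                    (0.0, (), (a1, a2, 1)),
                    (par.breakage, ((BREAK, a1.name, a2.name),), (a1, a2, 0)),
                ]
                options_b = [
                    (0.0, (), (b1, b2, 1)),
                    (par.breakage, ((BREAK, b1.name, b2.name),), (b1, b2, 0)),
                ]
                for fa in options_a:
                    for fb in options_b:
                        out.append(Derivation(
                            fa[0] + fb[0],
                            ((ADJ_DUP, v1.name, v2.name),) + fa[1] + fb[1],
                            (fa[2], fb[2]),
                        ))
        return out

    # -- minimum cost -------------------------------------------------------

    def cost(self, v1: GeneNode, v2: GeneNode, state: int) -> float:
        key = (id(v1), id(v2), state)
        val = self._memo.get(key)
        if val is None:
            val = math.inf
            for d in self.derivations(v1, v2, state):
                total = d.local
                for a, b, s in d.children:
                    total += self.cost(a, b, s)
                    if total == math.inf:
                        break
                val = min(val, total)
            self._memo[key] = val
        return val

    def root_costs(self) -> tuple[float, float]:
        a, b = self.acls.root_a, self.acls.root_b
        return self.cost(a, b, 1), self.cost(a, b, 0)

    def total_cost(self) -> float:
        c1, c0 = self.root_costs()
        return min(c0, c1 + self.params.gain)

    # -- backtracking -------------------------------------------------------

    def backtrack(self, tie_policy: str = "first", rng=None) -> AdjacencyHistory:
        """Reconstruct one optimal history.

        ``tie_policy``: "first" picks the first derivation (in listed case
        order) within 1e-9 of the optimum; "random" picks uniformly among
        ties using ``rng``.
        """
        if tie_policy not in ("first", "random"):
            raise ValueError(f"unknown tie policy {tie_policy!r}")
        if tie_policy == "random" and rng is None:
            raise ValueError("tie_policy='random' needs an rng")
        a, b = self.acls.root_a, self.acls.root_b
        c1, c0 = self.root_costs()
        total = min(c0, c1 + self.params.gain)
        history = AdjacencyHistory(self.acls.class_id, total)
        if c1 + self.params.gain < c0 - TIE_TOL:
            root_state = 1
        elif c0 < c1 + self.params.gain - TIE_TOL:
            root_state = 0
        else:  # tie: first-listed convention is "with adjacency" (gain at root)
            root_state = 1
        if root_state == 1:
            history.events.append((GAIN, a.name, b.name))
        self._backtrack_into(a, b, root_state, history, tie_policy, rng)
        history.entries.sort(key=lambda e: (e.v1.name, e.v2.name))
        return history

    def _backtrack_into(self, v1, v2, state, history, tie_policy, rng) -> None:
        history.entries.append(HistoryEntry(v1, v2, state))
        derivs = self.derivations(v1, v2, state)
        totals = []
        for d in derivs:
            t = d.local + sum(self.cost(a, b, s) for a, b, s in d.children)
            totals.append(t)
        best = min(totals)
        tie_idx = [i for i, t in enumerate(totals) if t <= best + TIE_TOL]
        idx = tie_idx[0] if tie_policy == "first" else tie_idx[int(rng.integers(len(tie_idx)))]
        chosen = derivs[idx]
        history.events.extend(chosen.events)
        for a, b, s in chosen.children:
            self._backtrack_into(a, b, s, history, tie_policy, rng)
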