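"""Boltzmann-ensemble exploration of the adjacency solution space.

Histories h are weighted e^(-s(h)/kT); the partition function Z of a
class sums these weights over all histories, and the support of a feature
(an adjacency at a given node pair) is the weighted fraction of histories
containing it.  Supports are computed exactly by inside-outside over the
same derivation grammar as the parsimony DP (in its non-redundant mode),
and can be cross-checked by stochastic backtracking: sampling complete
histories with probability proportional to their Boltzmann weight.

All arithmetic is carried in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classes import AdjacencyClass
from .dp import AdjacencyDP, AdjacencyHistory, CostParameters, GAIN, HistoryEntry
from .genome import GenomeAssembly
from .prior import FragmentationProfile
from .trees import EXTANT, LOSS, GeneNode

NEG_INF = float("-inf")


def _lse(values) -> float:
    m = max(values, default=NEG_INF)
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(sum(math.exp(v - m) for v in values))


def _logaddexp(a: float, b: float) -> float:
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    m = max(a, b)
    return m + math.log(math.exp(a - m) + math.exp(b - m))


def _depth(node: GeneNode) -> int:
    d = 0
    x = node.parent
    while x is not None:
        d += 1
        x = x.parent
    return d


class BoltzmannDP:
    """Partition functions, exact supports and a history sampler."""

    def __init__(self, acls: AdjacencyClass,
                 assemblies: dict[str, GenomeAssembly],
                 profiles: dict[str, FragmentationProfile],
                 params: CostParameters):
        self.acls = acls
        self.params = params
        self.dp = AdjacencyDP(acls, assemblies, profiles, params,
                              mode="boltzmann")
        self._logz: dict[tuple[int, int, int], float] = {}
        self._pairs: dict[tuple[int, int], tuple[GeneNode, GeneNode]] = {}
        self._outside: Optional[dict[tuple[int, int, int], float]] = None
        # force computation of the full table
        self.log_partition()

    # -- inside -------------------------------------------------------------

    def logz(self, v1: GeneNode, v2: GeneNode, state: int) -> float:
        key = (id(v1), id(v2), state)
        val = self._logz.get(key)
        if val is None:
            self._pairs[(id(v1), id(v2))] = (v1, v2)
            terms = []
            for d in self.dp.derivations(v1, v2, state):
                w = -d.local / self.params.kT
                for a, b, s in d.children:
                    w += self.logz(a, b, s)
                    if w == NEG_INF:
                        break
                terms.append(w)
            val = _lse(terms)
            self._logz[key] = val
        return val

    def log_partition(self) -> float:
        """log Z = log(z0(A,B) + z1(A,B) * e^(-Gain/kT))."""
        a, b = self.acls.root_a, self.acls.root_b
        lz1 = self.logz(a, b, 1)
        lz0 = self.logz(a, b, 0)
        return _logaddexp(lz0, lz1 - self.params.gain / self.params.kT)

    # -- outside / supports --------------------------------------------------

    def _compute_outside(self) -> dict[tuple[int, int, int], float]:
        if self._outside is not None:
            return self._outside
        a, b = self.acls.root_a, self.acls.root_b
        outside: dict[tuple[int, int, int], float] = {
            (id(a), id(b), 0): 0.0,
            (id(a), id(b), 1): -self.params.gain / self.params.kT,
        }
        # children of a derivation sit strictly deeper than their pair
        order = sorted(
            self._pairs.values(),
            key=lambda pair: (_depth(pair[0]) + _depth(pair[1]),
                              pair[0].name, pair[1].name),
        )
        for v1, v2 in order:
            for state in (0, 1):
                key = (id(v1), id(v2), state)
                out = outside.get(key, NEG_INF)
                if out == NEG_INF:
                    continue
                for d in self.dp.derivations(v1, v2, state):
                    base = out - d.local / self.params.kT
                    if base == NEG_INF:
                        continue
                    child_lz = [self._logz.get((id(x), id(y), s), NEG_INF)
                                for x, y, s in d.children]
                    for i, (x, y, s) in enumerate(d.children):
                        contrib = base
                        for j, lz in enumerate(child_lz):
                            if j != i:
                                contrib += lz
                        ckey = (id(x), id(y), s)
                        outside[ckey] = _logaddexp(outside.get(ckey, NEG_INF),
                                                   contrib)
        self._outside = outside
        return outside

    def support(self, v1: GeneNode, v2: GeneNode) -> float:
        """Boltzmann support of an adjacency between v1 and v2.

        The weighted fraction of histories in which the pair (v1, v2) is
        in state 1.  0 for pairs never reached by any derivation.
        """
        outside = self._compute_outside()
        lz = self._logz.get((id(v1), id(v2), 1), NEG_INF)
        lo = outside.get((id(v1), id(v2), 1), NEG_INF)
        if lz == NEG_INF or lo == NEG_INF:
            return 0.0
        val = math.exp(lz + lo - self.log_partition())
        return min(max(val, 0.0), 1.0)

    def all_supports(self) -> dict[tuple[str, str], float]:
        """Support of every reachable non-loss pair (by node names)."""
        out = {}
        for v1, v2 in self._pairs.values():
            if v1.event == LOSS or v2.event == LOSS:
                continue
            out[(v1.name, v2.name)] = self.support(v1, v2)
        return out

    def pair_species(self) -> dict[tuple[str, str], str]:
        """Species hosting each reachable pair (by node names)."""
        return {(v1.name, v2.name): v1.species.name
                for v1, v2 in self._pairs.values()}

    # -- sampling ------------------------------------------------------------

    def sample(self, rng: np.random.Generator) -> AdjacencyHistory:
        """Draw one history with probability e^(-s/kT) / Z."""
        a, b = self.acls.root_a, self.acls.root_b
        lw = [self.logz(a, b, 0),
              self.logz(a, b, 1) - self.params.gain / self.params.kT]
        root_state = _sample_index(lw, rng)
        history = AdjacencyHistory(self.acls.class_id, 0.0)
        if root_state == 1:
            history.events.append((GAIN, a.name, b.name))
            history.score += self.params.gain
        self._sample_into(a, b, root_state, history, rng)
        history.entries.sort(key=lambda e: (e.v1.name, e.v2.name))
        return history

    def _sample_into(self, v1, v2, state, history, rng) -> None:
        history.entries.append(HistoryEntry(v1, v2, state))
        derivs = self.dp.derivations(v1, v2, state)
        lw = []
        for d in derivs:
            w = -d.local / self.params.kT
            for x, y, s in d.children:
                w += self._logz[(id(x), id(y), s)]
            lw.append(w)
        chosen = derivs[_sample_index(lw, rng)]
        history.score += chosen.local
        history.events.extend(chosen.events)
        for x, y, s in chosen.children:
            self._sample_into(x, y, s, history, rng)

    def sample_histories(self, n: int, seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None,
                         ) -> list[AdjacencyHistory]:
        """Draw ``n`` independent Boltzmann-distributed histories."""
        if n < 1:
            raise ValueError("need n >= 1 samples")
        if rng is None:
            rng = np.random.default_rng(seed)
        return [self.sample(rng) for _ in range(n)]


def _sample_index(log_weights, rng: np.random.Generator) -> int:
    lw = np.asarray(log_weights, dtype=float)
    m = np.max(lw)
    if m == NEG_INF:
        raise RuntimeError("all derivation weights vanished")
    probs = np.exp(lw - m)
    probs /= probs.sum()
    return int(rng.choice(len(probs), p=probs))


def empirical_supports(histories: list[AdjacencyHistory],
                       ) -> dict[tuple[str, str], float]:
    """Fraction of sampled histories containing each pair in state 1."""
    counts: dict[tuple[str, str], int] = {}
    for h in histories:
        for e in h.entries:
            if e.state == 1 and e.v1.event != LOSS and e.v2.event != LOSS:
                key = (e.v1.name, e.v2.name)
                counts[key] = counts.get(key, 0) + 1
    n = len(histories)
    return {k: v / n for k, v in counts.items()}
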