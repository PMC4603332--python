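"""Contig-joining combinatorics and the a-priori adjacency probability.

The number of distinct ways to join ``n`` labeled, orientable contigs into
``p`` linear chromosomes (counted as sets of extremity adjacencies) has
the closed form

    f(n, p) = n!/p! * 2^(n-p) * C(n-1, p-1)

with f(n, p) = 0 when p > n or p = 0.  The probability that two contig
extremities are joined in a uniformly drawn solution is f(n-1, p)/f(n, p)
= (n-p) / (2 n (n-1)); at gene level it is multiplied by a correction
``rho`` in {1, 2, 4} accounting for single-gene contigs, whose unique gene
carries both extremities.  The per-genome fragmentation measure

    p(S) = (n - p) / (2 n (n - 1))

drives the choice of the logarithm base ``b`` that converts probabilities
into dynamic-programming costs: the program proposes a new adjacency
under an inferred parental one exactly when c1 < c0 + Br, i.e. when
b > ((1 - p(S)) / p(S))^(1/Br); the base is set a fixed multiplier
(default 1.05) above this phase-change threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .genome import GenomeAssembly
from .trees import InputError

#: clamp for the a-priori probability before taking logarithms; rho = 4 on
#: very small genomes could push the closed form to 1 or above.
P_CLAMP = 1.0 - 1e-12

DEFAULT_BASE_MULTIPLIER = 1.05


def count_solutions(n: int, p: int) -> int:
    """Exact number of ways to join n contigs into p linear chromosomes."""
    if n < 1:
        raise InputError(f"contig count must be >= 1, got {n}")
    if p <= 0 or p > n:
        return 0
    return math.factorial(n) // math.factorial(p) * 2 ** (n - p) * math.comb(n - 1, p - 1)


@lru_cache(maxsize=None)
def count_solutions_by_recurrence(n: int, p: int) -> int:
    """Same value as :func:`count_solutions`, via the one-chromosome recurrence.

    f(n+1, p) = 1/p * sum_{x=1}^{n+1-(p-1)} 2^(x-1) (n+1)!/(n+1-x)! f(n+1-x, p-1)

    (sum over the number x of contigs composing one distinguished
    chromosome).  Serves as an independent oracle for the closed form.
    """
    if n < 1:
        raise InputError(f"contig count must be >= 1, got {n}")
    if p <= 0 or p > n:
        return 0
    if n == 1:
        return 1 if p == 1 else 0
    m = n - 1  # recurrence written for f(m+1, p)
    total = 0
    for x in range(1, m + 1 - (p - 1) + 1):
        rest = m + 1 - x
        sub = 1 if (rest == 0 and p == 1) else (
            0 if rest == 0 else count_solutions_by_recurrence(rest, p - 1)
        )
        total += 2 ** (x - 1) * math.factorial(m + 1) // math.factorial(rest) * sub
    assert total % p == 0, "recurrence must divide evenly"
    return total // p


def fragmentation(n: int, p: int) -> float:
    """Assembly fragmentation measure p(S) = (n-p) / (2n(n-1))."""
    if n < 1 or p < 1 or p > n:
        raise InputError(f"invalid contig/chromosome counts n={n}, p={p}")
    if n == 1:
        return 0.0
    return (n - p) / (2 * n * (n - 1))


def rho(v1: str, v2: str, assembly: GenomeAssembly) -> int:
    """Extremity-multiplicity correction: 4, 2 or 1.

    4 if both genes are alone in their contigs, 2 if exactly one is, 1
    otherwise.  A singleton contig's gene carries both extremities of its
    contig, so it can be joined in more ways.
    """
    singles = sum(1 for v in (v1, v2) if len(assembly.contig_of(v)) == 1)
    return (1, 2, 4)[singles]


def prior_probability(v1: str, v2: str, assembly: GenomeAssembly) -> float:
    """A-priori probability that genes v1 and v2 are adjacent.

    1 for an observed adjacency; for a perfectly assembled genome (n = p)
    0 otherwise.  In a fragmented genome, a pair of free extremities on
    two different contigs gets rho * (n-p) / (2n(n-1)); any other pair
    (internal gene, or same contig) gets 0.
    """
    if v1 == v2:
        raise InputError("prior_probability needs two distinct genes")
    if assembly.is_observed(v1, v2):
        return 1.0
    n, p = assembly.n, assembly.p
    if n == p:
        return 0.0
    if not (assembly.is_free_end(v1) and assembly.is_free_end(v2)):
        return 0.0
    if assembly.same_contig(v1, v2):
        return 0.0
    prob = rho(v1, v2, assembly) * (n - p) / (2 * n * (n - 1))
    return min(prob, P_CLAMP)


def phase_change_threshold(p_s: float, br: float) -> float:
    """The base value at which c1 = c0 + Br for a rho = 1 eligible pair."""
    if p_s <= 0:
        return math.inf
    return ((1.0 - p_s) / p_s) ** (1.0 / br)


def log_base(n: int, p: int, br: float,
             multiplier: float = DEFAULT_BASE_MULTIPLIER) -> float:
    """DP logarithm base b = multiplier * ((1-p(S))/p(S))^(1/Br).

    Only defined for fragmented genomes (n > p); a fully assembled genome
    keeps the degenerate 0/infinity leaf costs and needs no base.
    """
    if n <= p:
        raise InputError("log base undefined for a fully assembled genome (n = p)")
    b = multiplier * phase_change_threshold(fragmentation(n, p), br)
    if b <= 1.0:
        raise InputError(f"log base {b} <= 1; increase the multiplier")
    return b


@dataclass(frozen=True)
class FragmentationProfile:
    """Per-species fragmentation summary and DP base.

    ``base`` is None for fully assembled genomes (n = p): such species
    never receive new adjacency proposals.
    """

    species: str
    n: int
    p: int
    p_s: float
    base: Optional[float]
    br: float
    multiplier: float = DEFAULT_BASE_MULTIPLIER

    @classmethod
    def from_assembly(cls, assembly: GenomeAssembly, br: float,
                      multiplier: float = DEFAULT_BASE_MULTIPLIER,
                      ) -> "FragmentationProfile":
        n, p = assembly.n, assembly.p
        p_s = fragmentation(n, p) if n >= 1 else 0.0
        base = log_base(n, p, br, multiplier) if n > p else None
        return cls(assembly.species, n, p, p_s, base, br, multiplier)
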