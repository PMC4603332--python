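# Methods

`adjscaff` jointly reconstructs ancestral gene adjacencies and proposes
scaffolding joins in fragmented extant genomes, by parsimony over pairs of
reconciled gene trees. This note documents the model, its parameters, the
numerical choices, what the synthetic-data generator does and does not
emulate, and known limitations.

## Model

### Inputs and reconciliation

The input is a rooted binary species tree, one rooted binary gene tree per
homologous family, a gene-to-species map, the observed adjacencies (unordered
neighbor pairs of genes) of each extant genome, and the expected chromosome
count `p` of each extant species. Gene trees are reconciled against the
species tree by LCA mapping — each internal node is assigned the lowest
common ancestor of its children's species — which minimizes the number of
gene duplications plus losses. Trees are then *loss-augmented*: intermediate
speciation nodes and explicit loss leaves are inserted so every lineage
visits every species on its species-tree path. Any event annotations already
present in the input (e.g. NHX duplication tags) are ignored and recomputed;
external annotations can disagree with the reconciliation criterion, and a
single consistent labeling is required downstream. Non-binary trees are
rejected rather than resolved: the dynamic program's case analysis assumes
binarity.

### Adjacency classes

Two observed adjacencies may descend from one ancestral adjacency only if
their extremities pair up into two family sides whose lineages co-occur in
some species: ancestors A and B with s(A) = s(B). This relation partitions
the observed adjacencies into equivalence classes, each analysed
independently. A class is represented by a *root pair* (A, B) of disjoint,
non-nested gene-tree nodes in a common species whose subtrees contain all
class extremities.

The root pair is lifted to the **most ancient** species the two lineage
chains share. This choice matters: a class observed only in species X can
still propose the adjacency in a fragmented sister species Y, because the
DP instance rooted at their common ancestor contains Y's leaves. When a
duplication makes several nodes of one species available, the most ancient
disjoint pair is taken, with lexicographic node-name tie-breaking so runs
are reproducible. Within a single family (tandem duplicates), extremity-to-
side assignments are propagated by BFS over the pairwise equivalences; a
class whose sides cannot be made disjoint (e.g. a tandem array a–b, b–c
sharing gene b between sides) is split back into singleton classes with a
warning, so every observed adjacency remains analysable.

### The dynamic program

For every same-species node pair (v1, v2) with v1 in T(A) and v2 in T(B),
two costs are computed bottom-up: `c1`, the minimum cost of an adjacency
history given an adjacency is present between v1 and v2, and `c0`, the same
given it is absent. Adjacency gains cost `Gain`, breakages `Br`; gene losses
terminate an adjacency lineage at no charge (gene-level events are already
paid for by the reconciliation). The cases:

- **Loss pair**: c1 = c0 = 0.
- **Extant–Extant**: probabilistic leaf costs (below).
- **Spec–Spec** (children matched by species): per child-species side,
  keep (`c1`) or break (`c0 + Br`) under c1; stay absent (`c0`) or gain
  (`c1 + Gain`) under c0; sum over the two sides.
- **Dup–other**: the duplicated gene's two copies each inherit or not; a
  break is charged only when neither copy inherits; under c0, each copy
  entering the adjacent state costs a gain.
- **Dup–Dup**: sequential expansion of either duplication, plus explicit
  co-duplication terms in which the adjacency itself duplicates along the
  paired copies ({(u1,u2),(w1,w2)} or the crossed pairing), each paired term
  being keep-or-break.

The class answer is `min(c0(A,B), c1(A,B) + Gain)`: an adjacency present at
the class root must have been gained there. Infinities are true IEEE
infinities with saturating addition — never numeric sentinels. Backtracking
reconstructs one optimal history; ties within an absolute tolerance of 1e-9
are resolved by first-listed case order (or seeded-random, if requested).

All modes — min-cost, backtracking, partition functions, inside–outside
supports, stochastic sampling — run on one shared *derivation grammar*:
each (pair, state) cell expands into alternative derivations carrying a
local cost, local events, and child cells. The min-plus semiring gives
parsimony; the log-sum-exp semiring gives the Boltzmann ensemble.

### Assembly-aware leaf costs

A genome with `n` contigs and `p` expected chromosomes needs `n − p` joins.
The number of distinct joinings (sets of extremity adjacencies turning the
n orientable contigs into p linear chromosomes) is

    f(n, p) = n!/p! · 2^(n−p) · C(n−1, p−1),

and the probability that two specific free extremities are joined in a
uniform random solution is f(n−1, p)/f(n, p) = (n−p)/(2n(n−1)). At gene
level this is multiplied by ρ ∈ {1, 2, 4}: a single-gene contig carries
both of its contig's extremities, doubling its chances per singleton end.
The per-genome fragmentation measure is p(S) = (n−p)/(2n(n−1)).

Leaf costs are `c1 = −log_b P` and `c0 = −log_b(1 − P)`, where P is 1 for
an observed pair, 0 for ineligible pairs (internal genes, same contig, or
any unobserved pair in a fully assembled genome), and ρ·p(S) otherwise.
With P ∈ {0, 1} these degenerate to the 0/∞ costs of the perfect-assembly
model, so fully assembled genomes never receive proposals.

The base `b` controls sensitivity. An adjacency inferred in the parent
species is propagated into the leaves exactly when `c1 < c0 + Br`, which
for ρ = 1 requires `b > ((1 − p(S))/p(S))^(1/Br)` — a sharp phase change.
The base is set `base_multiplier` (default 1.05) times this threshold, just
onto the plateau. Note that below the threshold a few proposals can still
occur: ρ = 2 and ρ = 4 pairs satisfy the inequality earlier, so the
"near-zero" regime is small but not exactly zero.

### Boltzmann supports

Histories h are weighted e^(−s(h)/kT). The class partition function is
Z = z0(A,B) + z1(A,B)·e^(−Gain/kT); the support of an adjacency at a pair
is the weighted fraction of histories placing that pair in state 1,
computed exactly by inside–outside over the derivation grammar. For the
Dup–Dup case the Boltzmann grammar expands only the first tree's
duplication (plus the co-duplication terms), so each history is derived
exactly once; the redundant second sequential order is kept only in the
min-cost grammar, where it cannot change a minimum. The grammar in its
non-redundant form *is* the definition of a history; test oracles
enumerate complete derivations without memoization and must reproduce both
the minimum and Z.

A stochastic backtracking sampler draws histories with probability
proportional to their Boltzmann weight and serves as an independent
cross-check of the exact supports. All ensemble arithmetic is in log space
with stable log-sum-exp.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `Gain` | 3 | cost | gaining a specific adjacency is far rarer than breaking an existing one: the candidate space is quadratic in gene count versus linear for existing adjacencies |
| `Br` | 1 | cost | reference unit of the objective |
| `base_multiplier` | 1.05 | — | places b just above the phase-change threshold, safely on the plateau |
| `kT` | 0.1 | score units | keeps the Boltzmann ensemble dominated by optimal and slightly sub-optimal histories (≥95% of sampled histories are optimal on our fixtures) |
| clamp ε | 1e-12 | probability | P is clamped to [0, 1−ε] before logs; ρ = 4 on tiny genomes can push the closed form to 1 or above |
| tie tolerance | 1e-9 | cost | absolute tolerance for floating-point ties in backtracking |

## Synthetic data

The forward simulator evolves a root genome (default 200 gene families on
2 chromosomes) down a species tree (default 8 species, Yule topology) under
per-branch events: gene duplication (2% per gene; tandem placement with a
20% translocation probability, to exercise the co-duplication DP terms),
gene loss (2% per gene; neighbors rejoin), and adjacency breakage (2% per
adjacency) followed by random rejoining of chromosome ends so extant
genomes remain disjoint paths at the stated chromosome count. These low
rates describe the conserved-synteny regime in which phylogenetic
scaffolding is informative. Fragmentation ("fission") experiments then
remove k (or a fraction of) random adjacencies from an assembled genome
and score how many the pipeline recovers.

What the simulator does **not** emulate: gene orientation, sequence
evolution, gene conversion or transfer, assembly chimerism (its fragmented
genomes have missing joins, never false ones), gene-tree estimation error,
and biased fission placement. A green end-to-end test therefore establishes
that the method recovers adjacencies removed from internally consistent
data — not that it is robust to wrong gene trees, which on real data are
the dominant source of conflicts.

Fission targets default to a *cherry* leaf (one whose sister is also a
leaf): a rooted parsimony method cannot scaffold an outgroup, since an
adjacency absent from a basal species is more parsimoniously gained once
in the ingroup ancestor than broken on the outgroup branch.

## Degenerate inputs and edge cases

- Observed adjacency graphs that are not disjoint paths are accepted with a
  warning; contigs remain connected components.
- Species with n = p are excluded from proposal (no base b is defined);
  their leaves keep 0/∞ costs.
- A circular contig would score −2 under the raw non-linearity formula
  D_nl = Σ_{deg>2}(d−2) + (m−2); it is clamped to 0 and counted separately
  as cyclic.
- Genes present in trees but absent from adjacency files become singleton
  contigs; adjacencies naming genes absent from every tree are dropped with
  a warning.

## Known limitations

- No gene orientation: adjacencies relate genes, not gene extremities, so
  single-gene inversions are invisible.
- Input adjacencies are never questioned (their prior is fixed at 1); a
  chimeric input contig cannot be cut.
- Output adjacency sets may conflict (genes with more than two neighbors);
  no linearization is performed — conflicts are reported and measured by
  the non-linearity statistics instead.
- Classes are independent by construction; two classes can propose
  conflicting adjacencies over the same genes.
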