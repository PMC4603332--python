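# adjscaff

Joint reconstruction of **ancestral gene adjacencies** and **scaffolding of
fragmented extant genomes**, by parsimony over pairs of reconciled gene
trees.

## The problem

Reconstructing ancestral gene order and scaffolding an incompletely
assembled genome are the same problem posed at different nodes of a species
tree: in both cases we ask which genes were (or are) neighbors, given the
neighborhoods observed in related genomes and the gene phylogenies linking
them. Many sequenced genomes remain collections of contigs; comparative
evidence can order them. `adjscaff` treats an *adjacency* — an unordered
pair of neighboring genes — as the evolving character. Adjacencies are
gained and broken by rearrangements, duplicated when both their genes
duplicate together, and silently terminated by gene loss.

## The method

Gene trees are reconciled with the species tree by LCA mapping (minimizing
duplications + losses) and augmented with explicit loss leaves. Observed
adjacencies are partitioned into independent equivalence classes — two
adjacencies may share an ancestral adjacency only if their extremity
lineages co-occur in a common species — and each class is solved by a
dynamic program over same-species node pairs (v1, v2), computing

    c1(v1, v2) / c0(v1, v2) = min cost of an adjacency history
                              with / without an adjacency at (v1, v2)

under costs *Gain* = 3 for an adjacency gain and *Br* = 1 for a breakage.

The key extension beyond perfect-assembly ancestral reconstruction is the
leaf case. For extant genes, costs come from an a-priori adjacency
probability derived from exact contig-joining combinatorics: with `n`
contigs and `p` chromosomes there are

    f(n, p) = n!/p! · 2^(n−p) · C(n−1, p−1)

ways to join the contigs into `p` linear chromosomes, giving each eligible
pair of free contig ends probability P = ρ·(n−p)/(2n(n−1)), ρ ∈ {1,2,4}
correcting for single-gene contigs. Leaf costs are c1 = −log_b P and
c0 = −log_b(1−P); the base b is set 1.05× above the phase-change threshold
((1−p(S))/p(S))^(1/Br), which guarantees that an adjacency inferred in the
parent species is always propagated into eligible free ends — the genome's
fragmentation p(S) = (n−p)/(2n(n−1)) itself sets the method's sensitivity.
Fully assembled genomes (n = p) keep degenerate 0/∞ costs and never receive
proposals.

Every proposed adjacency (ancestral or extant) can carry a **support**: its
weighted frequency under the Boltzmann distribution e^(−s(h)/kT) over all
adjacency histories h (kT = 0.1 by default), computed exactly by
inside–outside over the DP, with a stochastic-backtracking sampler as an
independent cross-check.

A forward simulator generates complete ground-truth datasets (species tree,
gene trees with duplications and losses, genomes as gene orders,
fragmentation by random adjacency removal), so the whole pipeline is
testable without any external data.

## Worked example

Simulate six genomes, fragment one by removing 15 adjacencies, reconstruct:

```sh
adjscaff simulate --out sim --species 6 --families 60 --seed 42
adjscaff fragment --adjacencies sim/adjacencies.tsv \
    --chromosomes sim/chromosome_counts.tsv \
    --species S2 --remove 15 --seed 42 \
    --out frag.tsv --removed-out removed.tsv
adjscaff run --species-tree sim/species.nwk --gene-trees sim/gene_trees.tsv \
    --gene-map sim/gene_map.tsv --adjacencies frag.tsv \
    --chromosomes sim/chromosome_counts.tsv \
    --supports exact --out predicted.tsv
adjscaff evaluate --removed removed.tsv --predicted predicted.tsv
```

prints

```
simulated 60 families over 6 species -> sim
removed 15 adjacencies from S2
80 classes, 289 ancestral adjacencies, 12 predicted extant adjacencies -> predicted.tsv
k_removed=15 TP=10 FP=2 TP_rate=0.5882 FP_rate=0.1176 precision=0.8333
```

Of the 15 removed adjacencies, 10 were recovered purely from the sister
genomes and the gene phylogenies, with 2 false proposals: the recovery rate
(TP/(k+FP)) is 59% and the precision (TP of all proposals) 83%. The output
TSV lists one adjacency per line — species or ancestral node, the two gene
(or ancestral-gene) identifiers, origin (`ancestral`/`predicted`), its
equivalence class, and its Boltzmann support:

```
A1	F0000|3	F0001|7	ancestral	0	1.000000
...
S2	F0002_S2	F0003_S2	predicted	5	0.894154
```

The first line is an ancestral adjacency in species A1 (the S2–S3
ancestor) present in every optimal history (support 1.0); the second is a
proposed scaffolding join in the fragmented S2 genome, present in 89% of
the Boltzmann ensemble. Sensitivity depends on how close the relatives are
— a basal species without a sister cannot be scaffolded at all, since
absence there is more parsimoniously explained by a gain in the ingroup —
while precision stays high, so the proposals are best read as a reliable
partial scaffolding rather than a finished assembly.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch through the library, the
two desk-scale checks: the base case of the closed-form contig-joining
count (one contig into one chromosome, cross-validated against the
independent recurrence) and the degree of non-linearity of a 5-gene contig
whose adjacency graph is a path with one extra branch. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
|---|---|
| `adjscaff.trees` | species/gene trees, LCA reconciliation, loss augmentation, NHX I/O |
| `adjscaff.genome` | assemblies, contigs, adjacency extraction |
| `adjscaff.prior` | contig-joining counts f(n,p), a-priori probability, log base |
| `adjscaff.classes` | adjacency equivalence classes and root pairs |
| `adjscaff.dp` | the parsimony DP, cost tables, backtracking |
| `adjscaff.boltzmann` | partition functions, inside–outside supports, sampler |
| `adjscaff.metrics` | recovery rates, non-linearity D_nl, improvement, sweeps |
| `adjscaff.simulate` | forward simulator, fission protocol, export |
| `adjscaff.pipeline` / `adjscaff.io` / `adjscaff.cli` | orchestration, formats, CLI |

See `docs/methods.md` for the full model description, parameter rationale
and limitations.
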