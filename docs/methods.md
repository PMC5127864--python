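# Methods

This note documents the models and procedures implemented in `viropan`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Ortholog profiling

Profiling reproduces the standard annotation discipline for viral
proteomes searched against a reference ortholog database:

1. **Query filter.** Only proteins of length ≥ 100 aa are used as
   queries (boundary inclusive). Shorter ORFs are too unreliable for
   similarity-based family assignment.
2. **Significance filter.** Hits must satisfy E < 1e-5, with the
   inequality strict. A stricter cutoff (e.g. 1e-20) is appropriate for
   single marker genes and is a plain parameter.
3. **One family per ORF.** When an ORF hits several reference families,
   the hit with the highest bit score wins.
4. **One ORF per family per genome.** When several ORFs of one genome
   hit the same family, the highest-bit-score ORF is kept as the
   ortholog; displaced ORFs are reported as paralog candidates rather
   than discarded silently.

Tie-breaks are fixed everywhere as (higher bit score, lower E-value,
lexicographic subject/ORF id); search tools rarely produce exact ties,
but fixing the order makes every run reproducible. After step 4 the
genome→family relation is injective in both directions, which the code
asserts.

**Paralogs vs transfers.** For a group of redundant ORFs within one
genome, the all-pairs identity range of the group is compared with the
range of each member's best-ortholog identity. If even the least
similar paralog pair is closer than the closest external ortholog, the
redundancy is classified as a likely recent duplication; the reverse
pattern suggests independent acquisition; overlapping ranges are
ambiguous. Identities default to the hit table's local-alignment
percent identity (what a search tool reports); a global-alignment
option (Needleman–Wunsch, BLOSUM62) exists because the two metrics can
differ for partially aligned pairs, and which one an annotation
pipeline "means" is usually unstated.

**Source tallies.** The per-genome distribution of best-hit source
organisms excludes subjects from the query genome itself before the
best hit is chosen, and reports the no-hit remainder explicitly, so the
fractions always sum to 1. Whether the denominator should be all ORFs
or only ORFs with some hit is ambiguous in common usage; both are
recoverable from the reported counts.

## Pan-genome clustering

Edges of the similarity graph require ≥ 20% identity and E < 1e-5
(identity boundary inclusive, E-value strict); the edge weight is the
maximum admitted bit score over the two directions. Markov clustering
then alternates expansion (matrix squaring) with inflation (entry-wise
power 2.0 followed by column renormalization) on the column-stochastic
transition matrix with self-loops, until the maximum entry change falls
below 1e-6 (at most 200 iterations; non-convergence is flagged and
best-effort clusters returned). Self-loop weight is the node's
strongest incident edge weight, a standard regularization that stops
high-degree hubs from swallowing their neighborhoods. Clusters are the
connected components of the attractor's support (entries > 1e-6).

The computation is run independently per connected component of the
input graph. This is exact — MCL can only split, never merge,
disconnected components — and keeps the dense matrix small. Node order
within a component is sorted, so the result is invariant to input
order and node relabeling.

Gene-content distance defaults to Jaccard on presence/absence: bounded
in [0, 1], symmetric, zero iff identical family sets. The classic
alternative −ln(shared / min(|A|, |B|)) is available; its zero-overlap
singularity is capped with a 0.5 pseudo-count. A genome with no
families is placed at maximal distance from everything and flagged.

## Distance trees

Alignment columns containing any gap are removed before distance
computation; an optional conservation filter additionally drops columns
whose modal residue frequency is strictly below a threshold (a column
exactly at the threshold is kept). Distances are uncorrected
p-distances by default — exact, model-free, and adequate for the
moderate divergences of concatenated core genes; the protein Kimura
correction d = −ln(1 − p − p²/5) is available behind a flag for deeper
divergences.

Neighbor joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with limb lengths from the
standard formulas and negative estimates clamped to zero. Q-ties
(within 1e-12 relative) are broken by the lexicographically smallest
pair of cluster keys, a cluster's key being its smallest member leaf
label — deterministic and order-invariant. On additive matrices the
algorithm is exact; the suite verifies topology and path-length
recovery to 1e-9 on randomly generated trees and cross-checks
topologies against scikit-bio's independent implementation on noisy
matrices.

Bootstrap support resamples alignment columns with replacement,
recomputes distances and the tree per replicate, and annotates each
internal branch of the full-data tree with the percentage of replicates
containing the same bipartition (default 1,000 replicates). Supports
are mapped onto the full-data tree rather than summarized as a
consensus. The column resampling depends only on the seed, never on row
order, so permuting taxa does not change supports.

## Wagner parsimony gain/loss reconstruction

Each family is reconstructed independently on the rooted guide tree by
a Sankoff dynamic program over integer copy counts 0..Cmax with branch
cost c(a→b) = g·max(b−a, 0) + max(a−b, 0): g is the gain penalty per
copy gained, each copy lost costs 1. Presence/absence data is the
Cmax = 1 special case; Cmax defaults to the largest observed leaf
count. The root takes its cheapest state and the backtrace selects, at
each node, the smallest child state achieving the parent's optimum.

Two penalty settings bracket the classic evolutionary scenarios: g = 1
treats gains and losses symmetrically (and on binary data reproduces
Fitch parsimony lengths, which the suite cross-checks against an
independent Fitch implementation), favoring small ancestors with
lineage-specific expansion; g = 5 makes independent acquisition
expensive, favoring large ancestors with subsequent reduction. Total
inferred gains are non-increasing, and losses non-decreasing, in g — a
monotonicity the suite verifies over g ∈ {0.5, 1, 2, 5, 10}.

**Ties.** Equally parsimonious reconstructions are resolved toward the
smaller ancestral state — deterministic, and conservative in that it
never asserts ancestral genes no descendant pattern demands. Families
whose optimum is not unique are flagged in the output. The convention
matters quantitatively: a family confined to exactly one of the root's
two child clades costs the same whether it was gained on its clade's
stem or present at the root and lost on the other stem, so the
tie-break resolves every such family away from the root. With
per-branch loss probability p this depresses the inferred root size by
roughly 2p·(number of families), the dominant term in the root-size
recovery error measured below.

**Correctness oracle.** The binding correctness check is exhaustive:
on 1,000 random instances (trees ≤ 6 leaves, counts ≤ 2) the DP
minimum must equal the minimum over every ancestral state assignment,
enumerated directly.

## Hallmark and core set algebra

Core families are present in every taxon. A hallmark of group G is
present in every member of G and absent from every non-member; an
anti-hallmark is absent from every member of G and present in all other
taxa. The definitions are strict by default — a single tolerated
missing member can hide a genuinely informative absence — with an
explicit `tolerance` parameter for exploration. Every family is
classified into exactly one of core / hallmark / anti-hallmark / other,
with that priority. No multiple-testing correction applies: the
procedure is set-algebraic, not inferential. Group labels are user
input and never inferred from the tree, because group membership of
borderline taxa is exactly what such analyses dispute.

## Synthetic data: what it emulates, and what it does not

The generator draws a random binary rooted tree (exponential branch
lengths, mean 0.1), seeds the root with `n_families_root` families, and
evolves presence/absence along each branch: every present family is
lost with probability 1 − exp(−loss_rate), every registered-but-absent
family gained with probability 1 − exp(−gain_rate), and each gain event
is redirected with probability 0.5 to a brand-new family — an open
pan-genome in which lineages keep acquiring genes nobody else has, the
dominant feature of real NCLDV gene repertoires. Event probabilities
are per branch, independent of branch length: each branch is one
evolutionary step, so expected content divergence is proportional to
topological path length, which is the regime in which a content-based
dendrogram is expected to mirror the tree.

Each present family at a leaf yields one protein: a copy of the
family's random ancestor sequence (length uniform in 120–180 aa, so the
100-aa query filter passes by default; a decoy option emits 50-aa
proteins to exercise the filter) mutated at `within_family_divergence`
substitutions per site. Hit tables score every within-family ordered
pair with its true ungapped identity, bit = 0.5 · identity% · length /
100 and E = 2^(−bit) · (database size) — a deliberately simple monotone
model; only the ordering matters downstream. Spurious between-family
hits are injected at a configurable rate and are sub-threshold by
construction (identity < 20%, E > 1e-5), so a correctly filtering
pipeline must remove every one.

Two limitations matter for interpreting green tests. First, sequences
follow a star model within each family — every member is mutated
independently from the family ancestor — so residues carry family
membership but no phylogenetic signal; the core-gene sequence tree on
synthetic data is not expected to match the true tree, and no test
asserts it. The sequence-tree machinery is validated instead on
constructed alignments with known signal. Second, there is no indel or
rate-variation model, so alignment trimming is exercised only lightly.
Passing tests demonstrate the correctness of the inference machinery
under the generative model's assumptions, not the adequacy of those
assumptions for any real virus set.

The truth ledger (ancestral contents, per-branch gained/lost family
sets, per-protein family labels) is checked for self-consistency by
replaying the events from the root. Everything is driven by one integer
seed; identical configurations produce byte-identical output files.

## Validation experiment sizes

The study-scale experiments use 18 taxa and 500 root families — the
scale of a realistic comparative panel. The end-to-end recovery run
uses gain and loss rates of 0.015 per branch (about 0.5 expected events
per family across the 34-branch tree) with no spurious hits: the
low-rate regime in which gene content retains enough signal for exact
tree recovery while parsimony's tie-induced root bias (see above) stays
within a few percent. Under these conditions the pipeline recovers the
true tree exactly (Robinson–Foulds 0), reproduces the truth content
matrix cell for cell, recovers every planted hallmark and
anti-hallmark, and the g = 1 root size lands within 5% of truth on
average over 20 seeds (mean error ≈ 3%). Generator defaults elsewhere
(rates 0.05) exercise the machinery at higher event densities.
Bootstrap uses 1,000 replicates in the pipeline default and the
per-gene trees use the nine lowest-numbered core families, matching
standard practice of building the concatenated tree from a small fixed
core set.

## Numerical choices

- E-value comparisons are strict (<); identity and length thresholds
  are inclusive (≥).
- NJ Q-ties and Wagner state ties resolve as described above; all other
  orderings (cluster ids, file rows) are lexicographic.
- Negative NJ branch-length estimates are clamped to zero.
- MCL prunes entries below 1e-12 during iteration and reads the
  attractor at 1e-6; inflation 2.0, tolerance 1e-6, max 200 iterations.
- Newick branch lengths are written with 10 significant digits, so
  write/read round trips preserve them to well under 1e-9.
- Degenerate inputs fail loudly: empty alignments after gap stripping,
  genomes with zero families, leaf/matrix label mismatches and
  malformed files all raise errors naming the offending item.
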