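# Methods

## Problem

Orthologs are genes that descend from their last common ancestor through a
speciation; paralogs descend through a duplication. Purely similarity-based
orthology detection at scale works on a graph of reciprocal near-best hits
and clusters it, which systematically confuses similar paralogs: when a
duplication precedes a speciation, all four copies look alike and end up in
one group. `synterho` adds conserved local gene order (synteny) as an
independent signal: among equally similar candidates, the partner that kept
the ancestral genomic neighborhood is preferred.

## Pipeline model

**1. Candidate graph.** For each ordered genome pair (A, B) and query gene
x in A, all hits y in B with

    s(x, y) >= f * max_z s(x, z)

are kept (bit scores; stringency `f`, default 0.95), subject to an E-value
cutoff (default 1e-5) and a minimum alignment coverage on both sequences
(default 0.5; the coverage default is this package's choice, exposed as
`--cov`). Only reciprocally surviving pairs become edges; the two directed
scores are averaged into one symmetric weight. Multiple HSPs per gene pair
collapse to the highest-scoring one. Within-species hits never become
edges. Setting `f = 0` disables the adaptive filter and keeps every
reciprocal hit that clears E-value and coverage.

**2. Gene-order filter.** Edges of one genome pair are pruned to a
near-matching that maximizes

    alpha * sum over conserved adjacencies sqrt(w(e) w(e'))
      + (1 - alpha) * sum over edges w(e)

with edge weights normalized by the pair's maximum weight. Two selected
edges form a conserved adjacency when their endpoints are neighbors in both
genomes' *projected* orders — the gene order after hiding genes that carry
no candidate edge, so unrelated intervening genes neither create nor break
adjacencies. Candidate edges are grouped into maximum common substrings
(MCSs): maximal runs occupying consecutive projected positions in both
genomes, forward or exactly reversed (both directions score identically;
the adjacency model is unoriented). The matching is built greedily by MCS
score with a total tie-break order (score desc, size desc, smallest
chromosome/rank of the first edge), splitting runs at conflicts; leftover
free edges are added as size-1 runs in descending weight. Because a
mid-weight run can lock genes needed by heavier isolated edges, the first
round finally compares its objective against a plain weight-greedy matching
and keeps whichever scores higher — the result is never worse than
similarity-only greedy matching.

*Duplicated regions*: the matching is repeated `n_iterations` times
(default 1 extra round) with previously selected edges removed; later
rounds accept only MCSs of at least `min_mcs_size` gene pairs (default 3)
and have no size-1 fallback, so only coherent duplicated blocks re-match.

*In-paralog relaxation*: if two chromosome neighbors x, y both have the
same best-scoring candidate z on the other side, both (x,z) and (y,z) are
emitted (flagged), deliberately breaking the matching property — x and y
are likely recent in-paralogs and choosing one by a marginal score
difference would be arbitrary. The relaxation is applied to neighbors in
either genome; the flagged edges are excluded from the one-to-one matching
used for breakpoint distances.

Chromosomes are treated as linear; a circular chromosome can be linearized
at an arbitrary cut at the cost of at most the two adjacencies spanning the
cut (a property the test suite checks by rotating circular orders).

**3. Clustering.** All pairwise pruned edge sets are merged (they are
disjoint by construction) and each connected component is tested: if the
algebraic connectivity of its weighted Laplacian, divided by component size
(normalization is switchable), reaches `conn_threshold` (default 0.1) the
component is an orthologous group; otherwise it is bisected by the sign of
the Fiedler vector (zero entries to the smaller side; ties to the side
holding the smallest gene id) and both sides recurse. Laplacian weights are
the normalized edge weights, keeping the threshold scale-free. Components
up to 10^4 nodes use a dense symmetric eigensolver; larger ones a seeded
iterative solver (tolerance 1e-8), with the contract that any eigenvalue
estimate within 1e-6 gives identical groups. The Laplacian is accumulated
in sorted edge order so results do not depend on graph insertion history.

## Synthetic data generator

The generator is first-class, tested code: it produces datasets whose true
orthology is known from event-labeled gene trees.

* **Species trees** grow under the Age Model: at each discrete step the
  leaf to speciate is drawn with probability proportional to its age; the
  tree is then rescaled so every root-to-leaf path has length exactly 1.
* **Gene content** starts as one ancestral gene per family in an ordered
  list at the root. Along each species-tree edge of length l, counts of
  gene duplications, cluster duplications, whole-genome duplications and
  losses are Poisson(rate * l) and applied in random order at uniform
  times. Defaults: r_dup 0.3, r_clusterdup 0.05, r_loss 0.3, r_genomedup 0
  (0.02 in the `F80d-like` preset), r_rearr 2.0 per unit branch length —
  chosen once to land in the regime of the reference benchmark datasets
  (tens of families across 20 species with visible paralogy). Single-gene
  duplicates are placed in tandem next to their source (creating exactly
  the neighbor-in-paralog situations the relaxation targets); cluster
  copies (geometric window, mean 4) and genome copies are appended as
  contiguous blocks and then shuffled by rearrangement. Each copy created
  on an edge is deleted again with probability 0.3 before the next
  speciation (redundant-duplicate purging); a copy of a still-recent copy
  inherits the purge risk.
* **Gene order** evolves by Poisson(r_rearr * l) inversions and
  translocations with geometric segment lengths (mean 3).
* **Sequences**: each family seeds a uniform-composition sequence of
  uniform length in [100, 1000] aa. Along a gene-tree edge of length l each
  site is substituted independently with probability branch_scale * l
  (branch_scale 0.5, i.e. about half the residues on a root-to-leaf path);
  the replacement residue is drawn from a PAM250-log-odds-derived
  conditional (with Dayhoff background frequencies), never the original, so
  the realized substitution fraction matches the Bernoulli rate exactly.
  Indels occur at 0.01 events/site/unit branch length with Zipf(1.7)
  lengths capped at a per-family fraction drawn from [1%, 10%] of the
  sequence length; deletions never reduce a sequence below length 1.
* **Truth**: two cross-species genes are orthologs iff the most recent
  common ancestor in their (pruned) gene tree is a speciation.

What the generator does *not* emulate: horizontal transfer, rate
heterogeneity across sites or lineages, codon-level structure, gene fission
/fusion, and unalignable domain shuffling. Passing tests on simulated data
therefore demonstrate the algorithmic behavior of the pipeline under the
stated evolutionary model, not its accuracy on real proteomes, where gene
orders decay faster relative to sequence divergence.

## Internal similarity search

An internal all-vs-all Smith–Waterman search (BLOSUM62, gap open 11 /
extend 1, via Biopython's pairwise aligner) lets the full pipeline run
without an external aligner. The reported score is a bit-like raw/2;
E-values use Karlin–Altschul statistics with the published gapped
BLOSUM62(11,1) constants (lambda 0.267, K 0.041). Alignments are scored
for every cross-species pair; coordinates (hence coverages) are computed by
traceback only for pairs passing a loose reporting threshold (E <= 1e-3),
which is the only pre-filter — downstream stringency is applied by the
candidate-graph stage. External BLAST tabular files are accepted
interchangeably.

## Evaluation framework

Predictions are scored over unordered cross-species gene pairs within a
fixed universe: all cross-species pairs among genes covered by the truth
set. tp/fp/tn/fn are counted there, and precision = tp/(tp+fp), recall =
tp/(tp+fn), accuracy = (tp+tn)/total, tn rate = tn/(tn+fp); ratios with
zero denominators are reported as undefined rather than 0. Group-only
references are converted to pairwise relations by declaring all
cross-species co-members orthologous, which strictly overestimates the
relation (a warning says so). The breakpoint-related distance between two
matched gene orders counts matched adjacencies of one genome whose partners
are not neighbors (either direction) in the other genome's matched-only
order, symmetrized as the maximum of the two directions; identical and
exactly reversed orders measure 0. Subdivision statistics report, per
reference group, how many predicted groups intersect it.

## Numerical and design choices

* The adjacency term uses the geometric mean sqrt(w w') of the two
  supporting normalized edge weights: adjacency credit is tied to the
  credibility of both edges and degenerates to adjacency counting for
  uniform weights. `alpha` defaults to 0.5; benchmark results are not
  strongly sensitive to it, and it is exposed as `--alpha`.
* All randomness flows from one `numpy` PCG64 generator per simulation;
  identical seeds give byte-identical datasets and pipeline outputs, for
  any worker count (per-pair results are collected in sorted pair order).
* Degenerate inputs: empty candidate graphs, genomes without coordinates
  (such genes join similarity filtering but never form or block
  adjacencies), zero-length branches and single-gene components are all
  defined no-ops rather than errors.
* Scale of the shipped checks: the test suite and the acceptance script
  use 5–10 species with 6–20 families and sequence lengths of 100–1000 aa,
  sizes chosen so a complete run stays in the minutes range on one core
  while still containing duplications, losses and rearrangements; rates
  and sequence parameters are the defaults above, not reduced.

## Known limitations

* The gene-order matching is a greedy heuristic; it is guaranteed to reach
  the weight-greedy baseline but not the exact FF-Adjacencies optimum
  (tests verify the bracket on exhaustively enumerable toys).
* MCS runs require strictly consecutive projected positions; a gapped or
  common-intervals synteny notion would be more permissive and is not
  implemented.
* Strand information is read and stored but unused: the adjacency model is
  unoriented.
* E-values of the internal aligner are analytic approximations, not
  empirically calibrated per database size, and are only used for
  thresholding.
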