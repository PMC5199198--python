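# Methods

## Problem and model

A proteome here is the complete protein complement of one genome
assembly. Redundancy is defined between proteomes of the same species
group (species plus its strains, sub-strains and isolates): proteome B
is redundant to proteome A when the length-weighted similarity

S(A, B) = Σ_{b∈B} length(b)·AS₉₀(A, b) / Σ_{b∈B} length(b)

reaches 0.9. AS₉₀(A, b) is the alignment identity of query protein b to
the longest protein of A that aligns at ≥ 90% identity; when no protein
of A qualifies, AS₉₀ = 0, so unmatched proteins drag the score down
with their full length. Weighting by length reflects that losing a long
protein's information matters more than losing a short one's.

Redundancy is neither symmetric (a plasmid-free strain can be contained
in its parent but not conversely) nor transitive, so above-threshold
comparisons form a *directed* redundancy graph. Selecting non-redundant
proteomes means finding a dominating set: every removed node must keep
an original out-edge to a survivor, so its content remains represented.
Minimum dominating set is NP-hard; a reasonable, deterministic
heuristic suffices because the goal is scalable redundancy removal, not
optimality.

## Greedy matching

Each query protein is compared against the subject's proteins sorted by
descending length (ties by ascending protein id, for determinism), and
the first seed reaching the identity threshold is taken — which, given
the ordering, is the longest qualifying seed required by the AS₉₀
definition. Identity is computed from a global end-to-end alignment
that maximizes the number of identical aligned columns (match +1,
mismatch 0, gaps free), divided by the length of the shorter sequence —
the convention of greedy incremental clustering tools. With this
scoring an exact subsequence scores identity 1, and percent identity
of point-mutated pairs equals the unmutated fraction (up to the rare
extra residue a gap can recover). The alignment score is computed with
Biopython's `PairwiseAligner`; the test suite checks it against an
independent dynamic-programming oracle.

A counting word filter skips seed/query pairs that provably cannot
reach the threshold: a pair at identity c over shorter length L has at
most ⌈(1−c)·L⌉ mismatched columns, each destroying at most w of the
L−w+1 words of length w, so at least L − w·⌈(1−c)·L⌉ − w + 1 shared
words must remain. A pair sharing fewer is rejected without alignment;
the bound is conservative, so filtering never changes match results
(property-tested). Word size defaults to 5, the customary choice for
identity thresholds this high; smaller words weaken the filter's
rejection power, longer words would make the bound vacuous for short
proteins.

## Comparison-space pruning

Two heuristics keep the quadratic pair space tractable. Proteomes are
compared only within their species group — within-species similarities
cluster near 1 while cross-species pairs fall below the threshold, so
cross-group comparisons are wasted work. The species group id is an
input column, not derived from a taxonomy dump, keeping the tool
self-contained. Second, the size heuristic: S(A, B) is computed only
when 0.9·|B| ≤ |A| (counts of proteins); a query more than ~11% larger
than the subject necessarily leaves too many proteins unmatched to
reach 0.9. The direction convention is fixed throughout: the query B is
the proteome being tested for redundancy, and its proteins form the
numerator of S.

## Graph reduction

Nodes are ranked by the quintuple (indegree, outdegree, priority score,
annotation level, previous state), compared lexicographically — higher
indegree wins, then lower outdegree, then reference status (priority 2
vs 1), then count of curator-reviewed entries, then having been
non-redundant in the previous run. Degrees are counted on the surviving
subgraph and recomputed after every elimination. The loop removes the
lowest-ranked *removable* node: not protected, having at least one
surviving out-neighbour, and not the last surviving representative of
any already-removed node. On rank ties the node with the smaller
represented set is removed (keeping the node that covers the more
comprehensive set of removed proteomes); exact ties fall to a seeded
random generator, making runs reproducible — the seed is a
configuration value (default 0). Representation follows original direct
out-edges only and is never re-routed transitively: when a
representative is itself later removed, the nodes it represented keep
their own (shrinking, never emptied) sets of surviving original
neighbours. The edge threshold is applied with 1e−12 absolute tolerance
so a similarity arriving at exactly 0.9 through floating-point
arithmetic is not dropped by representation error.

The priority-vs-annotation precedence cannot be distinguished by the
method's reference ranking examples (the favoured vector wins on both); the
listed parameter order is adopted.

## Incremental updates and reinstatement

Redundant proteomes are retained, not discarded. An update compares
only the pairs involving new proteomes (both orientations, same
heuristics), reuses old comparison records, rebuilds the graph, sets
each old proteome's previous-state term from its prior status, and
re-runs the reduction. The previous-state term damps oscillation: with
no new data, prior survivors outrank prior removals at every tie, and
statuses are reproduced. Because previously redundant proteomes remain
in the pool, a newcomer similar only to one of them can force its
reinstatement (it becomes the newcomer's last possible representative).
All incoming ids must be new; merging re-assembled versions of an
existing proteome is out of scope.

## Synthetic data

The generator emulates the dominant real-world redundancy pattern:
families of near-identical strain proteomes. A base proteome of
uniform-random sequences (default 50 proteins of 100–400 aa, the span
of typical bacterial protein lengths) spawns strains by (i) point
substitutions under an exact-count model — exactly round(rate·L)
positions per protein changed to a different residue, so per-protein
identity is analytically 1 − rate rather than merely in expectation,
making threshold logic testable without tolerances; (ii) random gene
loss; (iii) random gene gain. Each family is one species group. At the
default 1% divergence every within-family similarity sits near 0.98–0.99,
far above threshold, so ground truth is one survivor per family; at 20%
divergence every identity falls below 0.9 and ground truth is all
non-redundant. The base proteome receives a nonzero annotation level
(default 10 reviewed entries, strains 0), mirroring the fact that the
originally sequenced strain is the curated one; this makes the expected
survivor well-defined instead of falling to the random tie-break.

What the generator does not emulate: indels, paralogous families,
horizontal transfer, shared genes between species groups, and realistic
length or composition distributions. Passing the synthetic-recovery
checks therefore demonstrates the pipeline's threshold logic, graph
construction and reduction — not robustness to alignment ambiguity in
real proteomes, which enters only through the identity definition.

A second constructed fixture, `generate_isolate_pair`, reproduces the
textbook two-proteome illustration: four proteins of lengths 545, 393,
130 and 75 with exactly 8, 1, 0 and 0 substitutions, i.e. identities
0.9853/0.9975/1.0/1.0 and S = 1134/1143 ≈ 0.9921. The constructor
verifies each engineered identity by alignment (resampling positions in
the rare case a gapped alignment recovers an extra match), so the
fixture's ground truth is exact by construction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| identity_threshold | 0.9 | minimum per-protein alignment identity for a match |
| similarity_threshold | 0.9 | minimum S(A,B) for a redundancy-graph edge |
| size_factor | 0.9 | perform comparison iff factor·\|query\| ≤ \|subject\| |
| word_size | 5 | k-mer length of the pre-alignment filter |
| seed | 0 | reduction tie-break seed |

The two 0.9 thresholds are the method's canonical operating point,
chosen to capture only closely related organisms; they are exposed for
sensitivity analysis but the defaults are the intended conditions.

## Verification problem sizes

The acceptance checks run the worked four-protein example, 200 random
digraphs of up to 12 nodes (where an exhaustive-subset search provides
the exact minimum dominating-set size), and the five-family synthetic
collection (50 proteomes, 2 500 proteins, ~4 500 performed pairwise
proteome comparisons). These sizes exercise every code path — greedy
matching, both heuristics, graph construction, protected nodes,
tie-breaking, reinstatement — while remaining desk-scale; redundancy removal at the
scale of a full public protein knowledgebase requires the corpus itself
and is out of scope here.

## Known limitations

- The identity definition (free gaps, shorter-length denominator) is
  one of several conventions; tools using banded or penalized
  alignments can report slightly different identities near the
  threshold.
- The greedy reduction gives no approximation guarantee on dominating
  set size; it is validated empirically against the exact minimum on
  small graphs only.
- Single-process execution; per-group independence makes the
  computation embarrassingly parallel, and results are contractually
  independent of any scheduling.
- `update` treats every incoming proteome id as new; versioned
  re-submissions of an existing proteome must be renamed or removed
  upstream.
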