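# prm — proteome redundancy minimization

Large-scale sequencing of near-identical bacterial strains (outbreak
isolates, sub-strains, re-assemblies) floods protein databases with
proteomes that are all but copies of one another. Redundancy slows
searches, biases statistics and inflates every downstream analysis.
`prm` identifies a minimal set of *non-redundant* representative
proteomes within each species group and flags the rest as redundant,
while guaranteeing that every removed proteome keeps a surviving
representative.

The method has two stages:

**1. Pairwise proteome comparison.** Within a species group, every
ordered pair (A, B) is scored with a length-weighted similarity

    S(A, B) = Σ_{b∈B} length(b) · AS₉₀(A, b) / Σ_{b∈B} length(b)

where AS₉₀(A, b) is the alignment identity of protein b (from the query
proteome B) to the longest protein of the subject proteome A reaching at
least 90% identity, and 0 if none does. Matching is greedy: each query
protein is scanned against A's proteins in descending length order (a
k-mer filter skips hopeless pairs) until the first hit at ≥ 90%
identity. S is asymmetric — a proteome contained in a larger one scores
1 against it, not vice versa. A size heuristic skips queries more than
~11% larger than the subject, and proteomes in different species groups
are never compared.

**2. Dominating-set reduction.** Pairs with S(A, B) ≥ 0.9 form a
directed *redundancy graph* (edge B → A means "B is redundant to A").
The survivors must form a dominating set: every removed node keeps an
original out-edge to a survivor. Since the minimum dominating set is
NP-hard, the reduction is greedy: nodes are ranked by the quintuple
(indegree ↑, outdegree ↓, priority score ↑, annotation level ↑,
previous redundancy state ↑), compared lexicographically on the
surviving subgraph; the weakest removable node is eliminated, its
surviving out-neighbours inherit a reference to it, ranks are
recomputed, and the loop repeats. Reference proteomes (and an optional
immune list) are protected. Previously redundant proteomes stay in the
comparison pool and can be *reinstated* by later updates.

## Worked example

The classic illustration is a small phage proteome A and its isolate B,
four proteins each, with per-protein identities 98.53%, 99.75%, 100%
and 100% over lengths 545, 393, 130 and 75:

```python
>>> from prm import similarity_score
>>> similarity_score([(545, 0.9853), (393, 0.9975), (130, 1.0), (75, 1.0)])
0.9921312335958004
```

S = 0.9921 ≥ 0.9, so B is redundant to A. The same number emerges from
sequences: `prm.simulate.generate_isolate_pair()` builds such a pair with
exactly 8 and 1 substitutions in the two longer proteins, and
`compare_group` recovers S(A, B) = 1134/1143 ≈ 0.9921 from the alignments.

End-to-end, on a synthetic collection of 5 strain families (each one
base proteome of 50 proteins, 100–400 aa, plus 9 strains at 1%
divergence):

```bash
$ prm simulate data/ --families 5 --strains 9 --proteins 50
$ prm run data/ data/metadata.tsv results/
45 redundant, 5 non-redundant; results in results/
```

Exactly one proteome per family survives; the other 45 are flagged
redundant, each listing a same-family survivor as its representative in
`results/results.tsv`. `prm compare` and `prm reduce` expose the two
stages separately; `prm update` folds new proteomes into a previous run
incrementally.

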