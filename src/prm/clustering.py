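"""Greedy asymmetric clustering of a query proteome against subject seeds.

Each protein of the query proteome B is compared against the proteins of
the subject proteome A ("seeds"), scanned in descending length order, until
the first seed reaching the identity threshold (default 90%) is found.
Because seeds are scanned longest-first, the reported match is the longest
qualifying seed, and its identity is the per-protein similarity AS90(A, b)
that feeds the proteome similarity score.  Proteins with no qualifying seed
get AS90 = 0.

A k-mer counting filter skips seed/query pairs whose shared word count is
provably too small to reach the threshold; it never rejects a pair that
does reach it, so matching with and without the filter is identical.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

from .model import ProteinRecord, Proteome

DEFAULT_IDENTITY_THRESHOLD = 0.9
DEFAULT_WORD_SIZE = 5


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    # Global alignment maximizing identical columns: match +1, mismatch 0,
    # gap 0.  The optimal score is then the number of identical aligned
    # residues; gapped columns never count as identical.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity of two sequences.

    Identity = (maximum number of identical aligned columns over all
    end-to-end alignments) / (length of the shorter sequence) — the
    shorter-sequence denominator used by greedy incremental clusterers.
    Symmetric in its arguments and 1.0 when one sequence is an exact
    subsequence of the other.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches = _aligner().score(seq_a, seq_b)
    return matches / min(len(seq_a), len(seq_b))


def shared_word_count(seq_a: str, seq_b: str, word_size: int) -> int:
    """Number of k-mer positions of ``seq_a`` whose word occurs in ``seq_b``."""
    if word_size < 2:
        raise ValueError("word_size must be >= 2")
    words_b = {seq_b[i:i + word_size] for i in range(len(seq_b) - word_size + 1)}
    return sum(
        1 for i in range(len(seq_a) - word_size + 1)
        if seq_a[i:i + word_size] in words_b
    )


def min_shared_words(shorter_length: int, word_size: int,
                     identity_threshold: float) -> int:
    """Lower bound on shared k-mers for a pair at the identity threshold.

    A pair at identity c over shorter length L has at most ceil((1-c)*L)
    differing positions; each destroys at most ``word_size`` of the
    L - word_size + 1 words of the shorter sequence, leaving at least
    L - word_size*ceil((1-c)*L) - word_size + 1 intact shared words.
    """
    mismatches = math.ceil((1.0 - identity_threshold) * shorter_length)
    return max(0, shorter_length - word_size * mismatches - word_size + 1)


def word_filter_passes(query: ProteinRecord, seed: ProteinRecord,
                       word_size: int = DEFAULT_WORD_SIZE,
                       identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                       ) -> bool:
    """True unless the shared-word count rules out identity >= threshold."""
    shorter = min(query.length, seed.length)
    bound = min_shared_words(shorter, word_size, identity_threshold)
    if bound == 0:
        return True
    if query.length <= seed.length:
        shared = shared_word_count(query.sequence, seed.sequence, word_size)
    else:
        shared = shared_word_count(seed.sequence, query.sequence, word_size)
    return shared >= bound


@dataclass(frozen=True)
class MatchResult:
    """Greedy match of one query protein: longest seed at >= threshold identity.

    ``identity`` is AS90(A, b): 0 when no seed qualifies, otherwise the
    alignment identity to the matched seed.
    """

    query_protein_id: str
    query_length: int
    matched_seed_id: str | None
    identity: float

    def __post_init__(self) -> None:
        if (self.matched_seed_id is None) != (self.identity == 0.0):
            raise ValueError(
                "matched_seed_id must be None exactly when identity is 0")


@dataclass
class SeedIndex:
    """Subject proteins sorted longest-first, with an inverted k-mer index."""

    subject_proteome_id: str
    seeds: list[ProteinRecord]
    word_index: dict[str, list[int]]  # k-mer -> indices into seeds
    word_size: int = DEFAULT_WORD_SIZE
    # distinct-word Counters per seed, parallel to seeds
    _seed_words: list[set[str]] = field(default_factory=list, repr=False)


def build_seed_index(subject: Proteome,
                     word_size: int = DEFAULT_WORD_SIZE) -> SeedIndex:
    """Index the subject's proteins as cluster seeds.

    Seeds are ordered by descending length, ties broken by ascending
    protein id, so a greedy longest-first scan is deterministic.
    """
    seeds = sorted(subject.proteins, key=lambda p: (-p.length, p.protein_id))
    word_index: dict[str, list[int]] = {}
    seed_words: list[set[str]] = []
    for idx, seed in enumerate(seeds):
        words = {
            seed.sequence[i:i + word_size]
            for i in range(len(seed.sequence) - word_size + 1)
        }
        seed_words.append(words)
        for w in words:
            word_index.setdefault(w, []).append(idx)
    return SeedIndex(subject.proteome_id, seeds, word_index, word_size,
                     seed_words)


def match_sequences(query: Proteome, index: SeedIndex,
                    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                    use_word_filter: bool = True) -> list[MatchResult]:
    """Greedily match every query protein against the seed index.

    For each query protein the seeds are scanned in index (longest-first)
    order; pairs excluded by the word filter are skipped without
    alignment; the first seed whose alignment identity reaches the
    threshold is recorded.  Queries with no qualifying seed get identity 0.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    results: list[MatchResult] = []
    for protein in query.proteins:
        qlen = protein.length
        shared: dict[int, int] | None = None
        if use_word_filter:
            # Count, for every seed at once, how many query word positions
            # occur in that seed (same count word_filter_passes uses).
            shared = {}
            seq = protein.sequence
            w = index.word_size
            for i in range(qlen - w + 1):
                for seed_idx in index.word_index.get(seq[i:i + w], ()):
                    shared[seed_idx] = shared.get(seed_idx, 0) + 1
        match: MatchResult | None = None
        for seed_idx, seed in enumerate(index.seeds):
            if shared is not None:
                shorter = min(qlen, seed.length)
                bound = min_shared_words(shorter, index.word_size,
                                         identity_threshold)
                if shared.get(seed_idx, 0) < bound:
                    continue
            identity = pairwise_identity(protein.sequence, seed.sequence)
            if identity >= identity_threshold:
                match = MatchResult(protein.protein_id, qlen,
                                    seed.protein_id, identity)
                break
        if match is None:
            match = MatchResult(protein.protein_id, qlen, None, 0.0)
        results.append(match)
    return results
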