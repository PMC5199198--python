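"""Proteome similarity score and the comparison-space pruning heuristics.

The similarity of proteome B (the query, tested for redundancy) to proteome
A (the subject) is the length-weighted mean of per-protein identities::

    S(A, B) = sum_b length(b) * AS90(A, b) / sum_b length(b)

over all proteins b of B, where AS90(A, b) is the identity of b to the
longest protein of A reaching at least 90% identity, and 0 when no protein
of A qualifies.  Unmatched proteins therefore pull the score down with
their full length.  S is not symmetric: a proteome whose proteins are a
subset of a larger one scores 1 against it, while the reverse direction
scores lower.

Two heuristics prune the quadratic comparison space: proteomes are only
ever compared within their species group (strains, sub-strains, isolates),
and a query more than 10% larger than the subject is skipped, since enough
of its proteins would necessarily be unmatched to keep S below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .clustering import (
    DEFAULT_IDENTITY_THRESHOLD,
    DEFAULT_WORD_SIZE,
    build_seed_index,
    match_sequences,
)
from .model import Proteome

DEFAULT_SIZE_FACTOR = 0.9

COMPARISON_COLUMNS = ["subject_id", "query_id", "similarity", "performed"]


@dataclass(frozen=True)
class ComparisonRecord:
    """One ordered proteome comparison: S(subject, query), or a skip."""

    subject_id: str
    query_id: str
    similarity: float | None
    performed: bool

    def __post_init__(self) -> None:
        if self.subject_id == self.query_id:
            raise ValueError("self-comparisons are excluded")
        if self.performed and not (0.0 <= self.similarity <= 1.0):
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")
        if not self.performed and self.similarity is not None:
            raise ValueError("skipped comparison cannot carry a similarity")


def similarity_score(weighted_matches: Sequence[tuple[int, float]]) -> float:
    """Length-weighted mean identity over the query's proteins.

    ``weighted_matches`` holds one (length, identity) pair per query
    protein; unmatched proteins contribute identity 0 with their full
    length in the denominator.
    """
    if not weighted_matches:
        raise ValueError("a proteome has at least one protein")
    num = 0.0
    den = 0
    for length, identity in weighted_matches:
        if length < 1:
            raise ValueError(f"protein length must be >= 1, got {length}")
        if not 0.0 <= identity <= 1.0:
            raise ValueError(f"identity {identity} outside [0, 1]")
        num += length * identity
        den += length
    return num / den


def size_heuristic(query_count: int, subject_count: int,
                   factor: float = DEFAULT_SIZE_FACTOR) -> bool:
    """Decide whether S(subject, query) is worth computing.

    The comparison is performed iff ``factor * query_count <=
    subject_count``: when the query has over 1/factor times more proteins
    than the subject, too many of its proteins must go unmatched for it to
    be redundant, so the comparison is skipped.
    """
    if query_count < 1 or subject_count < 1:
        raise ValueError("protein counts must be >= 1")
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must be in (0, 1]")
    return factor * query_count <= subject_count


def group_by_species(proteomes: Iterable[Proteome]) -> dict[str, list[str]]:
    """Partition proteome ids by species group; only within-group pairs compare."""
    groups: dict[str, list[str]] = {}
    for proteome in proteomes:
        groups.setdefault(proteome.species_group_id, []).append(
            proteome.proteome_id)
    return groups


def compare_pair(subject: Proteome, query: Proteome,
                 identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                 word_size: int = DEFAULT_WORD_SIZE,
                 seed_index=None) -> float:
    """Compute S(subject, query) via greedy matching of the query's proteins."""
    index = seed_index if seed_index is not None else build_seed_index(
        subject, word_size)
    matches = match_sequences(query, index, identity_threshold)
    return similarity_score([(m.query_length, m.identity) for m in matches])


def compare_group(group: Sequence[Proteome],
                  identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                  size_factor: float = DEFAULT_SIZE_FACTOR,
                  word_size: int = DEFAULT_WORD_SIZE,
                  ) -> list[ComparisonRecord]:
    """Evaluate every ordered pair of one species group.

    For each ordered pair (subject, query) passing the size heuristic the
    full similarity S(subject, query) is computed; skipped pairs are
    emitted as non-performed records.  Each subject's seed index is built
    at most once.
    """
    records: list[ComparisonRecord] = []
    indexes: dict[str, object] = {}
    for subject in group:
        for query in group:
            if subject.proteome_id == query.proteome_id:
                continue
            if not size_heuristic(len(query), len(subject), size_factor):
                records.append(ComparisonRecord(
                    subject.proteome_id, query.proteome_id, None, False))
                continue
            if subject.proteome_id not in indexes:
                indexes[subject.proteome_id] = build_seed_index(
                    subject, word_size)
            similarity = compare_pair(
                subject, query, identity_threshold,
                seed_index=indexes[subject.proteome_id])
            records.append(ComparisonRecord(
                subject.proteome_id, query.proteome_id, similarity, True))
    return records


def write_comparisons(records: Iterable[ComparisonRecord],
                      path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "query_id": r.query_id,
            "similarity": "" if r.similarity is None else repr(r.similarity),
            "performed": int(r.performed),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COMPARISON_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_comparisons(path: str | Path) -> list[ComparisonRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        performed = bool(int(row.performed))
        sim = None
        if performed:
            sim = float(row.similarity)
        records.append(ComparisonRecord(
            str(row.subject_id), str(row.query_id), sim, performed))
    return records
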