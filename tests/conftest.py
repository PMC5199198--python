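"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from prm import Proteome, ProteinRecord, ProteomeMetadata

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def max_identical_matches(a: str, b: str) -> int:
    """Independent dynamic-programming oracle for the alignment score.

    Computes the maximum number of identical aligned columns over all
    global alignments with free gaps — the classic O(nm) recurrence,
    written without any alignment library.
    """
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            best = prev[j - 1] + (1 if ai == b[j - 1] else 0)
            if prev[j] > best:
                best = prev[j]
            if cur[j - 1] > best:
                best = cur[j - 1]
            cur[j] = best
        prev = cur
    return prev[m]


def random_protein(rng: np.random.Generator, length: int,
                   protein_id: str = "p1") -> ProteinRecord:
    seq = "".join(rng.choice(list(AA20), size=length))
    return ProteinRecord(protein_id, seq)


def substitute_exact(sequence: str, n_sub: int,
                     rng: np.random.Generator) -> str:
    """Substitute exactly n_sub positions, each to a different residue."""
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    chars = list(sequence)
    for pos in positions:
        options = [c for c in AA20 if c != chars[pos]]
        chars[pos] = options[rng.integers(len(options))]
    return "".join(chars)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_proteome() -> Proteome:
    """Four proteins with the worked-example length profile."""
    rng = np.random.default_rng(11)
    proteins = [
        random_protein(rng, length, f"g{i}")
        for i, length in enumerate([545, 393, 130, 75], start=1)
    ]
    return Proteome("toy", "sp1", proteins)


@pytest.fixture
def reference_metadata() -> ProteomeMetadata:
    return ProteomeMetadata.reference(annotation_level=100)
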