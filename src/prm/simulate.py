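"""Synthetic proteome families with known ground-truth redundancy.

Emulates collections of near-identical bacterial strain proteomes: each
family is one base proteome plus strains diverged from it by point
substitutions, gene loss and gene gain.  Substitutions follow an
exact-count model — each retained protein has exactly round(rate * length)
positions changed to a different residue — so the identity of a strain
protein to its base copy is analytically 1 - rate, and the expected
redundancy labels follow directly from the similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    AMINO_ACIDS,
    Proteome,
    ProteomeMetadata,
    ProteinRecord,
    write_metadata_table,
    write_proteome_fasta,
)

_ALPHABET = np.array(sorted(AMINO_ACIDS))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic strain family.

    ``substitution_rate`` is the per-residue divergence of every strain
    from the base; ``gene_loss_fraction`` and ``gene_gain_count`` model
    gene content differences between strains.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (100, 400)
    n_strains: int = 9
    substitution_rate: float = 0.01
    gene_loss_fraction: float = 0.0
    gene_gain_count: int = 0
    seed: int = 0
    #: Reviewed-entry count given to the base proteome (strains get 0), so
    #: the base outranks its strains and is the expected family survivor.
    base_annotation_level: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0.0 <= self.gene_loss_fraction < 1.0:
            raise ValueError("gene_loss_fraction must be in [0, 1)")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def generate_base_proteome(n_proteins: int,
                           length_range: tuple[int, int] = (100, 400),
                           seed: int = 0,
                           proteome_id: str = "base",
                           species_group_id: str = "sp1",
                           metadata: ProteomeMetadata | None = None,
                           lengths: list[int] | None = None,
                           ) -> Proteome:
    """Generate a proteome of i.i.d. uniform-residue proteins.

    Protein lengths are sampled uniformly from ``length_range`` (inclusive
    (min, max) pair) unless an explicit per-protein ``lengths`` list is
    given.
    """
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = rng.integers(length_range[0], length_range[1] + 1,
                               size=n_proteins)
    elif len(lengths) != n_proteins:
        raise ValueError("lengths must have one entry per protein")
    proteins = [
        ProteinRecord(f"{proteome_id}_g{i + 1:04d}",
                      _random_sequence(rng, int(length)))
        for i, length in enumerate(lengths)
    ]
    return Proteome(proteome_id, species_group_id, proteins,
                    metadata or ProteomeMetadata())


def mutate_sequence(sequence: str, substitution_rate: float,
                    rng: np.random.Generator) -> str:
    """Substitute exactly round(rate * length) positions to other residues."""
    n_sub = int(round(substitution_rate * len(sequence)))
    if n_sub == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    chars = list(sequence)
    for pos in positions:
        alternatives = [a for a in _ALPHABET if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def mutate_strain(base: Proteome, substitution_rate: float = 0.01,
                  gene_loss_fraction: float = 0.0,
                  gene_gain_count: int = 0, seed: int = 0,
                  proteome_id: str | None = None,
                  metadata: ProteomeMetadata | None = None) -> Proteome:
    """Derive one strain proteome from a base proteome.

    floor(gene_loss_fraction * n) proteins are dropped (chosen at random),
    every retained protein is point-substituted at the exact-count rate,
    and ``gene_gain_count`` novel random proteins (lengths drawn from the
    base's length distribution) are appended.
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    if not 0.0 <= gene_loss_fraction < 1.0:
        raise ValueError("gene_loss_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pid = proteome_id or f"{base.proteome_id}_strain{seed}"
    n_loss = int(gene_loss_fraction * len(base.proteins))
    keep = np.ones(len(base.proteins), dtype=bool)
    if n_loss:
        lost = rng.choice(len(base.proteins), size=n_loss, replace=False)
        keep[lost] = False
    proteins = [
        ProteinRecord(p.protein_id.replace(base.proteome_id, pid, 1),
                      mutate_sequence(p.sequence, substitution_rate, rng))
        for p, kept in zip(base.proteins, keep) if kept
    ]
    base_lengths = [p.length for p in base.proteins]
    for i in range(gene_gain_count):
        length = int(base_lengths[rng.integers(len(base_lengths))])
        proteins.append(ProteinRecord(f"{pid}_novel{i + 1:03d}",
                                      _random_sequence(rng, length)))
    return Proteome(pid, base.species_group_id, proteins,
                    metadata or ProteomeMetadata())


def generate_family(spec: FamilySpec, family_id: str = "fam1",
                    ) -> list[Proteome]:
    """One base proteome plus ``n_strains`` derived strains, one species group."""
    base = generate_base_proteome(
        spec.n_proteins, spec.length_range, spec.seed,
        proteome_id=f"{family_id}_base", species_group_id=family_id,
        metadata=ProteomeMetadata(
            annotation_level=spec.base_annotation_level))
    strains = [
        mutate_strain(base, spec.substitution_rate, spec.gene_loss_fraction,
                      spec.gene_gain_count, seed=spec.seed + 1 + i,
                      proteome_id=f"{family_id}_s{i + 1:02d}")
        for i in range(spec.n_strains)
    ]
    return [base] + strains


def generate_family_collection(specs: list[FamilySpec],
                               ) -> tuple[list[Proteome], dict[str, str]]:
    """Generate several families and their expected redundancy labels.

    Each family gets its own species group id.  Ground truth: when the
    divergence keeps within-family similarities at or above the 0.9
    threshold, exactly one proteome per family is expected to survive and
    the rest to be redundant; when divergence pushes similarity below
    threshold, every proteome is expected non-redundant.
    """
    if not specs:
        raise ValueError("at least one family spec required")
    proteomes: list[Proteome] = []
    labels: dict[str, str] = {}
    for i, spec in enumerate(specs):
        family_id = f"fam{i + 1}"
        members = generate_family(spec, family_id)
        proteomes.extend(members)
        collapses = (
            1.0 - spec.substitution_rate >= 0.9
            and spec.gene_loss_fraction == 0.0
            and spec.gene_gain_count == 0
        )
        for j, member in enumerate(members):
            if not collapses or j == 0:
                labels[member.proteome_id] = "non-redundant"
            else:
                labels[member.proteome_id] = "redundant"
    return proteomes, labels


def generate_isolate_pair(lengths: tuple[int, ...] = (545, 393, 130, 75),
                          substitutions: tuple[int, ...] = (8, 1, 0, 0),
                          seed: int = 0,
                          species_group_id: str = "phage",
                          ) -> tuple[Proteome, Proteome]:
    """A base proteome and an isolate with exact per-protein divergence.

    Protein i of the isolate carries exactly ``substitutions[i]`` point
    substitutions, and the construction is verified (resampling positions
    if a coincidental alignment recovers extra matches) so that the
    global-alignment identity of each protein pair is exactly
    (length - substitutions) / length.  The defaults emulate a small
    phage-sized proteome and its near-identical isolate: per-protein
    identities (0.9853, 0.9975, 1.0, 1.0) over lengths (545, 393, 130,
    75), giving a length-weighted proteome similarity of 0.9921.
    """
    from .clustering import pairwise_identity

    if len(lengths) != len(substitutions):
        raise ValueError("need one substitution count per protein")
    rng = np.random.default_rng(seed)
    base = generate_base_proteome(
        len(lengths), seed=seed, proteome_id="A",
        species_group_id=species_group_id, lengths=list(lengths))
    isolate_proteins = []
    for protein, n_sub in zip(base.proteins, substitutions):
        target = (protein.length - n_sub) / protein.length
        for _ in range(100):
            rate = n_sub / protein.length
            mutated = mutate_sequence(protein.sequence, rate, rng)
            if pairwise_identity(protein.sequence, mutated) == target:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not realise the exact divergence")
        isolate_proteins.append(
            ProteinRecord(protein.protein_id.replace("A_", "B_", 1), mutated))
    isolate = Proteome("B", species_group_id, isolate_proteins)
    return base, isolate


def write_collection(proteomes: list[Proteome], out_dir: str | Path,
                     labels: dict[str, str] | None = None) -> None:
    """Write per-proteome FASTAs, the metadata TSV and optional truth labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for proteome in proteomes:
        write_proteome_fasta(proteome, out_dir / f"{proteome.proteome_id}.fasta")
        entries[proteome.proteome_id] = (proteome.species_group_id,
                                         proteome.metadata)
    write_metadata_table(entries, out_dir / "metadata.tsv")
    if labels is not None:
        with open(out_dir / "ground_truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("proteome_id\texpected_status\n")
            for pid in sorted(labels):
                fh.write(f"{pid}\t{labels[pid]}\n")
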