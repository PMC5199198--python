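"""Domain types for proteins and proteomes, plus FASTA and table I/O.

A :class:`Proteome` is the unit of redundancy analysis: the complete set of
protein sequences derived from one genome assembly, together with the
metadata used to rank it against other proteomes of the same species group
(reference status, priority score, annotation level and the redundancy
status it held in a previous run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Twenty standard amino acids plus the ambiguity/rare codes B, Z, X, U, O
#: used in curated protein databases.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ACCEPTED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBZXUO")

METADATA_COLUMNS = [
    "proteome_id",
    "species_group_id",
    "is_reference",
    "priority_score",
    "annotation_level",
    "previous_state",
]


class ProteomeError(ValueError):
    """Raised for malformed proteomes, metadata or result tables."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its identifier.

    Parameters
    ----------
    protein_id
        Non-empty token, unique within its proteome.
    sequence
        Upper-case amino-acid string over the accepted residue alphabet.
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ProteomeError("protein_id must be non-empty")
        if not self.sequence:
            raise ProteomeError(f"protein {self.protein_id!r}: empty sequence")
        for pos, residue in enumerate(self.sequence, start=1):
            if residue not in ACCEPTED_RESIDUES:
                raise ProteomeError(
                    f"protein {self.protein_id!r}: invalid residue "
                    f"{residue!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        """Residue count of the sequence."""
        return len(self.sequence)


@dataclass(frozen=True)
class ProteomeMetadata:
    """Ranking metadata for one proteome.

    ``priority_score`` is 2 for curator-designated reference proteomes and 1
    otherwise.  ``annotation_level`` counts the curator-reviewed entries of
    the proteome.  ``previous_state`` is 1 when the proteome was
    non-redundant in the previous run (the default for never-seen
    proteomes) and 0 when it was redundant; it damps oscillation of
    redundancy status between successive runs.
    """

    is_reference: bool = False
    priority_score: int = 1
    annotation_level: int = 0
    previous_state: int = 1

    def __post_init__(self) -> None:
        expected = 2 if self.is_reference else 1
        if self.priority_score != expected:
            raise ProteomeError(
                f"priority_score must be {expected} when is_reference="
                f"{self.is_reference}, got {self.priority_score}"
            )
        if self.previous_state not in (0, 1):
            raise ProteomeError(
                f"previous_state must be 0 or 1, got {self.previous_state}"
            )
        if self.annotation_level < 0:
            raise ProteomeError("annotation_level must be >= 0")

    @classmethod
    def reference(cls, annotation_level: int = 0, previous_state: int = 1) -> "ProteomeMetadata":
        return cls(True, 2, annotation_level, previous_state)


@dataclass
class Proteome:
    """An ordered collection of proteins plus metadata; one redundancy-graph node."""

    proteome_id: str
    species_group_id: str
    proteins: list[ProteinRecord]
    metadata: ProteomeMetadata = field(default_factory=ProteomeMetadata)

    def __post_init__(self) -> None:
        if not self.proteome_id:
            raise ProteomeError("proteome_id must be non-empty")
        if not self.proteins:
            raise ProteomeError(f"proteome {self.proteome_id!r} has no proteins")
        seen: set[str] = set()
        for protein in self.proteins:
            if protein.protein_id in seen:
                raise ProteomeError(
                    f"proteome {self.proteome_id!r}: duplicate protein id "
                    f"{protein.protein_id!r}"
                )
            seen.add(protein.protein_id)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    @property
    def total_length(self) -> int:
        return sum(p.length for p in self.proteins)


def read_proteome_fasta(path: str | Path, proteome_id: str,
                        species_group_id: str = "",
                        metadata: ProteomeMetadata | None = None) -> Proteome:
    """Read one protein FASTA file into a :class:`Proteome`.

    The first whitespace-delimited token of each header is the protein id.
    Sequences are upper-cased and a single terminal stop symbol ``*`` is
    stripped; any other non-amino-acid character raises an error naming the
    record and position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ProteomeError(f"{path}: no FASTA records")
    proteins = []
    for rec in records:
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        proteins.append(ProteinRecord(rec.id, seq))
    return Proteome(proteome_id, species_group_id, proteins,
                    metadata or ProteomeMetadata())


def write_proteome_fasta(proteome: Proteome, path: str | Path) -> None:
    """Write a proteome as FASTA, preserving record order."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteome.proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata_table(path: str | Path) -> dict[str, tuple[str, ProteomeMetadata]]:
    """Read the tab-separated proteome metadata table.

    Expected header: proteome_id, species_group_id, is_reference,
    priority_score, annotation_level, previous_state.  A missing
    previous_state column (or empty cell) defaults to 1, so a first run
    treats every proteome as previously non-redundant.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [c for c in METADATA_COLUMNS if c != "previous_state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ProteomeError(f"{path}: missing required column(s) {missing}")
    if "previous_state" not in df.columns:
        df["previous_state"] = "1"
    out: dict[str, tuple[str, ProteomeMetadata]] = {}
    for row in df.itertuples(index=False):
        pid = str(row.proteome_id)
        if pid in out:
            raise ProteomeError(f"{path}: duplicate proteome_id {pid!r}")
        prev = getattr(row, "previous_state")
        prev_state = 1 if pd.isna(prev) or str(prev) == "" else int(prev)
        meta = ProteomeMetadata(
            is_reference=_parse_bool(row.is_reference),
            priority_score=int(row.priority_score),
            annotation_level=int(row.annotation_level),
            previous_state=prev_state,
        )
        out[pid] = (str(row.species_group_id), meta)
    return out


def write_metadata_table(entries: Mapping[str, tuple[str, ProteomeMetadata]],
                         path: str | Path) -> None:
    rows = [
        {
            "proteome_id": pid,
            "species_group_id": group,
            "is_reference": int(meta.is_reference),
            "priority_score": meta.priority_score,
            "annotation_level": meta.annotation_level,
            "previous_state": meta.previous_state,
        }
        for pid, (group, meta) in sorted(entries.items())
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def write_results_table(statuses: Mapping[str, tuple[str, list[str]]],
                        path: str | Path) -> None:
    """Write the redundancy call per proteome as TSV.

    Columns: proteome_id, status (redundant / non-redundant), and the
    semicolon-joined surviving representatives (empty for non-redundant
    proteomes).  Rows are sorted by proteome_id for determinism.
    """
    rows = []
    for pid in sorted(statuses):
        status, reps = statuses[pid]
        if status not in ("redundant", "non-redundant"):
            raise ProteomeError(f"{pid}: invalid status {status!r}")
        if status == "redundant" and not reps:
            raise ProteomeError(f"{pid}: redundant proteome without representative")
        rows.append({
            "proteome_id": pid,
            "status": status,
            "representatives": ";".join(reps),
        })
    pd.DataFrame(rows, columns=["proteome_id", "status", "representatives"]).to_csv(
        path, sep="\t", index=False)


def read_results_table(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for row in df.itertuples(index=False):
        reps = [r for r in str(row.representatives).split(";") if r]
        out[str(row.proteome_id)] = (str(row.status), reps)
    return out


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise ProteomeError(f"cannot parse boolean value {value!r}")
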