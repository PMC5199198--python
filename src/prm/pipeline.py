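"""End-to-end orchestration: compare within species groups, build the
redundancy graph, reduce it, and report statuses.

The pipeline has two stages.  The comparison stage partitions proteomes by
species group and evaluates every ordered within-group pair (subject to the
size heuristic), producing similarity records.  The reduction stage turns
above-threshold records into a directed redundancy graph per group and
greedily eliminates weakest nodes until the survivors form a dominating
set.  Reference proteomes (plus an optional user-supplied immune list) are
protected from elimination.

Incremental updates keep previously redundant proteomes in play: new
proteomes are compared against all same-group proteomes, the graph is
rebuilt, and the reduction is re-run with each old proteome's previous
redundancy state feeding its rank — so a previously redundant proteome can
be reinstated when new data makes it the better representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import graph as rg
from .comparison import (
    ComparisonRecord,
    compare_group,
    group_by_species,
    write_comparisons,
)
from .model import (
    Proteome,
    ProteomeError,
    ProteomeMetadata,
    read_metadata_table,
    read_proteome_fasta,
    write_results_table,
)

logger = logging.getLogger("prm")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs of one pipeline run.

    identity_threshold
        Minimum per-protein alignment identity for a greedy match (0.9).
    similarity_threshold
        Minimum proteome similarity S for a redundancy-graph edge (0.9).
    size_factor
        Size-heuristic factor: a query is only compared when
        factor * |query| <= |subject| (0.9, i.e. at most 1/0.9 ≈ 11% larger).
    word_size
        k-mer size of the pre-alignment word filter.
    seed
        Seed for the reduction's final tie-break.
    """

    identity_threshold: float = 0.9
    similarity_threshold: float = 0.9
    size_factor: float = 0.9
    word_size: int = 5
    seed: int = 0
    worker_count: int = 1

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "similarity_threshold",
                     "size_factor"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.word_size < 2:
            raise ValueError("word_size must be >= 2")
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")


@dataclass
class PipelineResult:
    """Statuses, representatives and the artefacts behind them."""

    statuses: dict[str, str]
    representatives: dict[str, list[str]]
    comparisons: list[ComparisonRecord]
    graphs: dict[str, rg.RedundancyGraph]
    proteomes: dict[str, Proteome] = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def non_redundant(self) -> set[str]:
        return {p for p, s in self.statuses.items() if s == "non-redundant"}

    @property
    def redundant(self) -> set[str]:
        return {p for p, s in self.statuses.items() if s == "redundant"}

    def status_table(self) -> dict[str, tuple[str, list[str]]]:
        return {
            pid: (status, self.representatives.get(pid, []))
            for pid, status in self.statuses.items()
        }


def load_proteomes(fasta_dir: str | Path, metadata_path: str | Path,
                   ) -> list[Proteome]:
    """Load one FASTA per metadata row; FASTA/metadata sets must match."""
    fasta_dir = Path(fasta_dir)
    entries = read_metadata_table(metadata_path)
    fasta_files = {p.stem: p for p in sorted(fasta_dir.glob("*.fasta"))}
    missing_fasta = sorted(set(entries) - set(fasta_files))
    missing_meta = sorted(set(fasta_files) - set(entries))
    if missing_fasta or missing_meta:
        raise ProteomeError(
            f"metadata/FASTA mismatch: no FASTA for {missing_fasta}; "
            f"no metadata for {missing_meta}")
    return [
        read_proteome_fasta(fasta_files[pid], pid, group, meta)
        for pid, (group, meta) in sorted(entries.items())
    ]


def run_on_proteomes(proteomes: Sequence[Proteome],
                     config: PipelineConfig = PipelineConfig(),
                     immune: Iterable[str] = (),
                     previous_comparisons: Sequence[ComparisonRecord] = (),
                     known_pairs: set[tuple[str, str]] | None = None,
                     ) -> PipelineResult:
    """Run comparison + reduction on in-memory proteomes.

    ``previous_comparisons`` (with ``known_pairs`` marking the ordered
    pairs they already cover) lets incremental updates reuse old work.
    """
    by_id = {p.proteome_id: p for p in proteomes}
    if len(by_id) != len(proteomes):
        raise ProteomeError("duplicate proteome ids")
    immune = set(immune)
    unknown = immune - set(by_id)
    if unknown:
        raise ProteomeError(f"immune list names unknown proteomes: {sorted(unknown)}")

    groups = group_by_species(proteomes)
    comparisons: list[ComparisonRecord] = list(previous_comparisons)
    statuses: dict[str, str] = {}
    representatives: dict[str, list[str]] = {}
    graphs: dict[str, rg.RedundancyGraph] = {}

    for group_id in sorted(groups):
        members = [by_id[pid] for pid in sorted(groups[group_id])]
        logger.info("group %s: %d proteomes", group_id, len(members))
        group_records = [
            r for r in comparisons
            if r.subject_id in groups[group_id] and r.query_id in groups[group_id]
        ]
        if known_pairs is None:
            new_records = compare_group(
                members, config.identity_threshold, config.size_factor,
                config.word_size)
        else:
            fresh = [
                (s, q) for s in members for q in members
                if s.proteome_id != q.proteome_id
                and (s.proteome_id, q.proteome_id) not in known_pairs
            ]
            new_records = _compare_pairs(fresh, config)
        group_records.extend(new_records)
        comparisons.extend(new_records)
        performed = sum(1 for r in group_records if r.performed)
        logger.info("group %s: %d comparisons performed, %d skipped",
                    group_id, performed, len(group_records) - performed)

        metadata = {p.proteome_id: p.metadata for p in members}
        graph = rg.build_graph(group_records, metadata,
                               config.similarity_threshold)
        graphs[group_id] = graph
        protected = {
            p.proteome_id for p in members
            if p.metadata.is_reference or p.proteome_id in immune
        }
        state = rg.reduce(graph, protected, seed=config.seed)
        logger.info("group %s: removed %d of %d", group_id,
                    len(state.removed), len(members))
        for pid in state.surviving:
            statuses[pid] = "non-redundant"
            representatives[pid] = []
        for pid in state.removed:
            statuses[pid] = "redundant"
            representatives[pid] = sorted(state.surviving_neighbours[pid])

    return PipelineResult(statuses, representatives, comparisons, graphs,
                          dict(by_id), config)


def _compare_pairs(pairs: Sequence[tuple[Proteome, Proteome]],
                   config: PipelineConfig) -> list[ComparisonRecord]:
    from .clustering import build_seed_index
    from .comparison import compare_pair, size_heuristic

    records = []
    indexes: dict[str, object] = {}
    for subject, query in pairs:
        if not size_heuristic(len(query), len(subject), config.size_factor):
            records.append(ComparisonRecord(
                subject.proteome_id, query.proteome_id, None, False))
            continue
        if subject.proteome_id not in indexes:
            indexes[subject.proteome_id] = build_seed_index(
                subject, config.word_size)
        sim = compare_pair(subject, query, config.identity_threshold,
                           seed_index=indexes[subject.proteome_id])
        records.append(ComparisonRecord(
            subject.proteome_id, query.proteome_id, sim, True))
    return records


def run_pipeline(fasta_dir: str | Path, metadata_path: str | Path,
                 config: PipelineConfig = PipelineConfig(),
                 immune: Iterable[str] = (),
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Full run from a FASTA directory and metadata table.

    When ``out_dir`` is given, the comparison records and the per-proteome
    status table are written there as TSV.
    """
    proteomes = load_proteomes(fasta_dir, metadata_path)
    result = run_on_proteomes(proteomes, config, immune)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_comparisons(result.comparisons, out_dir / "comparisons.tsv")
        write_results_table(result.status_table(), out_dir / "results.tsv")
    return result


def incremental_update(previous: PipelineResult,
                       new_proteomes: Sequence[Proteome] = (),
                       new_fasta_dir: str | Path | None = None,
                       new_metadata_path: str | Path | None = None,
                       config: PipelineConfig | None = None,
                       immune: Iterable[str] = ()) -> PipelineResult:
    """Fold new proteomes into a previous result.

    Old proteomes keep their sequences and metadata but their
    ``previous_state`` is set from their prior status (1 non-redundant, 0
    redundant), stabilising the solution across runs.  New proteomes are
    compared in both directions against all same-group proteomes —
    including previously redundant ones, which may thereby be reinstated.
    Old within-group comparisons are reused, not recomputed.
    """
    config = config or previous.config
    incoming = list(new_proteomes)
    if new_fasta_dir is not None and new_metadata_path is not None:
        incoming.extend(load_proteomes(new_fasta_dir, new_metadata_path))
    collisions = {p.proteome_id for p in incoming} & set(previous.proteomes)
    if collisions:
        raise ProteomeError(
            f"new proteome ids collide with existing: {sorted(collisions)}")

    old = [
        replace(
            p,
            metadata=ProteomeMetadata(
                p.metadata.is_reference, p.metadata.priority_score,
                p.metadata.annotation_level,
                1 if previous.statuses[p.proteome_id] == "non-redundant" else 0,
            ),
        )
        for p in previous.proteomes.values()
    ]
    known_pairs = {(r.subject_id, r.query_id) for r in previous.comparisons}
    return run_on_proteomes(old + incoming, config, immune,
                            previous_comparisons=previous.comparisons,
                            known_pairs=known_pairs)
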