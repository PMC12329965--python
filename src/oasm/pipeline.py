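"""End-to-end orchestration: reads -> unitig graph -> labeled components ->
primary sequences."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotate import AnnotationParams, assign_organelle_types
from .assembly_graph import (
    CleanParams,
    UnitigGraph,
    build_unitig_graph,
    clean_graph,
    count_junctions,
    disentangle,
    drop_small_components,
    map_read_to_unitigs,
)
from .error_correct import CorrectionParams, correct_reads
from .io_formats import SequenceRecord
from .kmer_graph import build_kmer_graph
from .pathfinder import (
    PathSolution,
    SelectionParams,
    enumerate_candidate_paths,
    estimate_copy_numbers,
    orient_and_rotate_plastome,
    path_sequence,
    resolve_component,
    select_primary_path,
)
from .syncmer import SyncmerParams, build_syncmer_table

logger = logging.getLogger(__name__)

__all__ = ["AssemblyResult", "assemble", "resolve", "unitig_records"]


@dataclass
class AssemblyResult:
    table: object
    vectors: list
    kgraph: object
    ugraph: UnitigGraph
    paths: list = field(default_factory=list)  # mapped read walks
    junctions: dict = field(default_factory=dict)
    correction_stats: object = None


def unitig_records(ugraph: UnitigGraph) -> list[SequenceRecord]:
    """One FASTA record per complement pair, named u<id>."""
    return [
        SequenceRecord(f"u{uid}", ugraph.units[uid].seq)
        for uid in sorted(ugraph.units)
    ]


def assemble(
    reads,
    params: SyncmerParams = SyncmerParams(),
    correction: CorrectionParams | None = CorrectionParams(),
    clean: CleanParams | None = None,
    run_disentangle: bool = True,
) -> AssemblyResult:
    """Reads to a cleaned, disentangled unitig graph with mapped reads."""
    table, vectors = build_syncmer_table(reads, params)
    logger.info("syncmer table: %d entries, %d read vectors", len(table), len(vectors))
    stats = None
    if correction is not None:
        vectors, stats = correct_reads(vectors, table, correction)
    kg = build_kmer_graph(table, vectors)
    if clean is not None:
        clean_graph(kg, clean)
        drop_small_components(kg, clean.min_component_bp)
    ug = build_unitig_graph(kg)
    if run_disentangle:
        ug = disentangle(ug, vectors)
    paths = []
    for vec in vectors:
        gp = map_read_to_unitigs(vec, ug)
        if gp is not None:
            paths.append(gp)
    junctions = count_junctions(paths)
    return AssemblyResult(table, vectors, kg, ug, paths, junctions, stats)


@dataclass
class ResolvedGenome:
    organelle: str
    component: list[int]
    solution: PathSolution
    sequence: str


def resolve(
    result: AssemblyResult,
    hits,
    annotation: AnnotationParams = AnnotationParams(),
    selection: SelectionParams = SelectionParams(),
    sa_seed: int = 42,
    max_expanded: int = 64,
) -> list[ResolvedGenome]:
    """Classify components and resolve each organelle component into its
    primary sequence (plastomes oriented and rotated to psbA)."""
    ug = result.ugraph
    components = ug.components()
    names = [[f"u{uid}" for uid in cc] for cc in components]
    labels = assign_organelle_types(names, hits, annotation)
    genomes: list[ResolvedGenome] = []
    for label, cc in zip(labels, components):
        if label.label == "unassigned":
            continue
        sol = resolve_component(
            ug, cc, result.junctions, selection, sa_seed, max_expanded
        )
        if label.label == "plastid" and sol.circular:
            lengths = {u: ug.units[u].length for u in cc}
            depths = {u: ug.units[u].cov for u in cc}
            model = estimate_copy_numbers(lengths, depths)
            cands = [
                p
                for p in enumerate_candidate_paths(
                    ug, cc, model, max_expanded=max_expanded
                )
                if p.circular and p.length == sol.length
            ]
            if len(cands) >= 2:
                seq, chosen, _ = orient_and_rotate_plastome(ug, cands, hits)
                genomes.append(
                    ResolvedGenome(
                        "plastid",
                        cc,
                        PathSolution(chosen.walk, True, chosen.length, sol.support),
                        seq,
                    )
                )
                continue
            seq, _, _ = orient_and_rotate_plastome(ug, [sol], hits)
            genomes.append(ResolvedGenome("plastid", cc, sol, seq))
            continue
        seq = path_sequence(ug, sol.walk, sol.circular)
        genomes.append(ResolvedGenome(label.label, cc, sol, seq))
    return genomes
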