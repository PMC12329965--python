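"""Synthetic genomes, HiFi-like reads and gene-hit tables for testing.

Everything is deterministic under the spec/config seeds.  Read names encode
the truth (component, start, strand, index) so downstream oracles can check
mappings and structure calls without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._dna import revcomp
from .io_formats import HmmHit, SequenceRecord

__all__ = [
    "RepeatSpec",
    "ComponentSpec",
    "SharedSegmentSpec",
    "GeneSpec",
    "GenomeSpec",
    "ReadSimConfig",
    "SimulatedGenomes",
    "make_genomes",
    "simulate_reads",
    "make_hit_table",
    "quadripartite_plastome_spec",
    "circular_component_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass(frozen=True)
class RepeatSpec:
    length: int
    kind: str  # "IR" | "DR"
    positions: tuple[int, int]  # start of template copy, start of planted copy


@dataclass(frozen=True)
class SharedSegmentSpec:
    length: int
    donor: str
    donor_start: int
    acceptor: str
    acceptor_start: int
    divergence: float = 0.0  # per-base substitution rate applied to the copy


@dataclass(frozen=True)
class GeneSpec:
    gene: str
    organelle: str
    component: str
    start: int
    end: int  # 0-based half-open
    strand: str = "+"


@dataclass
class ComponentSpec:
    name: str
    size: int
    circular: bool = True
    depth: float = 50.0
    repeats: list[RepeatSpec] = field(default_factory=list)


@dataclass
class GenomeSpec:
    seed: int
    components: list[ComponentSpec]
    shared_segments: list[SharedSegmentSpec] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)


@dataclass
class SimulatedGenomes:
    records: list[SequenceRecord]
    spec: GenomeSpec

    def record(self, name: str) -> SequenceRecord:
        return next(r for r in self.records if r.id == name)

    def component(self, name: str) -> ComponentSpec:
        return next(c for c in self.spec.components if c.name == name)


def _check_overlaps(spec: GenomeSpec) -> None:
    for comp in spec.components:
        spans = []
        for rep in comp.repeats:
            for p in rep.positions:
                if p < 0 or p + rep.length > comp.size:
                    raise ValueError(f"repeat outside component {comp.name}")
                spans.append((p, p + rep.length))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping planted repeats in {comp.name}")


def make_genomes(spec: GenomeSpec) -> SimulatedGenomes:
    """Deterministically realise a genome spec (repeats exact, IRs as exact
    reverse complements; shared segments copied with optional divergence)."""
    _check_overlaps(spec)
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, list[str]] = {}
    for comp in spec.components:
        seq = list(_random_dna(rng, comp.size))
        for rep in comp.repeats:
            p0, p1 = rep.positions
            template = "".join(seq[p0 : p0 + rep.length])
            planted = revcomp(template) if rep.kind == "IR" else template
            seq[p1 : p1 + rep.length] = planted
        seqs[comp.name] = seq
    for seg in spec.shared_segments:
        donor = seqs[seg.donor]
        chunk = list(donor[seg.donor_start : seg.donor_start + seg.length])
        if seg.divergence > 0:
            nmut = rng.binomial(seg.length, seg.divergence)
            for i in rng.choice(seg.length, size=nmut, replace=False):
                old = chunk[i]
                chunk[i] = rng.choice([b for b in "ACGT" if b != old])
        seqs[seg.acceptor][seg.acceptor_start : seg.acceptor_start + seg.length] = chunk
    records = [
        SequenceRecord(comp.name, "".join(seqs[comp.name])) for comp in spec.components
    ]
    return SimulatedGenomes(records, spec)


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadSimConfig:
    seed: int = 0
    mean_len: int = 15_000
    sigma: float = 0.35
    min_len: int = 5_000
    max_len: int = 25_000
    sub_rate: float = 0.0
    hp_rate: float = 0.0  # per-homopolymer-run probability of a +-1 error


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    nmut = rng.binomial(n, rate)
    if nmut == 0:
        return seq
    chars = list(seq)
    for i in rng.choice(n, size=nmut, replace=False):
        old = chars[i]
        chars[i] = "ACGT"[(("ACGT".index(old)) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def _apply_hp_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        if rng.random() < rate:
            run = max(1, run + (1 if rng.random() < 0.5 else -1))
        out.append(seq[i] * run)
        i = j
    return "".join(out)


def simulate_reads(
    genomes: SimulatedGenomes, cfg: ReadSimConfig
) -> list[SequenceRecord]:
    """Sample reads to each component's depth; names encode the truth as
    ``component|start|strand|index``."""
    rng = np.random.default_rng(cfg.seed)
    reads: list[SequenceRecord] = []
    for comp in genomes.spec.components:
        seq = genomes.record(comp.name).sequence
        doubled = seq + seq if comp.circular else seq
        target = comp.depth * comp.size
        total = 0
        idx = 0
        mu = math.log(cfg.mean_len)
        while total < target:
            length = int(rng.lognormal(mu, cfg.sigma))
            length = max(cfg.min_len, min(cfg.max_len, length))
            if comp.circular:
                start = int(rng.integers(0, comp.size))
                length = min(length, comp.size)
            else:
                if length >= comp.size:
                    length = comp.size
                    start = 0
                else:
                    start = int(rng.integers(0, comp.size - length + 1))
            frag = doubled[start : start + length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            frag = _apply_substitutions(frag, cfg.sub_rate, rng)
            frag = _apply_hp_errors(frag, cfg.hp_rate, rng)
            reads.append(
                SequenceRecord(
                    f"{comp.name}|{start}|{strand}|{idx}",
                    frag,
                    "I" * len(frag),
                )
            )
            total += length
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# synthetic gene-hit tables


def make_hit_table(
    genomes: SimulatedGenomes,
    unitigs: list[SequenceRecord],
    seed: int = 0,
    decoys: int = 0,
) -> list[HmmHit]:
    """One significant hit per planted gene, located by exact search of the
    gene's sequence (or its reverse complement) on the unitig sequences.

    Decoy hits score below the significance thresholds and must be removed
    by hit filtering.
    """
    rng = np.random.default_rng(seed)
    hits: list[HmmHit] = []
    for g in genomes.spec.genes:
        gseq = genomes.record(g.component).sequence[g.start : g.end]
        if g.strand == "-":
            gseq = revcomp(gseq)
        score = float(rng.uniform(300.0, 2000.0))
        placed = False
        for rec in unitigs:
            pos = rec.sequence.find(gseq)
            strand = "+"
            if pos < 0:
                pos = rec.sequence.find(revcomp(gseq))
                strand = "-"
            if pos >= 0:
                hits.append(
                    HmmHit(
                        target_id=rec.id,
                        gene=g.gene,
                        organelle=g.organelle,
                        score=score,
                        evalue=1e-20,
                        start=pos + 1,
                        end=pos + len(gseq),
                        strand=strand,
                    )
                )
                placed = True
                break
        if not placed:
            continue  # gene interrupted by a graph junction; no hit
    for i in range(decoys):
        rec = unitigs[int(rng.integers(0, len(unitigs)))]
        hits.append(
            HmmHit(
                target_id=rec.id,
                gene=f"decoy{i}",
                organelle="plastid" if i % 2 == 0 else "mitochondrion",
                score=float(rng.uniform(50.0, 299.0)),
                evalue=float(rng.uniform(1e-5, 1e-2)),
                start=1,
                end=100,
                strand="+",
            )
        )
    return hits


# ---------------------------------------------------------------------------
# convenience specs


def quadripartite_plastome_spec(
    seed: int = 1,
    lsc: int = 86_000,
    ir: int = 25_000,
    ssc: int = 18_000,
    depth: float = 50.0,
    name: str = "plastome",
    gene_names: list[str] | None = None,
    n_lsc_genes: int = 20,
    n_ssc_genes: int = 6,
    gene_len: int = 900,
) -> GenomeSpec:
    """A circular LSC+IRa+SSC+IRb component with genes laid out so that the
    canonical conformation matches the reference gene order (psbA first)."""
    size = lsc + ir + ssc + ir
    comp = ComponentSpec(
        name,
        size,
        circular=True,
        depth=depth,
        repeats=[RepeatSpec(ir, "IR", (lsc, lsc + ir + ssc))],
    )
    genes: list[GeneSpec] = []
    if gene_names is None:
        from .pathfinder import reference_gene_order

        gene_names = reference_gene_order()
    n_lsc = min(n_lsc_genes, len(gene_names) - n_ssc_genes)
    lsc_gap = (lsc - 200) // max(1, n_lsc)
    pos = 100
    for gname in gene_names[:n_lsc]:
        genes.append(GeneSpec(gname, "plastid", name, pos, pos + gene_len, "+"))
        pos += lsc_gap
    ssc_start = lsc + ir
    ssc_gap = (ssc - 200) // max(1, n_ssc_genes)
    pos = ssc_start + 100
    for gname in gene_names[len(gene_names) - n_ssc_genes :]:
        genes.append(GeneSpec(gname, "plastid", name, pos, pos + gene_len, "+"))
        pos += ssc_gap
    return GenomeSpec(seed=seed, components=[comp], genes=genes)


def circular_component_spec(
    seed: int = 2,
    size: int = 300_000,
    depth: float = 50.0,
    name: str = "mito",
    organelle: str = "mitochondrion",
    n_genes: int = 12,
    gene_len: int = 900,
) -> GenomeSpec:
    comp = ComponentSpec(name, size, circular=True, depth=depth)
    genes = []
    gap = (size - 200) // max(1, n_genes)
    pos = 100
    for i in range(n_genes):
        genes.append(
            GeneSpec(f"nad{i + 1}", organelle, name, pos, pos + gene_len, "+")
        )
        pos += gap
    return GenomeSpec(seed=seed, components=[comp], genes=genes)
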