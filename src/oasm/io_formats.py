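"""Readers/writers for the standard formats the pipeline touches.

FASTA/FASTQ (optionally gzipped), GFA 1 assembly graphs, and HMMER
nhmmscan ``--tblout`` hit tables.  No algorithmic content lives here;
coordinates in hit tables are 1-based inclusive, everything else in the
codebase is 0-based half-open and converted at this boundary.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path

from ._dna import revcomp

__all__ = [
    "SequenceRecord",
    "HmmHit",
    "ParseError",
    "read_seq_records",
    "write_fasta",
    "write_fastq",
    "parse_nhmmscan_tbl",
    "write_nhmmscan_tbl",
]

_VALID = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path):
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _check_seq(seq: str, lineno: int) -> str:
    seq = seq.upper()
    if not _VALID.issuperset(seq):
        bad = next(ch for ch in seq if ch not in _VALID)
        raise ParseError(f"line {lineno}: invalid sequence character {bad!r}")
    return seq


def read_seq_records(path):
    """Stream SequenceRecords from a FASTA or FASTQ file (plain or gzip).

    The format is sniffed from the first non-blank character ('>' FASTA,
    '@' FASTQ).  Sequences are uppercased; characters outside ACGTN are
    rejected with a ParseError carrying the line number.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        while first in ("\n", "\r"):
            first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == ">":
            yield from _read_fasta(fh)
        elif first == "@":
            yield from _read_fastq(fh)
        else:
            raise ParseError(f"line 1: unrecognized format (starts with {first!r})")


def _read_fasta(fh):
    rid, chunks, start = None, [], 0
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if rid is not None:
                yield SequenceRecord(rid, "".join(chunks))
            rid = line[1:].split()[0] if len(line) > 1 else ""
            if not rid:
                raise ParseError(f"line {lineno}: empty FASTA header")
            chunks, start = [], lineno
        else:
            if rid is None:
                raise ParseError(f"line {lineno}: sequence before first header")
            chunks.append(_check_seq(line, lineno))
    if rid is not None:
        yield SequenceRecord(rid, "".join(chunks))


def _read_fastq(fh):
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip()
        if not header:
            continue
        if not header.startswith("@"):
            raise ParseError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
        rid = header[1:].split()[0]
        seq = fh.readline().rstrip()
        plus = fh.readline().rstrip()
        qual = fh.readline().rstrip()
        if not qual and not plus:
            raise ParseError(f"line {lineno}: truncated FASTQ record")
        lineno += 3
        if not plus.startswith("+"):
            raise ParseError(f"line {lineno - 1}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        yield SequenceRecord(rid, _check_seq(seq, lineno - 2), qual)


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records, path) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# nhmmscan --tblout


@dataclass
class HmmHit:
    target_id: str  # sequence (unitig) name
    gene: str
    organelle: str  # "plastid" | "mitochondrion"
    score: float
    evalue: float
    start: int  # 1-based inclusive, start <= end
    end: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.start > self.end:
            raise ValueError("start must be <= end after strand normalization")


def _gene_organelle(gene: str, organelle_map: dict[str, str] | None) -> str:
    if organelle_map is not None and gene in organelle_map:
        return organelle_map[gene]
    # query-name convention: trailing _pt / _mt marker
    if gene.endswith("_pt"):
        return "plastid"
    if gene.endswith("_mt"):
        return "mitochondrion"
    raise ParseError(f"cannot determine organelle for gene {gene!r}")


def parse_nhmmscan_tbl(path, organelle_map: dict[str, str] | None = None):
    """Parse nhmmscan --tblout text into HmmHits.

    Column layout (whitespace separated): target(model) name, accession,
    query(sequence) name, accession, hmmfrom, hmm to, alifrom, ali to,
    envfrom, env to, modlen, strand, E-value, score, bias, description.
    Reverse-strand rows (alifrom > ali to) are normalized to start <= end
    with strand '-'.  Gene organelle comes from ``organelle_map`` or a
    ``_pt``/``_mt`` suffix on the model name.
    """
    hits = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 15:
                raise ParseError(
                    f"line {lineno}: expected >=15 columns, got {len(cols)}"
                )
            model, query = cols[0], cols[2]
            alifrom, alito = int(cols[6]), int(cols[7])
            strand = cols[11]
            evalue, score = float(cols[12]), float(cols[13])
            if alifrom > alito:
                alifrom, alito = alito, alifrom
                strand = "-"
            base = model
            for suf in ("_pt", "_mt"):
                if model.endswith(suf):
                    base = model[: -len(suf)]
            hits.append(
                HmmHit(
                    target_id=query,
                    gene=base,
                    organelle=_gene_organelle(model, organelle_map),
                    score=score,
                    evalue=evalue,
                    start=alifrom,
                    end=alito,
                    strand=strand,
                )
            )
    return hits


def write_nhmmscan_tbl(hits, path) -> None:
    """Emit hits in the nhmmscan --tblout dialect (used by the simulator)."""
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("# target name  accession  query name  accession  hmmfrom  hmm to"
                 "  alifrom  ali to  envfrom  env to  modlen  strand  E-value"
                 "  score  bias  description of target\n")
        for h in hits:
            suf = "_pt" if h.organelle == "plastid" else "_mt"
            length = h.end - h.start + 1
            alifrom, alito = (h.start, h.end) if h.strand == "+" else (h.end, h.start)
            fh.write(
                f"{h.gene}{suf} - {h.target_id} - 1 {length} {alifrom} {alito} "
                f"{alifrom} {alito} {length} {h.strand} {h.evalue:g} "
                f"{h.score:.1f} 0.0 -\n"
            )


# ---------------------------------------------------------------------------
# GFA 1 (implemented here; graph construction lives in assembly_graph)


def write_gfa(ugraph, path) -> None:
    """Write a unitig graph as GFA 1: one S line per complement pair.

    The S-line sequence is the lexicographically smaller of the two
    orientations; depth goes in a dc:f tag, length in LN:i.  L lines carry
    the expanded overlap as an "NM" CIGAR.
    """
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("H\tVN:Z:1.0\n")
        flipped = {}
        for uid in sorted(ugraph.units):
            u = ugraph.units[uid]
            seq = u.seq
            rc = revcomp(seq)
            flip = rc < seq
            flipped[uid] = flip
            out = rc if flip else seq
            fh.write(
                f"S\tu{uid}\t{out}\tLN:i:{len(out)}\tdc:f:{u.cov:.6g}\n"
            )
        seen = set()
        for (a, b), edge in sorted(ugraph.edges.items()):
            key = ugraph.canonical_edge(a, b)
            if key in seen:
                continue
            seen.add(key)
            (ua, oa), (ub, ob) = key
            oa ^= flipped[ua]
            ob ^= flipped[ub]
            fh.write(
                f"L\tu{ua}\t{'+-'[oa]}\tu{ub}\t{'+-'[ob]}\t{edge.overlap_bp}M\n"
            )


def read_gfa(path):
    """Read GFA 1 written by :func:`write_gfa` back into a UnitigGraph."""
    from .assembly_graph import Unitig, UnitigGraph

    g = UnitigGraph()
    links = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "H#":
                continue
            cols = line.split("\t")
            if cols[0] == "S":
                if len(cols) < 3:
                    raise ParseError(f"line {lineno}: short S line")
                name, seq = cols[1], cols[2]
                cov = 0.0
                for tag in cols[3:]:
                    if tag.startswith(("dc:f:", "DP:f:")):
                        cov = float(tag.split(":", 2)[2])
                uid = int(name.lstrip("u"))
                g.units[uid] = Unitig(
                    id=uid, path=[], seq=seq, length=len(seq), cov=cov
                )
            elif cols[0] == "L":
                if len(cols) < 6:
                    raise ParseError(f"line {lineno}: short L line")
                links.append((lineno, cols[1], cols[2], cols[3], cols[4], cols[5]))
    for lineno, a, oa, b, ob, cigar in links:
        ua, ub = int(a.lstrip("u")), int(b.lstrip("u"))
        if ua not in g.units or ub not in g.units:
            raise ParseError(f"line {lineno}: L line references unknown segment")
        ov = int(cigar.rstrip("M")) if cigar not in ("*", "0M") else 0
        g.add_edge((ua, int(oa == "-")), (ub, int(ob == "-")), overlap_bp=ov)
    return g
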