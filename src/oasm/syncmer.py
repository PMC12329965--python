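"""Closed-syncmer extraction, the syncmer table, and the read transform.

Reads are homopolymer compressed (hoco) before k-mer collection; a k-mer
window qualifies as a closed syncmer iff the strand-canonical hash of its
first or last s-mer is minimal among all s-mer hashes in the window.  Each
distinct syncmer (canonicalised over strands) becomes a table entry that
accumulates its frequency and per-position homopolymer run lengths; each
read is rewritten as an ordered vector of <entry index, position,
orientation> triples.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from ._dna import encode, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "SyncmerParams",
    "HocoSequence",
    "SyncmerEntry",
    "SyncmerTable",
    "SyncmerVector",
    "hoco_compress",
    "canonical_smer_hash",
    "smer_hash_array",
    "syncmer_positions",
    "extract_closed_syncmers",
    "build_syncmer_table",
    "kmer_hash",
    "kmer_consensus_sequence",
    "reconstruct_hoco",
]


@dataclass(frozen=True)
class SyncmerParams:
    """k-mer and s-mer sizes (both counted in hoco bases)."""

    k: int = 1001
    s: int = 31

    def __post_init__(self) -> None:
        if not (0 < self.s <= self.k):
            raise ValueError(f"require 0 < s <= k, got s={self.s}, k={self.k}")
        if self.s > 31:
            raise ValueError("s must be <= 31 to fit 2-bit packing in 62 bits")


@dataclass
class HocoSequence:
    """Homopolymer-compressed sequence with per-base run lengths."""

    bases: str
    run_lengths: np.ndarray  # positive ints, same length as bases

    def __len__(self) -> int:
        return len(self.bases)

    def expand(self) -> str:
        """Reproduce the original, uncompressed sequence."""
        return "".join(b * int(n) for b, n in zip(self.bases, self.run_lengths))


def hoco_compress(seq: str) -> HocoSequence:
    """Collapse homopolymer runs to single bases, recording run lengths."""
    if not seq:
        return HocoSequence("", np.zeros(0, dtype=np.int64))
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    keep = np.empty(len(codes), dtype=bool)
    keep[0] = True
    np.not_equal(codes[1:], codes[:-1], out=keep[1:])
    starts = np.flatnonzero(keep)
    runs = np.diff(np.append(starts, len(codes)))
    return HocoSequence(codes[starts].tobytes().decode("ascii"), runs.astype(np.int64))


# ---------------------------------------------------------------------------
# s-mer hashing: perfect, strand-canonical


def _mix64(v: np.ndarray) -> np.ndarray:
    """Bijective 64-bit finaliser (xorshift-multiply chain)."""
    v = v.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        v ^= v >> np.uint64(30)
        v *= np.uint64(0xBF58476D1CE4E5B9)
        v ^= v >> np.uint64(27)
        v *= np.uint64(0x94D049BB133111EB)
        v ^= v >> np.uint64(31)
    return v


def smer_hash_array(codes: np.ndarray, s: int) -> np.ndarray:
    """Canonical hashes of every s-mer of a 2-bit-coded sequence.

    Entry i is the hash of codes[i:i+s].  The hash is the mixed 2-bit packing
    of min(smer, revcomp(smer)); the mix is invertible, so the map is perfect
    on canonical s-mers.
    """
    n = len(codes) - s + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for j in range(s):
        fwd |= c64[j : j + n] << np.uint64(2 * (s - 1 - j))
        rev |= (np.uint64(3) - c64[j : j + n]) << np.uint64(2 * j)
    return _mix64(np.minimum(fwd, rev))


def _sliding_min(h: np.ndarray, w: int) -> np.ndarray:
    """Exact O(n) sliding-window minimum (block prefix/suffix minima)."""
    n = len(h)
    nwin = n - w + 1
    if nwin <= 0:
        return np.zeros(0, dtype=h.dtype)
    pad = (-n) % w
    filler = np.full(pad, np.iinfo(h.dtype).max, dtype=h.dtype)
    hp = np.concatenate([h, filler]).reshape(-1, w)
    pref = np.minimum.accumulate(hp, axis=1).ravel()
    suff = np.minimum.accumulate(hp[:, ::-1], axis=1)[:, ::-1].ravel()
    return np.minimum(suff[:nwin], pref[w - 1 : w - 1 + nwin])


def canonical_smer_hash(smer: str) -> int:
    """Strand-canonical perfect hash of a single s-mer (s <= 31)."""
    if len(smer) > 31:
        raise ValueError("s-mer longer than 31")
    codes = encode(smer)
    return int(smer_hash_array(codes, len(smer))[0])


def kmer_hash(seq: str) -> int:
    """64-bit content hash used for k-mer bucketing (collisions possible)."""
    return int.from_bytes(
        hashlib.blake2b(seq.encode("ascii"), digest_size=8).digest(), "little"
    )


# ---------------------------------------------------------------------------
# closed-syncmer extraction


def syncmer_positions(bases: str, params: SyncmerParams) -> np.ndarray:
    """Start positions of all closed-syncmer k-mer windows of ``bases``.

    A window qualifies iff the hash of its first or last s-mer is not larger
    than any other s-mer hash in the window (ties qualify).
    """
    k, s = params.k, params.s
    if len(bases) < k:
        return np.zeros(0, dtype=np.int64)
    codes = encode(bases)
    h = smer_hash_array(codes, s)
    w = k - s + 1  # number of s-mers per k-mer window
    if w == 1:
        return np.arange(len(bases) - k + 1, dtype=np.int64)
    winmin = _sliding_min(h, w)
    nwin = len(h) - w + 1
    first = h[:nwin]
    last = h[w - 1 :]
    return np.flatnonzero((first == winmin) | (last == winmin)).astype(np.int64)


@dataclass
class SyncmerOccurrence:
    """One closed-syncmer window found on a (hoco) sequence."""

    pos: int
    kmer: str  # as read off the sequence
    canonical: str  # min-hash orientation of the two strands
    orient: int  # 0 if kmer == canonical else 1
    psi: int  # kmer_hash(canonical)


def extract_closed_syncmers(
    bases: str, params: SyncmerParams
) -> list[SyncmerOccurrence]:
    """All closed syncmers of a hoco sequence, in position order."""
    out = []
    for pos in syncmer_positions(bases, params):
        km = bases[pos : pos + params.k]
        rc = revcomp(km)
        hf, hr = kmer_hash(km), kmer_hash(rc)
        if (hf, km) <= (hr, rc):
            out.append(SyncmerOccurrence(int(pos), km, km, 0, hf))
        else:
            out.append(SyncmerOccurrence(int(pos), km, rc, 1, hr))
    return out


# ---------------------------------------------------------------------------
# syncmer table and read vectors


@dataclass
class SyncmerEntry:
    index: int
    canonical_hash: int
    hoco_seq: str
    frequency: int = 0
    runlen_sum: np.ndarray | None = None  # int64, length k
    runlen_count: int = 0  # every occurrence covers all k positions

    def consensus_runs(self) -> np.ndarray:
        """Per-position run-length consensus: round-half-up of the mean."""
        n = self.runlen_count
        if n == 0:
            raise ValueError("entry has no occurrences")
        return (2 * self.runlen_sum + n) // (2 * n)

    def consensus_length(self) -> int:
        return int(self.consensus_runs().sum())


def kmer_consensus_sequence(entry: SyncmerEntry) -> str:
    """Full-length consensus: hoco sequence expanded by consensus run lengths."""
    runs = entry.consensus_runs()
    return "".join(b * int(n) for b, n in zip(entry.hoco_seq, runs))


@dataclass
class SyncmerVector:
    """A read (fragment) rewritten as <index, hoco position, orientation>."""

    read_id: str
    triples: list[tuple[int, int, int]]
    hoco: str = ""
    runs: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.triples)

    def validate(self, k: int) -> None:
        for a, b in zip(self.triples, self.triples[1:]):
            if not 0 < b[1] - a[1] < k:
                raise ValueError(f"vector overlap invariant broken on {self.read_id}")


@dataclass
class SyncmerTable:
    params: SyncmerParams
    entries: list[SyncmerEntry] = field(default_factory=list)
    buckets: dict[int, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def find(self, canonical: str, psi: int) -> int | None:
        for idx in self.buckets.get(psi, ()):
            if self.entries[idx].hoco_seq == canonical:
                return idx
        return None

    def find_or_create(self, canonical: str, psi: int) -> int:
        idx = self.find(canonical, psi)
        if idx is None:
            idx = len(self.entries)
            self.entries.append(
                SyncmerEntry(
                    idx, psi, canonical, 0, np.zeros(self.params.k, np.int64), 0
                )
            )
            self.buckets.setdefault(psi, []).append(idx)
        return idx

    def add_occurrence(self, occ: SyncmerOccurrence, runs: np.ndarray) -> int:
        """Account one occurrence; ``runs`` are the hoco run lengths of its span."""
        idx = self.find_or_create(occ.canonical, occ.psi)
        e = self.entries[idx]
        e.frequency += 1
        e.runlen_count += 1
        e.runlen_sum += runs[::-1] if occ.orient else runs
        return idx

    def reset_frequencies(self) -> None:
        for e in self.entries:
            e.frequency = 0

    def oriented_seq(self, idx: int, orient: int) -> str:
        seq = self.entries[idx].hoco_seq
        return revcomp(seq) if orient else seq

    def oriented_consensus_runs(self, idx: int, orient: int) -> np.ndarray:
        runs = self.entries[idx].consensus_runs()
        return runs[::-1] if orient else runs


def _split_at_n(seq: str) -> list[str]:
    return [frag for frag in seq.upper().split("N") if frag]


def build_syncmer_table(
    reads, params: SyncmerParams
) -> tuple[SyncmerTable, list[SyncmerVector]]:
    """Build the distinct-syncmer table and rewrite every read as a vector.

    ``reads`` yields objects with ``id`` and ``sequence`` attributes (or
    (id, sequence) pairs).  Reads are split at N into fragments processed
    independently; fragments shorter than k in hoco space produce empty
    vectors.
    """
    table = SyncmerTable(params)
    vectors: list[SyncmerVector] = []
    for rec in reads:
        rid, seq = (rec.id, rec.sequence) if hasattr(rec, "id") else rec
        frags = _split_at_n(seq)
        multi = len(frags) > 1
        for i, frag in enumerate(frags):
            fid = f"{rid}/{i}" if multi else rid
            h = hoco_compress(frag)
            if len(h) < params.k:
                logger.debug("fragment %s shorter than k in hoco space", fid)
                vectors.append(SyncmerVector(fid, [], h.bases, h.run_lengths))
                continue
            triples = []
            for occ in extract_closed_syncmers(h.bases, params):
                idx = table.add_occurrence(
                    occ, h.run_lengths[occ.pos : occ.pos + params.k]
                )
                triples.append((idx, occ.pos, occ.orient))
            vectors.append(SyncmerVector(fid, triples, h.bases, h.run_lengths))
    return table, vectors


def recount_frequencies(table: SyncmerTable, vectors: list[SyncmerVector]) -> None:
    """Recompute entry frequencies from a (corrected) vector set."""
    table.reset_frequencies()
    for vec in vectors:
        for idx, _, _ in vec.triples:
            table.entries[idx].frequency += 1


def reconstruct_hoco(vec: SyncmerVector, table: SyncmerTable) -> str:
    """Hoco sequence spanned by a vector (first syncmer start to last end)."""
    if not vec.triples:
        return ""
    k = table.params.k
    idx0, p0, o0 = vec.triples[0]
    parts = [table.oriented_seq(idx0, o0)]
    prev = p0
    for idx, p, o in vec.triples[1:]:
        dist = p - prev
        parts.append(table.oriented_seq(idx, o)[k - dist :])
        prev = p
    return "".join(parts)
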