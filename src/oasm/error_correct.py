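"""Read error correction on syncmer vectors.

Low-frequency table entries are treated as error syncmers.  Maximal runs of
them on a read form error blocks; each block is corrected by a depth-first
search over the error-trimmed k-mer graph, scoring candidate paths with a
banded (Ukkonen O(ND)-style) prefix edit distance against the read
subsequence and accepting the best path only when it is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._dna import encode, revcomp
from .kmer_graph import KmerGraph, Vertex, build_kmer_graph
from .syncmer import SyncmerTable, SyncmerVector, recount_frequencies

logger = logging.getLogger(__name__)

INF = np.int64(1 << 40)

__all__ = [
    "CorrectionParams",
    "ErrorBlock",
    "CorrectionStats",
    "find_error_blocks",
    "prefix_edit_distance",
    "correct_block",
    "correct_reads",
]


@dataclass(frozen=True)
class CorrectionParams:
    theta: int = 3  # frequency threshold: entries with freq < theta are errors
    epsilon: float = 0.01  # edit budget per target bp
    tau: int = 10000  # max completed depth searches per block
    omega: float = 0.7  # best/second-best ambiguity ratio

    def __post_init__(self) -> None:
        if self.theta < 1 or not (0 < self.epsilon < 1) or not (0 < self.omega <= 1):
            raise ValueError("invalid correction parameters")


@dataclass
class ErrorBlock:
    read_id: str
    start: int  # triple index of first error syncmer
    stop: int  # one past last error syncmer
    has_left: bool
    has_right: bool


def find_error_blocks(
    vec: SyncmerVector, table: SyncmerTable, params: CorrectionParams
) -> list[ErrorBlock]:
    """Maximal runs of below-threshold syncmers on a read vector."""
    blocks: list[ErrorBlock] = []
    m = len(vec.triples)
    i = 0
    while i < m:
        if table.entries[vec.triples[i][0]].frequency < params.theta:
            j = i
            while j < m and table.entries[vec.triples[j][0]].frequency < params.theta:
                j += 1
            blocks.append(ErrorBlock(vec.read_id, i, j, i > 0, j < m))
            i = j
        else:
            i += 1
    return blocks


# ---------------------------------------------------------------------------
# banded prefix edit distance


class BandedDP:
    """Incremental banded edit-distance rows against a fixed target.

    Rows correspond to query characters appended one at a time (and popped
    on DFS backtrack); columns to the target.  Row ``i`` is confined to the
    band ``[i-B, i+B]``; cells outside are implicitly infinite, so results
    match the full DP whenever the distance stays within the band.
    """

    def __init__(self, target: str, band: int):
        self.t = encode(target)
        self.l = len(target)
        self.B = int(band)
        hi = min(self.l, self.B)
        row0 = np.arange(hi + 1, dtype=np.int64)
        self.rows: list[tuple[int, np.ndarray]] = [(0, row0)]

    @property
    def nrows(self) -> int:
        return len(self.rows) - 1  # number of query chars consumed

    def push(self, ch_code: int) -> None:
        i = self.nrows + 1
        lo = max(0, i - self.B)
        hi = min(self.l, i + self.B)
        plo, prev = self.rows[-1]
        width = hi - lo + 1
        if width <= 0:
            self.rows.append((lo, np.empty(0, dtype=np.int64)))
            return
        js = np.arange(lo, hi + 1)
        # vertical: prev[j] + 1
        vert = np.full(width, INF, dtype=np.int64)
        vs = js - plo
        ok = (vs >= 0) & (vs < len(prev))
        vert[ok] = prev[vs[ok]] + 1
        # diagonal: prev[j-1] + mismatch
        diag = np.full(width, INF, dtype=np.int64)
        ds = js - 1 - plo
        ok = (ds >= 0) & (ds < len(prev)) & (js >= 1)
        if ok.any():
            mism = (self.t[js[ok] - 1] != ch_code).astype(np.int64)
            diag[ok] = prev[ds[ok]] + mism
        m = np.minimum(vert, diag)
        # horizontal (insertions of target chars): running min scan
        cur = np.minimum.accumulate(m - js) + js
        self.rows.append((lo, cur))

    def push_seq(self, seq: str) -> None:
        for c in encode(seq):
            self.push(int(c))

    def pop(self, n: int) -> None:
        del self.rows[len(self.rows) - n :]

    def prefix_distance(self) -> tuple[int, int]:
        """(d, g): min of the current row and trailing target overhang.

        g uses the largest column achieving the minimum, i.e. the alignment
        with the fewest trailing insertions of the target.
        """
        return self.prefix_distance_at(len(self.rows))

    def prefix_distance_at(self, nrows_total: int) -> tuple[int, int]:
        """(d, g) evaluated at a previously saved row count."""
        lo, row = self.rows[nrows_total - 1]
        if len(row) == 0:
            return int(INF), 0
        d = int(row.min())
        jstar = lo + int(len(row) - 1 - np.argmin(row[::-1]))
        return d, self.l - jstar


def prefix_edit_distance(
    target: str, query: str, budget: int
) -> tuple[int, int] | None:
    """Banded prefix edit distance between ``target`` and ``query``.

    Returns ``(d, g)`` where ``d`` is the minimum edit distance between
    ``query`` and any prefix of ``target`` and ``g`` the length of the
    unconsumed target suffix; returns None when d exceeds ``budget``.
    """
    dp = BandedDP(target, max(1, int(budget)))
    dp.push_seq(query)
    d, g = dp.prefix_distance()
    if d > budget:
        return None
    return d, g


# ---------------------------------------------------------------------------
# block correction by DFS over the trimmed graph


@dataclass
class _SearchResult:
    best_e: float = float("inf")
    best_path: tuple | None = None
    second_e: float = float("inf")
    searches: int = 0
    states: int = 0


def _examine_prefixes(
    res: _SearchResult,
    path: list[Vertex],
    boundary_rows: list[int],
    dp: BandedDP,
    right_vertex: Vertex | None,
) -> None:
    """Score every prefix subpath of a concluded depth search."""
    for t in range(len(path) - 1, 0, -1):
        if right_vertex is not None and path[t] != right_vertex:
            continue
        d, g = dp.prefix_distance_at(boundary_rows[t])
        if d >= INF:
            continue
        e = d + g
        key = tuple(path[: t + 1])
        if e < res.best_e:
            if res.best_path is not None and key != res.best_path:
                res.second_e = res.best_e
            res.best_e, res.best_path = e, key
        elif key != res.best_path and e < res.second_e:
            res.second_e = e


def correct_block(
    vec: SyncmerVector,
    block: ErrorBlock,
    gprime: KmerGraph,
    table: SyncmerTable,
    params: CorrectionParams,
) -> tuple[str, list[Vertex] | None]:
    """Search the trimmed graph for a replacement path for one error block.

    Returns (status, path).  ``path`` starts at the left-boundary vertex and,
    when a right boundary exists, ends at the right-boundary vertex.  Status
    is one of corrected / ambiguous / failed.
    """
    k = gprime.k
    assert block.has_left, "caller must orient the block to have a left boundary"
    left = vec.triples[block.start - 1]
    v0: Vertex = (left[0], left[2])
    if v0[0] not in gprime.alive:
        return "failed", None
    right_vertex: Vertex | None = None
    if block.has_right:
        r = vec.triples[block.stop]
        right_vertex = (r[0], r[2])
        end = r[1] + k  # through the right-boundary k-mer
    else:
        end = vec.triples[block.stop - 1][1] + k
    xi = vec.hoco[left[1] : end]
    l = len(xi)
    budget = params.epsilon * l
    dp = BandedDP(xi, max(4, int(np.ceil(budget)) + 1))
    dp.push_seq(table.oriented_seq(*v0))

    res = _SearchResult()
    max_len = (1 + params.epsilon) * l
    # iterative DFS; each stack frame: (vertex, child iterator, rows before it)
    boundary_rows = [len(dp.rows)]
    path = [v0]

    def children(v: Vertex):
        succ = sorted(
            gprime.successors(v),
            key=lambda w: (-gprime.edges[(v, w)].coverage, w),
        )
        return iter(succ)

    stack = [children(v0)]
    while stack:
        if res.searches >= params.tau:
            return "failed", None
        it = stack[-1]
        advanced = False
        for w in it:
            v = path[-1]
            suffix = table.oriented_seq(*w)[gprime.overlap(v, w) :]
            dp.push_seq(suffix)
            path.append(w)
            boundary_rows.append(len(dp.rows))
            d, _ = dp.prefix_distance()
            ln = dp.nrows
            if d >= budget or ln >= max_len or gprime.outdeg(w) == 0:
                # depth search concluded here
                res.searches += 1
                _examine_prefixes(res, path, boundary_rows, dp, right_vertex)
                path.pop()
                boundary_rows.pop()
                if len(dp.rows) > boundary_rows[-1]:
                    dp.pop(len(dp.rows) - boundary_rows[-1])
            else:
                stack.append(children(w))
            advanced = True
            break
        if not advanced:
            stack.pop()
            if len(path) > len(stack):
                path.pop()
                boundary_rows.pop()
                if stack and len(dp.rows) > boundary_rows[-1]:
                    dp.pop(len(dp.rows) - boundary_rows[-1])

    if res.best_path is None or res.best_e > budget:
        return "failed", None
    if not res.best_e < params.omega * res.second_e:
        return "ambiguous", None
    return "corrected", list(res.best_path)


def _reverse_vector(vec: SyncmerVector, k: int) -> SyncmerVector:
    lh = len(vec.hoco)
    triples = [(i, lh - (p + k), 1 - o) for (i, p, o) in reversed(vec.triples)]
    runs = None if vec.runs is None else vec.runs[::-1]
    return SyncmerVector(vec.read_id, triples, revcomp(vec.hoco), runs)


def _apply_path(
    vec: SyncmerVector, block: ErrorBlock, path: list[Vertex], gprime: KmerGraph
) -> SyncmerVector:
    """Replace the block (and its boundaries) with the corrected path."""
    k = gprime.k
    left = vec.triples[block.start - 1]
    new_triples = []
    pos = left[1]
    prev = path[0]
    new_triples.append((prev[0], pos, prev[1]))
    for w in path[1:]:
        pos += gprime.edges[(prev, w)].dist
        new_triples.append((w[0], pos, w[1]))
        prev = w
    tail_from = block.stop + 1 if block.has_right else block.stop
    tail = vec.triples[tail_from:]
    if block.has_right:
        shift = pos - vec.triples[block.stop][1]
        tail = [(i, p + shift, o) for (i, p, o) in tail]
        if shift:
            logger.debug("block on %s shifted tail by %d", vec.read_id, shift)
    triples = vec.triples[: block.start - 1] + new_triples + tail
    return SyncmerVector(vec.read_id, triples, vec.hoco, vec.runs)


@dataclass
class CorrectionStats:
    found: int = 0
    corrected: int = 0
    ambiguous: int = 0
    failed: int = 0
    excluded: int = 0

    def log(self) -> None:
        logger.info(
            "error_correct found=%d corrected=%d ambiguous=%d failed=%d excluded=%d",
            self.found, self.corrected, self.ambiguous, self.failed, self.excluded,
        )


def correct_reads(
    vectors: list[SyncmerVector],
    table: SyncmerTable,
    params: CorrectionParams,
    graph: KmerGraph | None = None,
) -> tuple[list[SyncmerVector], CorrectionStats]:
    """Correct every read vector; returns corrected vectors and statistics.

    The trimmed graph is the k-mer graph with all below-threshold vertices
    removed.  After correction the table frequencies are recomputed from the
    corrected vectors (the caller rebuilds the graph from them).
    """
    if graph is None:
        graph = build_kmer_graph(table, vectors)
    gprime = build_kmer_graph(table, vectors)
    for idx in [i for i in gprime.alive if table.entries[i].frequency < params.theta]:
        gprime.remove_vertex_pair(idx)

    stats = CorrectionStats()
    out: list[SyncmerVector] = []
    k = table.params.k
    for vec in vectors:
        blocks = find_error_blocks(vec, table, params)
        if not blocks:
            out.append(vec)
            continue
        if len(blocks) == 1 and not blocks[0].has_left and not blocks[0].has_right:
            stats.found += 1
            stats.excluded += 1
            out.append(vec)
            continue
        cur = vec
        for block in reversed(find_error_blocks(cur, table, params)):
            stats.found += 1
            if block.has_left:
                status, path = correct_block(cur, block, gprime, table, params)
                if status == "corrected":
                    cur = _apply_path(cur, block, path, gprime)
            elif block.has_right:
                rvec = _reverse_vector(cur, k)
                m = len(cur.triples)
                rblock = ErrorBlock(
                    cur.read_id, m - block.stop, m - block.start, True, False
                )
                status, path = correct_block(rvec, rblock, gprime, table, params)
                if status == "corrected":
                    cur = _reverse_vector(_apply_path(rvec, rblock, path, gprime), k)
            else:  # whole-read blocks were handled above
                status = "failed"
            setattr(stats, status, getattr(stats, status) + 1)
        out.append(cur)
    recount_frequencies(table, out)
    stats.log()
    return out, stats
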