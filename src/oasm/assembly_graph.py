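"""Graph cleaning, unitig construction, read-to-graph mapping, and
triplet-based disentangling.

The unitig graph keeps the Watson-Crick pairing of the k-mer graph: a node
is addressed as ``(unitig_id, orientation)`` and every edge add also adds
the complement edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._dna import revcomp
from .kmer_graph import KmerGraph, Vertex, comp
from .syncmer import SyncmerTable, SyncmerVector

logger = logging.getLogger(__name__)

SignedUnit = tuple[int, int]

__all__ = [
    "disentangle_round",
    "CleanParams",
    "Unitig",
    "UnitigEdge",
    "UnitigGraph",
    "GraphPath",
    "clean_graph",
    "drop_small_components",
    "build_unitig_graph",
    "map_read_to_unitigs",
    "count_triplets",
    "disentangle",
    "comp_su",
]


def comp_su(su: SignedUnit) -> SignedUnit:
    return (su[0], 1 - su[1])


@dataclass(frozen=True)
class CleanParams:
    cov_threshold: int
    tip_len: int = 10_000
    bubble_len: int = 100_000
    min_component_bp: int = 10_000

    def __post_init__(self) -> None:
        if min(self.cov_threshold, self.tip_len, self.bubble_len) <= 0:
            raise ValueError("clean parameters must be positive")


# ---------------------------------------------------------------------------
# k-mer graph cleaning


def _consensus_len(table: SyncmerTable, idx: int) -> int:
    return table.entries[idx].consensus_length()


def _path_bp(g: KmerGraph, path: list[Vertex]) -> int:
    """Uncompressed consensus length of a k-mer vertex chain."""
    table = g.table
    total = _consensus_len(table, path[0][0])
    prev = path[0]
    for w in path[1:]:
        ov = g.overlap(prev, w)
        runs = table.oriented_consensus_runs(*w)
        total += int(runs[ov:].sum())
        prev = w
    return total


def _follow_chain(g: KmerGraph, v: Vertex) -> tuple[list[Vertex], bool]:
    """Walk forward from a dead-end start; returns (chain, attached)."""
    chain = [v]
    seen = {v}
    cur = v
    attached = False
    while True:
        succ = g.successors(cur)
        if len(succ) == 0:
            break
        if len(succ) > 1:
            attached = True
            break
        (nxt,) = succ
        if g.indeg(nxt) != 1:
            attached = True
            break
        if nxt in seen:
            break
        chain.append(nxt)
        seen.add(nxt)
        cur = nxt
    return chain, attached


def _trim_tips(g: KmerGraph, tip_len: int) -> int:
    removed = 0
    for v in list(g.vertices()):
        if v[0] not in g.alive or g.indeg(v) != 0 or g.outdeg(v) == 0:
            continue
        chain, attached = _follow_chain(g, v)
        if attached and _path_bp(g, chain) < tip_len:
            for w in chain:
                g.remove_vertex_pair(w[0])
            removed += 1
    return removed


def _arm_from(g: KmerGraph, v: Vertex) -> tuple[list[Vertex], Vertex | None]:
    """Follow a simple chain from ``v``; returns (internal arm, terminal)."""
    arm: list[Vertex] = []
    cur = v
    seen = set()
    while g.indeg(cur) == 1 and g.outdeg(cur) == 1:
        if cur in seen:
            return arm, None
        seen.add(cur)
        arm.append(cur)
        (cur,) = g.successors(cur)
    return arm, cur


def _arm_score(g: KmerGraph, arm: list[Vertex]) -> tuple[float, int]:
    if not arm:
        return (0.0, 0)
    bp = _path_bp(g, arm)
    cov = float(np.mean([g.freq(w[0]) for w in arm]))
    return (cov * bp, bp)


def _pop_bubbles(g: KmerGraph, bubble_len: int) -> int:
    popped = 0
    for v in list(g.vertices()):
        if v[0] not in g.alive or g.outdeg(v) != 2:
            continue
        a, b = sorted(g.successors(v))
        arm_a, term_a = _arm_from(g, a)
        arm_b, term_b = _arm_from(g, b)
        if term_a is None or term_a != term_b or term_a == v:
            continue
        ids_a = {w[0] for w in arm_a}
        ids_b = {w[0] for w in arm_b}
        if ids_a & ids_b:
            # shared entries: the "arms" are the two strand readings of the
            # same sequence (e.g. a single-copy region between IRs), not a
            # bubble
            continue
        if v[0] in ids_a | ids_b or term_a[0] in ids_a | ids_b:
            continue
        score_a, bp_a = _arm_score(g, arm_a)
        score_b, bp_b = _arm_score(g, arm_b)
        if max(bp_a, bp_b) >= bubble_len:
            continue
        # true bubbles are alternative versions of the same locus and have
        # near-equal arm lengths; wildly different arms (e.g. two circles
        # through a shared repeat) are left for disentangling
        if abs(bp_a - bp_b) > max(50, 0.1 * max(bp_a, bp_b)):
            continue
        # keep the arm with higher coverage*length; ties -> lower vertex id
        keep_a = (score_a, [-w[0] for w in arm_a]) >= (score_b, [-w[0] for w in arm_b])
        loser, lstart = (arm_b, b) if keep_a else (arm_a, a)
        if loser:
            for w in loser:
                g.remove_vertex_pair(w[0])
        else:
            g.remove_edge_pair(v, lstart)
            # lstart == terminal in the empty-arm case
        popped += 1
    return popped


def clean_graph(g: KmerGraph, params: CleanParams) -> KmerGraph:
    """Coverage filter, then iterative tip trimming and bubble popping."""
    for idx in [i for i in g.alive if g.freq(i) < params.cov_threshold]:
        g.remove_vertex_pair(idx)
    for _ in range(64):
        changed = _trim_tips(g, params.tip_len)
        changed += _pop_bubbles(g, params.bubble_len)
        if not changed:
            break
    return g


def _kmer_components(g: KmerGraph) -> list[set[int]]:
    seen: set[int] = set()
    comps = []
    adj: dict[int, set[int]] = {}
    for (v, w) in g.edges:
        adj.setdefault(v[0], set()).add(w[0])
        adj.setdefault(w[0], set()).add(v[0])
    for idx in g.alive:
        if idx in seen:
            continue
        stack, cc = [idx], set()
        seen.add(idx)
        while stack:
            cur = stack.pop()
            cc.add(cur)
            for nb in adj.get(cur, ()):
                if nb not in seen and nb in g.alive:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(cc)
    return comps


def drop_small_components(g: KmerGraph, min_bp: int = 10_000) -> int:
    """Remove debris components whose total consensus length is < min_bp."""
    dropped = 0
    for cc in _kmer_components(g):
        total = sum(_consensus_len(g.table, i) for i in cc)
        if total < min_bp:
            for i in cc:
                g.remove_vertex_pair(i)
            dropped += 1
            logger.debug("dropped %d-vertex debris component (%d bp)", len(cc), total)
    return dropped


# ---------------------------------------------------------------------------
# unitig graph


@dataclass
class Unitig:
    id: int
    path: list[Vertex]  # signed k-mer vertices in + orientation
    seq: str = ""  # uncompressed consensus, + orientation
    length: int = 0
    cov: float = 0.0
    hoco: str = ""

    def oriented_seq(self, orient: int) -> str:
        return revcomp(self.seq) if orient else self.seq

    def signed_path(self, orient: int) -> list[Vertex]:
        if orient == 0:
            return self.path
        return [comp(v) for v in reversed(self.path)]


@dataclass
class UnitigEdge:
    overlap_hoco: int = 0
    overlap_bp: int = 0
    coverage: int = 0


@dataclass
class GraphPath:
    read_id: str
    walk: list[SignedUnit]


class UnitigGraph:
    def __init__(self) -> None:
        self.units: dict[int, Unitig] = {}
        self.edges: dict[tuple[SignedUnit, SignedUnit], UnitigEdge] = {}
        self.out_adj: dict[SignedUnit, set[SignedUnit]] = {}
        self.in_adj: dict[SignedUnit, set[SignedUnit]] = {}
        self.kmer_index: dict[Vertex, list[tuple[int, int]]] = {}
        self._next_id = 0

    # -- construction ------------------------------------------------------
    def new_id(self) -> int:
        i = self._next_id
        self._next_id = i + 1
        return i

    def add_unit(self, u: Unitig) -> None:
        self.units[u.id] = u
        self._next_id = max(self._next_id, u.id + 1)
        for i, v in enumerate(u.path):
            self.kmer_index.setdefault(v, []).append((u.id, i))

    def add_edge(
        self,
        a: SignedUnit,
        b: SignedUnit,
        overlap_bp: int = 0,
        overlap_hoco: int = 0,
        coverage: int = 0,
    ) -> None:
        for x, y in {(a, b), (comp_su(b), comp_su(a))}:
            if (x, y) not in self.edges:
                self.edges[(x, y)] = UnitigEdge(overlap_hoco, overlap_bp, coverage)
                self.out_adj.setdefault(x, set()).add(y)
                self.in_adj.setdefault(y, set()).add(x)

    def remove_edge_pair(self, a: SignedUnit, b: SignedUnit) -> None:
        for x, y in {(a, b), (comp_su(b), comp_su(a))}:
            if (x, y) in self.edges:
                del self.edges[(x, y)]
                self.out_adj[x].discard(y)
                self.in_adj[y].discard(x)

    def remove_unit(self, uid: int) -> None:
        u = self.units.pop(uid)
        for o in (0, 1):
            su = (uid, o)
            for b in list(self.out_adj.get(su, ())):
                self.remove_edge_pair(su, b)
            for a in list(self.in_adj.get(su, ())):
                self.remove_edge_pair(a, su)
            self.out_adj.pop(su, None)
            self.in_adj.pop(su, None)
        for i, v in enumerate(u.path):
            locs = self.kmer_index.get(v)
            if locs is not None:
                self.kmer_index[v] = [x for x in locs if x[0] != uid]
                if not self.kmer_index[v]:
                    del self.kmer_index[v]

    # -- queries -----------------------------------------------------------
    def successors(self, su: SignedUnit) -> set[SignedUnit]:
        return self.out_adj.get(su, set())

    def predecessors(self, su: SignedUnit) -> set[SignedUnit]:
        return self.in_adj.get(su, set())

    def outdeg(self, su: SignedUnit) -> int:
        return len(self.out_adj.get(su, ()))

    def indeg(self, su: SignedUnit) -> int:
        return len(self.in_adj.get(su, ()))

    def canonical_edge(self, a: SignedUnit, b: SignedUnit):
        return min((a, b), (comp_su(b), comp_su(a)))

    def locate(self, v: Vertex) -> list[tuple[SignedUnit, int]]:
        """All (signed unit, offset) places where k-mer vertex ``v`` occurs."""
        out = []
        for uid, i in self.kmer_index.get(v, ()):
            out.append(((uid, 0), i))
        for uid, i in self.kmer_index.get(comp(v), ()):
            n = len(self.units[uid].path)
            out.append(((uid, 1), n - 1 - i))
        return out

    def path_vertex(self, su: SignedUnit, t: int) -> Vertex:
        u = self.units[su[0]]
        if su[1] == 0:
            return u.path[t]
        return comp(u.path[len(u.path) - 1 - t])

    def components(self) -> list[list[int]]:
        """Connected components (ignoring orientation), as unitig id lists."""
        adj: dict[int, set[int]] = {uid: set() for uid in self.units}
        for (a, b) in self.edges:
            adj[a[0]].add(b[0])
            adj[b[0]].add(a[0])
        seen: set[int] = set()
        comps = []
        for uid in sorted(self.units):
            if uid in seen:
                continue
            stack, cc = [uid], []
            seen.add(uid)
            while stack:
                cur = stack.pop()
                cc.append(cur)
                for nb in adj[cur]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            comps.append(sorted(cc))
        return comps


def _unit_payload(g: KmerGraph, path: list[Vertex]) -> tuple[str, str, int, float]:
    """(seq, hoco, length, cov) for a unitig k-mer path."""
    table = g.table
    hoco_parts = [table.oriented_seq(*path[0])]
    run_parts = [table.oriented_consensus_runs(*path[0])]
    prev = path[0]
    for w in path[1:]:
        ov = g.overlap(prev, w)
        hoco_parts.append(table.oriented_seq(*w)[ov:])
        run_parts.append(table.oriented_consensus_runs(*w)[ov:])
        prev = w
    hoco = "".join(hoco_parts)
    runs = np.concatenate(run_parts)
    seq = "".join(b * int(n) for b, n in zip(hoco, runs))
    cov = float(np.mean([g.freq(v[0]) for v in path]))
    return seq, hoco, len(seq), cov


def build_unitig_graph(g: KmerGraph, table: SyncmerTable | None = None) -> UnitigGraph:
    """Partition the cleaned k-mer graph into maximal unambiguous paths."""
    table = table or g.table
    ug = UnitigGraph()
    visited: set[Vertex] = set()

    def is_start(v: Vertex) -> bool:
        preds = g.predecessors(v)
        if len(preds) != 1:
            return True
        (p,) = preds
        return g.outdeg(p) != 1

    paths: list[list[Vertex]] = []
    for idx in sorted(g.alive):
        for o in (0, 1):
            v = (idx, o)
            if v in visited or not is_start(v):
                continue
            path = [v]
            visited.add(v)
            cur = v
            while g.outdeg(cur) == 1:
                (nxt,) = g.successors(cur)
                if g.indeg(nxt) != 1 or nxt in visited or nxt == comp(v):
                    break
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            for w in path:
                visited.add(comp(w))
            paths.append(path)
    # leftovers are pure cycles (every vertex has in/out degree 1)
    for idx in sorted(g.alive):
        for o in (0, 1):
            v = (idx, o)
            if v in visited:
                continue
            path = [v]
            visited.add(v)
            visited.add(comp(v))
            cur = v
            while True:
                (nxt,) = g.successors(cur)
                if nxt == v:
                    break
                path.append(nxt)
                visited.add(nxt)
                visited.add(comp(nxt))
                cur = nxt
            paths.append(path)

    for path in paths:
        uid = ug.new_id()
        seq, hoco, length, cov = _unit_payload(g, path)
        ug.add_unit(Unitig(uid, path, seq, length, cov, hoco))

    # edges: k-mer edges from a signed unit's last vertex to another's first
    start_map: dict[Vertex, SignedUnit] = {}
    end_map: dict[SignedUnit, Vertex] = {}
    for uid, u in ug.units.items():
        start_map[u.path[0]] = (uid, 0)
        start_map[comp(u.path[-1])] = (uid, 1)
        end_map[(uid, 0)] = u.path[-1]
        end_map[(uid, 1)] = comp(u.path[0])
    for su, x in end_map.items():
        for y in g.successors(x):
            b = start_map.get(y)
            if b is None:
                continue
            e = g.edges[(x, y)]
            ov = g.overlap(x, y)
            runs = table.oriented_consensus_runs(*y)
            ov_bp = int(runs[:ov].sum())
            ug.add_edge(su, b, overlap_bp=ov_bp, overlap_hoco=ov, coverage=e.coverage)
    return ug


# ---------------------------------------------------------------------------
# read mapping


def _extend_from(
    ug: UnitigGraph, verts: list[Vertex], su: SignedUnit, offset: int
) -> list[SignedUnit] | None:
    walk = [su]
    j = offset
    n = len(ug.units[su[0]].path)
    for v in verts[1:]:
        if j + 1 < n:
            if ug.path_vertex(walk[-1], j + 1) != v:
                return None
            j += 1
        else:
            nxt = None
            for cand, pos in ug.locate(v):
                if pos == 0 and cand in ug.successors(walk[-1]):
                    nxt = cand
                    break
            if nxt is None:
                return None
            walk.append(nxt)
            j = 0
            n = len(ug.units[nxt[0]].path)
    return walk


def map_read_to_unitigs(vec: SyncmerVector, ug: UnitigGraph) -> GraphPath | None:
    """Seed-and-extend mapping of a read vector onto the unitig graph.

    The first read k-mer present in the graph seeds the walk; the walk then
    follows the read's k-mer order through unitig boundaries.  Any mismatch
    (a k-mer not where the graph expects it) leaves the read unmapped.
    """
    verts = [(i, o) for (i, _, o) in vec.triples]
    for start in range(len(verts)):
        locs = ug.locate(verts[start])
        if not locs:
            continue
        for su, offset in locs:
            walk = _extend_from(ug, verts[start:], su, offset)
            if walk is not None:
                return GraphPath(vec.read_id, walk)
        return None
    return None


def count_triplets(
    paths: list[GraphPath],
) -> dict[int, dict[tuple[SignedUnit, SignedUnit], int]]:
    """Read counts per spanning triplet, keyed by the (+-oriented) center."""
    counts: dict[int, dict[tuple[SignedUnit, SignedUnit], int]] = {}
    for gp in paths:
        w = gp.walk
        for t in range(1, len(w) - 1):
            uid, o = w[t]
            if o == 0:
                key = (w[t - 1], w[t + 1])
            else:
                key = (comp_su(w[t + 1]), comp_su(w[t - 1]))
            d = counts.setdefault(uid, {})
            d[key] = d.get(key, 0) + 1
    return counts


def count_junctions(paths: list[GraphPath]) -> dict[tuple, int]:
    """Read counts per ordered unitig pair, both directions summed."""
    counts: dict[tuple, int] = {}
    for gp in paths:
        w = gp.walk
        for a, b in zip(w, w[1:]):
            key = min((a, b), (comp_su(b), comp_su(a)))
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# disentangling


def _compound_unit(ug: UnitigGraph, parts: list[SignedUnit]) -> Unitig:
    uid = ug.new_id()
    in_su = parts[0]
    path: list[Vertex] = list(ug.units[in_su[0]].signed_path(in_su[1]))
    seq = ug.units[in_su[0]].oriented_seq(in_su[1])
    for a, b in zip(parts, parts[1:]):
        e = ug.edges[(a, b)]
        path.extend(ug.units[b[0]].signed_path(b[1]))
        seq += ug.units[b[0]].oriented_seq(b[1])[e.overlap_bp :]
    freqs = []
    covs = []
    for p in parts:
        u = ug.units[p[0]]
        covs.append(u.cov * len(u.path))
        freqs.append(len(u.path))
    cov = sum(covs) / sum(freqs)
    return Unitig(uid, path, seq, len(seq), cov, "")


def disentangle_round(
    ug: UnitigGraph,
    paths: list[GraphPath],
    lam: float = 0.1,
) -> bool:
    """One resolution round over mapped read paths; returns True if the
    graph changed."""
    triplets = count_triplets(paths)
    changed = False
    for uid in sorted(list(ug.units)):
        if uid not in ug.units:
            continue
        center = (uid, 0)
        ins = sorted(ug.predecessors(center))
        outs = sorted(ug.successors(center))
        if len(ins) < 2 or len(outs) < 2:
            continue
        nbr_ids = {su[0] for su in ins} | {su[0] for su in outs}
        if uid in nbr_ids:
            continue  # self-adjacent repeat: leave untouched
        if len({su[0] for su in ins}) < len(ins) or len(
            {su[0] for su in outs}
        ) < len(outs):
            # both orientations of one neighbour flank the repeat (e.g. the
            # IR of a quadripartite genome): this is flip-flop structure,
            # not a transfer tangle; resolving it would duplicate sequence
            continue
        tc = triplets.get(uid, {})
        x = np.zeros((len(ins), len(outs)), dtype=np.int64)
        for i, a in enumerate(ins):
            for j, b in enumerate(outs):
                x[i, j] = tc.get((a, b), 0)
        colmax = x.max(axis=0, keepdims=True)
        rowmax = x.max(axis=1, keepdims=True)
        dom = np.where(
            (colmax > 0) & (rowmax > 0),
            (x < lam * colmax) & (x < lam * rowmax),
            True,
        )
        if not dom.any() or dom.all():
            continue
        changed = True
        used_in: set[SignedUnit] = set()
        used_out: set[SignedUnit] = set()
        for i, a in enumerate(ins):
            for j, b in enumerate(outs):
                if dom[i, j]:
                    continue
                if a == b:
                    # the triplet closes a circle through the center: build
                    # arc+center with a self-closing edge instead of
                    # duplicating the arc
                    closing = ug.edges[(center, a)]
                    cu = _compound_unit(ug, [a, center])
                    ug.add_unit(cu)
                    ug.add_edge(
                        (cu.id, 0),
                        (cu.id, 0),
                        closing.overlap_bp,
                        closing.overlap_hoco,
                        closing.coverage,
                    )
                else:
                    cu = _compound_unit(ug, [a, center, b])
                    ug.add_unit(cu)
                    for s in ug.successors(b):
                        e = ug.edges[(b, s)]
                        ug.add_edge(
                            (cu.id, 0), s, e.overlap_bp, e.overlap_hoco, e.coverage
                        )
                for p in ug.predecessors(a):
                    if p == center:
                        continue
                    e = ug.edges[(p, a)]
                    ug.add_edge(
                        p, (cu.id, 0), e.overlap_bp, e.overlap_hoco, e.coverage
                    )
                used_in.add(a)
                used_out.add(b)
        ug.remove_unit(uid)
        for a in used_in:
            if a[0] in ug.units and ug.outdeg(a) == 0:
                ug.remove_unit(a[0])
        for b in used_out:
            if b[0] in ug.units and ug.indeg(b) == 0:
                ug.remove_unit(b[0])
    return changed


def disentangle(
    ug: UnitigGraph,
    vectors: list[SyncmerVector],
    lam: float = 0.1,
    max_rounds: int = 16,
) -> UnitigGraph:
    """Resolve repeat nodes using read-supported spanning triplets.

    A triplet is dominated when its read support is below ``lam`` times the
    maxima of both its row and column in the center node's support matrix;
    nodes with at least one dominated triplet are replaced by one compound
    node per non-dominated triplet.  Repeats until the structure converges.
    """
    if not 0 < lam <= 1:
        raise ValueError("lambda must be in (0, 1]")
    for _ in range(max_rounds):
        paths = []
        for vec in vectors:
            gp = map_read_to_unitigs(vec, ug)
            if gp is not None:
                paths.append(gp)
        if not disentangle_round(ug, paths, lam):
            break
    else:
        logger.warning("disentangling did not converge within %d rounds", max_rounds)
    return ug
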