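"""Sparse de Bruijn graph over closed syncmers.

Vertices come in Watson-Crick complement pairs referencing syncmer-table
entries; a vertex is a ``(entry_index, orientation)`` pair and its
complement flips the orientation bit.  Directed edges connect syncmers
adjacent on a read; every edge add also adds the complement edge, keeping
the graph Watson-Crick complete by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .syncmer import SyncmerTable, SyncmerVector

Vertex = tuple[int, int]  # (entry index, orientation bit)

__all__ = ["KmerGraph", "KmerEdge", "build_kmer_graph", "verify_wc_complete", "comp"]


def comp(v: Vertex) -> Vertex:
    return (v[0], 1 - v[1])


@dataclass
class KmerEdge:
    coverage: int = 0
    dist: int = 0  # consolidated k-mer start distance in hoco bp (max observed)
    dists: set[int] = field(default_factory=set)  # diagnostics


@dataclass
class KmerGraph:
    table: SyncmerTable
    alive: set[int] = field(default_factory=set)  # entry indices present
    edges: dict[tuple[Vertex, Vertex], KmerEdge] = field(default_factory=dict)
    out_adj: dict[Vertex, set[Vertex]] = field(default_factory=dict)
    in_adj: dict[Vertex, set[Vertex]] = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------
    @property
    def k(self) -> int:
        return self.table.params.k

    def successors(self, v: Vertex) -> set[Vertex]:
        return self.out_adj.get(v, set())

    def predecessors(self, v: Vertex) -> set[Vertex]:
        return self.in_adj.get(v, set())

    def outdeg(self, v: Vertex) -> int:
        return len(self.out_adj.get(v, ()))

    def indeg(self, v: Vertex) -> int:
        return len(self.in_adj.get(v, ()))

    def overlap(self, v: Vertex, w: Vertex) -> int:
        """Sequence overlap (hoco bp) between adjacent k-mers."""
        return self.k - self.edges[(v, w)].dist

    def freq(self, idx: int) -> int:
        return self.table.entries[idx].frequency

    # -- construction ------------------------------------------------------
    def add_vertex_pair(self, idx: int) -> None:
        self.alive.add(idx)

    def _add_directed(self, v: Vertex, w: Vertex, dist: int, cov: int) -> None:
        e = self.edges.get((v, w))
        if e is None:
            e = self.edges[(v, w)] = KmerEdge()
            self.out_adj.setdefault(v, set()).add(w)
            self.in_adj.setdefault(w, set()).add(v)
        e.coverage += cov
        e.dists.add(dist)
        # multiple observed distances: the largest distance (smallest
        # overlap) wins
        e.dist = max(e.dist, dist)

    def add_observation(self, v: Vertex, w: Vertex, dist: int) -> None:
        """Record one read-adjacency v->w with k-mer start distance ``dist``."""
        if not 0 < dist < self.k:
            raise ValueError(f"adjacency distance {dist} outside (0, k)")
        self.alive.add(v[0])
        self.alive.add(w[0])
        self._add_directed(v, w, dist, 1)
        if (v, w) != (comp(w), comp(v)):
            self._add_directed(comp(w), comp(v), dist, 1)

    # -- deletion (always complement-paired) -------------------------------
    def remove_edge_pair(self, v: Vertex, w: Vertex) -> None:
        for a, b in {(v, w), (comp(w), comp(v))}:
            if (a, b) in self.edges:
                del self.edges[(a, b)]
                self.out_adj[a].discard(b)
                self.in_adj[b].discard(a)

    def remove_vertex_pair(self, idx: int) -> None:
        """Delete both orientations of entry ``idx`` and incident edges."""
        self.alive.discard(idx)
        for o in (0, 1):
            v = (idx, o)
            for w in list(self.out_adj.get(v, ())):
                self.remove_edge_pair(v, w)
            for u in list(self.in_adj.get(v, ())):
                self.remove_edge_pair(u, v)
            self.out_adj.pop(v, None)
            self.in_adj.pop(v, None)

    def vertices(self):
        for idx in self.alive:
            yield (idx, 0)
            yield (idx, 1)


def build_kmer_graph(table: SyncmerTable, vectors: list[SyncmerVector]) -> KmerGraph:
    """Build the syncmer graph from the table and the transformed read set."""
    g = KmerGraph(table)
    for vec in vectors:
        for (i1, p1, o1), (i2, p2, o2) in zip(vec.triples, vec.triples[1:]):
            g.add_observation((i1, o1), (i2, o2), p2 - p1)
        if len(vec.triples) == 1:
            g.add_vertex_pair(vec.triples[0][0])
    return g


def verify_wc_complete(g: KmerGraph) -> tuple[bool, str | None]:
    """Check Watson-Crick completeness; returns (ok, first violation)."""
    for (v, w), e in g.edges.items():
        if v[0] not in g.alive or w[0] not in g.alive:
            return False, f"edge {v}->{w} touches dead vertex"
        ce = g.edges.get((comp(w), comp(v)))
        if ce is None:
            return False, f"missing complement edge for {v}->{w}"
        if ce.coverage != e.coverage or ce.dist != e.dist:
            return False, f"complement mismatch on {v}->{w}"
    for idx in g.alive:
        for o in (0, 1):
            v = (idx, o)
            if g.indeg(v) != g.outdeg(comp(v)):
                return False, f"degree asymmetry at {v}"
    return True, None
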