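"""Resolving an organelle graph component into a primary sequence.

Pipeline per component: EM multiplicity estimation, exhaustive canonical
path enumeration over the copy-expanded graph, longest-path selection with
a circular preference and read-support tie-break; for plastomes, conformation
choice by gene-order rank correlation against a packaged reference order and
rotation to the psbA start; plus inverted-repeat (quadripartite) structure
detection and the flip-flop read-balance test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

from ._dna import revcomp
from .assembly_graph import GraphPath, SignedUnit, UnitigGraph, comp_su, count_triplets

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberModel",
    "CandidatePath",
    "PathSolution",
    "EdgeVisitAssignment",
    "QuadripartiteStructure",
    "SelectionParams",
    "estimate_copy_numbers",
    "enumerate_candidate_paths",
    "select_primary_path",
    "optimize_edge_visits",
    "path_sequence",
    "walk_layout",
    "orient_and_rotate_plastome",
    "detect_quadripartite",
    "flipflop_support",
    "reference_gene_order",
    "resolve_component",
]


def reference_gene_order() -> list[str]:
    """Packaged plastome protein-coding gene order used for orientation."""
    text = (
        resources.files("oasm").joinpath("data/plastid_gene_order.txt").read_text()
    )
    return [line.strip() for line in text.splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# EM copy numbers


@dataclass
class CopyNumberModel:
    copy: dict[int, int]
    dbar: float
    iterations: int


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def estimate_copy_numbers(
    lengths: dict[int, int], depths: dict[int, float], max_iter: int = 1000
) -> CopyNumberModel:
    """EM fixpoint of d̄ = Σ l·d / Σ l·c and c = ⌊d/d̄⌉ (c clamped ≥ 1)."""
    uids = sorted(lengths)
    l = np.array([lengths[u] for u in uids], dtype=float)
    d = np.array([depths[u] for u in uids], dtype=float)
    if np.any(l <= 0) or np.any(d <= 0):
        raise ValueError("lengths and depths must be positive")
    dmin = d.min()
    c = np.maximum(1, _round_half_up(d / dmin))
    trace = []
    for it in range(1, max_iter + 1):
        dbar = float(np.sum(l * d) / np.sum(l * c))
        c_new = np.maximum(1, _round_half_up(d / dbar))
        trace.append((dbar, c_new.tolist()))
        if np.array_equal(c_new, c):
            return CopyNumberModel(dict(zip(uids, c.tolist())), dbar, it)
        c = c_new
    raise RuntimeError(f"copy-number EM did not converge; trace tail: {trace[-5:]}")


# ---------------------------------------------------------------------------
# path enumeration


@dataclass
class CandidatePath:
    walk: list[SignedUnit]
    circular: bool
    length: int
    support: int = 0

    def canonical_key(self) -> tuple:
        fwd = tuple(self.walk)
        rev = tuple(comp_su(s) for s in reversed(self.walk))
        if not self.circular:
            return min(fwd, rev)
        cands = []
        for t in (fwd, rev):
            cands.extend(t[i:] + t[:i] for i in range(len(t)))
        return min(cands)


@dataclass
class PathSolution(CandidatePath):
    pass


def _walk_length(ug: UnitigGraph, walk: list[SignedUnit], circular: bool) -> int:
    total = sum(ug.units[s[0]].length for s in walk)
    for a, b in zip(walk, walk[1:]):
        total -= ug.edges[(a, b)].overlap_bp
    if circular and len(walk) > 0:
        total -= ug.edges[(walk[-1], walk[0])].overlap_bp
    return total


def enumerate_candidate_paths(
    ug: UnitigGraph,
    uids: list[int],
    model: CopyNumberModel,
    max_expanded: int = 64,
    max_states: int = 10_000_000,
    edge_limits: dict | None = None,
    return_all: bool = False,
) -> list[CandidatePath]:
    """All canonical maximal walks over the copy-expanded component.

    Circular walks using every node exactly its copy number of times are the
    preferred candidates; otherwise the longest closing walks and the longest
    linear (extension-impossible) walks are returned.  Rotation, reversal and
    copy-permutation duplicates are collapsed via canonical keys.
    """
    cset = set(uids)
    c = {u: model.copy[u] for u in uids}
    if edge_limits is not None:
        # edge visits constrain the walk; node caps follow from them
        for u in uids:
            tin = sum(
                t
                for (a, b), t in edge_limits.items()
                if b == (u, 0) or a == (u, 1)
            )
            tout = sum(
                t
                for (a, b), t in edge_limits.items()
                if a == (u, 0) or b == (u, 1)
            )
            c[u] = max(1, tin, tout)
    if sum(c.values()) > max_expanded:
        raise RuntimeError(
            f"expanded graph too large ({sum(c.values())} nodes); "
            "raise the coverage filter"
        )
    complete: dict[tuple, CandidatePath] = {}
    partial: dict[tuple, CandidatePath] = {}
    linear: dict[tuple, CandidatePath] = {}
    states = 0

    def edge_key(a, b):
        return min((a, b), (comp_su(b), comp_su(a)))

    def record(walk: list[SignedUnit], circular: bool, store: dict) -> None:
        cand = CandidatePath(list(walk), circular, _walk_length(ug, walk, circular))
        key = cand.canonical_key()
        if key not in store:
            store[key] = cand

    def dfs(walk, used, edge_used):
        nonlocal states
        states += 1
        if states > max_states:
            raise RuntimeError("path enumeration exceeded the state cap")
        last = walk[-1]
        if walk[0] in ug.successors(last):
            close_ok = edge_limits is None or (
                edge_used.get(edge_key(last, walk[0]), 0)
                < edge_limits.get(edge_key(last, walk[0]), 0)
            )
            if close_ok:
                if all(used.get(u, 0) == c[u] for u in uids):
                    record(walk, True, complete)
                else:
                    record(walk, True, partial)
        moved = False
        for w in sorted(ug.successors(last)):
            if w[0] not in cset or used.get(w[0], 0) >= c[w[0]]:
                continue
            if edge_limits is not None:
                ek = edge_key(last, w)
                if edge_used.get(ek, 0) >= edge_limits.get(ek, 0):
                    continue
                edge_used[ek] = edge_used.get(ek, 0) + 1
            used[w[0]] = used.get(w[0], 0) + 1
            walk.append(w)
            dfs(walk, used, edge_used)
            walk.pop()
            used[w[0]] -= 1
            if edge_limits is not None:
                edge_used[edge_key(last, w)] -= 1
            moved = True
        if not moved:
            record(walk, False, linear)

    for u in sorted(uids):
        for o in (0, 1):
            dfs([(u, o)], {u: 1}, {})

    if return_all:
        allc = list(complete.values()) + list(partial.values()) + list(linear.values())
        return sorted(allc, key=lambda p: (not p.circular, p.canonical_key()))
    if complete:
        return sorted(complete.values(), key=lambda p: p.canonical_key())
    out = []
    if partial:
        best = max(p.length for p in partial.values())
        out.extend(p for p in partial.values() if p.length == best)
    if linear:
        best = max(p.length for p in linear.values())
        out.extend(p for p in linear.values() if p.length == best)
    return sorted(out, key=lambda p: (not p.circular, p.canonical_key()))


@dataclass(frozen=True)
class SelectionParams:
    circular_preference: float = 0.90
    reference_gene_order: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.circular_preference <= 1:
            raise ValueError("circular preference must be in (0, 1]")


def path_support(
    walk: list[SignedUnit], circular: bool, junction_counts: dict
) -> int:
    pairs = list(zip(walk, walk[1:]))
    if circular and len(walk) > 1:
        pairs.append((walk[-1], walk[0]))
    total = 0
    for a, b in pairs:
        total += junction_counts.get(min((a, b), (comp_su(b), comp_su(a))), 0)
    return total


def select_primary_path(
    candidates: list[CandidatePath],
    junction_counts: dict | None = None,
    params: SelectionParams = SelectionParams(),
) -> PathSolution:
    """Longest path, preferring circular within the 90% rule; read-support
    tie-break among equal lengths."""
    if not candidates:
        raise ValueError("no candidate paths")
    junction_counts = junction_counts or {}
    circ = [p for p in candidates if p.circular]
    lin = [p for p in candidates if not p.circular]
    pool: list[CandidatePath]
    if circ and (
        not lin
        or max(p.length for p in circ)
        >= params.circular_preference * max(p.length for p in lin)
    ):
        best_len = max(p.length for p in circ)
        pool = [p for p in circ if p.length == best_len]
    else:
        best_len = max(p.length for p in lin)
        pool = [p for p in lin if p.length == best_len]
    for p in pool:
        p.support = path_support(p.walk, p.circular, junction_counts)
    pool.sort(key=lambda p: (-p.support, p.canonical_key()))
    w = pool[0]
    return PathSolution(w.walk, w.circular, w.length, w.support)


# ---------------------------------------------------------------------------
# edge-visit optimization (second-round resolution of non-circular primaries)


@dataclass
class EdgeVisitAssignment:
    visits: dict[tuple, int]
    objective: float
    method: str


def _edge_ends(e: tuple) -> tuple[tuple[int, int], tuple[int, int]]:
    """Physical node ends an edge attaches to: (tail_end, head_end).

    Ends are (uid, side) with side 1 = right end (+ orientation outgoing)
    and side 0 = left end (+ orientation incoming).
    """
    (a, oa), (b, ob) = e
    tail = (a, 1 - oa)
    head = (b, ob)
    return tail, head


def _objective(
    edges: list[tuple], t: np.ndarray, c: dict[int, int], lengths: dict[int, int]
) -> float:
    left: dict[int, int] = {}
    right: dict[int, int] = {}
    for e, te in zip(edges, t):
        (ta, sa), (hb, sb) = _edge_ends(e)
        (right if sa else left).setdefault(ta, 0)
        (right if sa else left)[ta] += int(te)
        (left if sb == 0 else right).setdefault(hb, 0)
        (left if sb == 0 else right)[hb] += int(te)
    obj = 0.0
    for z, cz in c.items():
        tm = left.get(z, 0)
        tp = right.get(z, 0)
        obj += (abs(cz - tm) / 2 + abs(cz - tp) / 2 + abs(tm - tp)) * math.log(
            lengths[z]
        )
    return obj


def optimize_edge_visits(
    ug: UnitigGraph,
    uids: list[int],
    model: CopyNumberModel,
    brute_force_cap: int = 100_000_000,
    seed: int = 42,
    sa_t0: float = 10.0,
    sa_cooling: float = 0.95,
    sa_proposals: int = 200,
    sa_tmin: float = 1e-3,
) -> EdgeVisitAssignment:
    """Integer edge-visit counts minimising the degree-consistency objective.

    Brute force when the solution space is within ``brute_force_cap``;
    otherwise seeded simulated annealing (geometric cooling, +-1 proposals).
    """
    cset = set(uids)
    edges = sorted(
        {
            ug.canonical_edge(a, b)
            for (a, b) in ug.edges
            if a[0] in cset and b[0] in cset
        }
    )
    c = {u: model.copy[u] for u in uids}
    lengths = {u: ug.units[u].length for u in uids}
    lo = np.empty(len(edges), dtype=np.int64)
    hi = np.empty(len(edges), dtype=np.int64)
    for i, ((a, _), (b, _)) in enumerate(edges):
        lo[i] = max(0, min(c[a], c[b]) - 3)
        hi[i] = max(c[a], c[b]) + 3
    space = float(np.prod((hi - lo + 1).astype(float)))
    if space <= brute_force_cap:
        best_t, best_obj = None, float("inf")
        t = lo.copy()
        while True:
            obj = _objective(edges, t, c, lengths)
            if obj < best_obj:
                best_obj, best_t = obj, t.copy()
            i = 0
            while i < len(edges):
                t[i] += 1
                if t[i] <= hi[i]:
                    break
                t[i] = lo[i]
                i += 1
            else:
                break
            if len(edges) == 0:
                break
        if best_t is None:  # no edges
            best_t, best_obj = lo.copy(), _objective(edges, lo, c, lengths)
        return EdgeVisitAssignment(
            dict(zip(edges, best_t.tolist())), best_obj, "brute_force"
        )
    # simulated annealing
    rng = np.random.default_rng(seed)
    t = np.clip(np.array([min(c[a], c[b]) for ((a, _), (b, _)) in edges]), lo, hi)
    cur = _objective(edges, t, c, lengths)
    best_t, best_obj = t.copy(), cur
    temp = sa_t0
    while temp > sa_tmin:
        for _ in range(sa_proposals):
            i = int(rng.integers(len(edges)))
            step = int(rng.choice([-1, 1]))
            if not lo[i] <= t[i] + step <= hi[i]:
                continue
            t[i] += step
            nxt = _objective(edges, t, c, lengths)
            if nxt <= cur or rng.random() < math.exp((cur - nxt) / temp):
                cur = nxt
                if cur < best_obj:
                    best_obj, best_t = cur, t.copy()
            else:
                t[i] -= step
        temp *= sa_cooling
    return EdgeVisitAssignment(
        dict(zip(edges, best_t.tolist())), best_obj, "simulated_annealing"
    )


# ---------------------------------------------------------------------------
# sequences, orientation, rotation


def walk_layout(ug: UnitigGraph, walk: list[SignedUnit]) -> list[int]:
    """Start offset of each walk step in the concatenated path sequence."""
    offsets = [0]
    for a, b in zip(walk, walk[1:]):
        offsets.append(
            offsets[-1] + ug.units[a[0]].length - ug.edges[(a, b)].overlap_bp
        )
    return offsets


def path_sequence(ug: UnitigGraph, walk: list[SignedUnit], circular: bool) -> str:
    parts = [ug.units[walk[0][0]].oriented_seq(walk[0][1])]
    for a, b in zip(walk, walk[1:]):
        ov = ug.edges[(a, b)].overlap_bp
        parts.append(ug.units[b[0]].oriented_seq(b[1])[ov:])
    seq = "".join(parts)
    if circular and len(walk) > 0:
        ov = ug.edges[(walk[-1], walk[0])].overlap_bp
        if ov:
            seq = seq[:-ov]
    return seq


def _gene_positions(
    ug: UnitigGraph, walk: list[SignedUnit], hits
) -> dict[str, tuple[int, str]]:
    """Gene -> (position on the walk sequence, strand), best hit per gene."""
    offsets = walk_layout(ug, walk)
    first_at: dict[int, int] = {}
    for step, (uid, _) in enumerate(walk):
        first_at.setdefault(uid, step)
    best: dict[str, tuple[float, int, str]] = {}
    for h in hits:
        uid = int(h.target_id.lstrip("u")) if h.target_id.startswith("u") else None
        if uid is None or uid not in first_at:
            continue
        step = first_at[uid]
        _, orient = walk[step]
        ulen = ug.units[uid].length
        if orient == 0:
            pos = offsets[step] + (h.start - 1)
            strand = h.strand
        else:
            pos = offsets[step] + (ulen - h.end)
            strand = "-" if h.strand == "+" else "+"
        if h.gene not in best or h.score > best[h.gene][0]:
            best[h.gene] = (h.score, pos, strand)
    return {g: (pos, strand) for g, (_, pos, strand) in best.items()}


def orient_and_rotate_plastome(
    ug: UnitigGraph,
    conformations: list[CandidatePath],
    hits,
    reference: list[str] | None = None,
) -> tuple[str, CandidatePath, float]:
    """Pick the conformation whose gene order best matches the reference
    (Spearman rank correlation), then rotate/flip to start at psbA.

    Returns (sequence, chosen conformation, correlation).
    """
    reference = reference or reference_gene_order()
    ref_rank = {g: i for i, g in enumerate(reference)}
    anchor = reference[0]  # psbA by convention
    best = None
    for cand in conformations:
        for flip in (0, 1):
            walk = (
                cand.walk
                if not flip
                else [comp_su(s) for s in reversed(cand.walk)]
            )
            pos = _gene_positions(ug, walk, hits)
            shared = [g for g in pos if g in ref_rank]
            if len(shared) < 2:
                rho = float("-inf")
            else:
                length = _walk_length(ug, walk, cand.circular) or 1
                origin = pos[anchor][0] if anchor in pos else 0
                ranks = [ref_rank[g] for g in shared]
                coords = [(pos[g][0] - origin) % max(length, 1) for g in shared]
                rho = float(stats.spearmanr(ranks, coords).statistic)
            if best is None or rho > best[0]:
                best = (rho, cand, walk, pos)
    rho, chosen, walk, pos = best
    seq = path_sequence(ug, walk, chosen.circular)
    if anchor not in pos:
        logger.warning("%s not annotated; skipping rotation", anchor)
        return seq, chosen, rho
    p, strand = pos[anchor]
    if strand == "-":
        hit = max((h for h in hits if h.gene == anchor), key=lambda h: h.score)
        glen = hit.end - hit.start + 1
        seq = revcomp(seq)
        p = len(seq) - (p + glen)
    if chosen.circular:
        seq = seq[p:] + seq[:p]
    return seq, chosen, rho


# ---------------------------------------------------------------------------
# quadripartite structure


@dataclass
class QuadripartiteStructure:
    classification: str  # "quadripartite" | "IR-lacking"
    lsc: tuple[int, int] | None = None  # 0-based half-open, may wrap
    ira: tuple[int, int] | None = None
    ssc: tuple[int, int] | None = None
    irb: tuple[int, int] | None = None
    ir_length: int = 0
    identity: float = 0.0


def _inverted_self_matches(seq: str, sd: int = 31):
    """Maximal exact reverse-complement self-matches via seeded extension."""
    n = len(seq)
    rc = revcomp(seq)
    index: dict[str, list[int]] = {}
    for j in range(n - sd + 1):
        index.setdefault(rc[j : j + sd], []).append(j)
    seen: dict[int, int] = {}  # diagonal -> rightmost extended i
    out = []
    for i in range(n - sd + 1):
        for j in index.get(seq[i : i + sd], ()):
            diag = i - j
            if seen.get(diag, -1) >= i:
                continue
            bi, bj = i, j
            while bi > 0 and bj > 0 and seq[bi - 1] == rc[bj - 1]:
                bi -= 1
                bj -= 1
            ei, ej = i + sd, j + sd
            while ei < n and ej < n and seq[ei] == rc[ej]:
                ei += 1
                ej += 1
            seen[diag] = ei
            a = (bi, ei)
            b = (n - ej, n - bj)  # rc coords back to forward coords
            if a[0] < b[0] and a[1] <= b[0]:  # keep ordered, non-overlapping
                out.append((a, b, ei - bi))
    return out


def _merge_matches(matches, gap: int):
    """Merge aligned segment pairs whose closest endpoints are within
    Manhattan distance ``gap``."""
    matches = sorted(matches)
    merged = []
    for a, b, m in matches:
        placed = False
        for seg in merged:
            (sa, sb, sm) = seg
            dist = max(0, a[0] - sa[1]) + max(0, sb[0] - b[1])
            if dist < gap and a[0] >= sa[0] and b[1] <= sb[1] + gap:
                seg[0] = (sa[0], max(sa[1], a[1]))
                seg[1] = (min(sb[0], b[0]), sb[1])
                seg[2] = sm + m
                placed = True
                break
        if not placed:
            merged.append([a, b, m])
    return merged


def detect_quadripartite(
    seq: str, min_identity: float = 0.95, merge_gap: int = 50, min_ir: int = 1000
) -> QuadripartiteStructure:
    """Locate the IR pair of a circular sequence and label LSC/SSC flanks."""
    n = len(seq)
    merged = _merge_matches(_inverted_self_matches(seq), merge_gap)
    best = None
    for a, b, m in merged:
        span = max(a[1] - a[0], b[1] - b[0])
        ident = m / span if span else 0.0
        if span >= min_ir and ident >= min_identity:
            if best is None or span > best[3]:
                best = (a, b, ident, span)
    if best is None:
        return QuadripartiteStructure("IR-lacking")
    ira, irb, ident, span = best
    inner = (ira[1], irb[0])  # between the IRs
    outer = (irb[1], ira[0] + n)  # wrapping region
    inner_len = inner[1] - inner[0]
    outer_len = outer[1] - outer[0]
    if outer_len >= inner_len:
        lsc, ssc = (irb[1] % n, ira[0]), inner
    else:
        lsc, ssc = inner, (irb[1] % n, ira[0])
    return QuadripartiteStructure(
        "quadripartite", lsc, ira, ssc, irb, span, ident
    )


# ---------------------------------------------------------------------------
# flip-flop heteroplasmy support


def flipflop_support(
    ug: UnitigGraph, paths: list[GraphPath], ir_uid: int
) -> tuple[int, int, float | None]:
    """Read counts for the two IR-mediated conformations and a two-sided
    binomial p-value under p=0.5; p is None when no reads span the repeat."""
    center = (ir_uid, 0)
    ins = sorted(ug.predecessors(center))
    outs = sorted(ug.successors(center))
    if len(ins) != 2 or len(outs) != 2:
        raise ValueError("flip-flop test requires a 2-in/2-out repeat node")
    tc = count_triplets(paths).get(ir_uid, {})
    x = np.zeros((2, 2), dtype=int)
    for i, a in enumerate(ins):
        for j, b in enumerate(outs):
            x[i, j] = tc.get((a, b), 0)
    n1 = int(x[0, 0] + x[1, 1])
    n2 = int(x[0, 1] + x[1, 0])
    if n1 + n2 == 0:
        return 0, 0, None
    p = float(stats.binomtest(n1, n1 + n2, 0.5).pvalue)
    return n1, n2, p


# ---------------------------------------------------------------------------
# component orchestration


def resolve_component(
    ug: UnitigGraph,
    uids: list[int],
    junction_counts: dict | None = None,
    params: SelectionParams = SelectionParams(),
    sa_seed: int = 42,
    max_expanded: int = 64,
) -> PathSolution:
    """EM, enumeration and selection; second round with optimized edge
    visits when the first-round primary is non-circular."""
    lengths = {u: ug.units[u].length for u in uids}
    depths = {u: ug.units[u].cov for u in uids}
    model = estimate_copy_numbers(lengths, depths)
    cands = enumerate_candidate_paths(ug, uids, model, max_expanded=max_expanded)
    sol = select_primary_path(cands, junction_counts, params)
    if not sol.circular:
        assign = optimize_edge_visits(ug, uids, model, seed=sa_seed)
        cands2 = enumerate_candidate_paths(
            ug, uids, model, max_expanded=max_expanded, edge_limits=assign.visits
        )
        if cands2:
            sol2 = select_primary_path(cands2, junction_counts, params)
            if sol2.circular or sol2.length > sol.length:
                sol = sol2
    return sol
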