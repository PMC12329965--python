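import numpy as np
import pytest

from oasm._dna import revcomp
from oasm.assembly_graph import (
    CleanParams,
    GraphPath,
    Unitig,
    UnitigGraph,
    build_unitig_graph,
    clean_graph,
    comp_su,
    count_triplets,
    disentangle,
    disentangle_round,
    drop_small_components,
    map_read_to_unitigs,
)
from oasm.kmer_graph import build_kmer_graph, comp, verify_wc_complete
from oasm.pipeline import assemble
from oasm.simulate import (
    ComponentSpec,
    GenomeSpec,
    ReadSimConfig,
    SharedSegmentSpec,
    make_genomes,
    simulate_reads,
)
from oasm.syncmer import SyncmerParams, build_syncmer_table

P = SyncmerParams(101, 13)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _graph_from(reads):
    table, vecs = build_syncmer_table(reads, P)
    return build_kmer_graph(table, vecs), table, vecs


# ---------------------------------------------------------------------------
# cleaning


def test_clean_noop_fixed_point():
    rng = np.random.default_rng(0)
    genome = _rand(rng, 5000)
    g, table, vecs = _graph_from([(f"r{i}", genome) for i in range(10)])
    before = (set(g.alive), set(g.edges))
    clean_graph(g, CleanParams(cov_threshold=5, tip_len=1000, bubble_len=5000))
    assert (set(g.alive), set(g.edges)) == before


def test_coverage_filter_separates_organelle_from_nuclear():
    rng = np.random.default_rng(1)
    circle = _rand(rng, 6000)
    nuclear = _rand(rng, 20_000)
    reads = [
        (f"c{i}", circle[(i * 149) % 6000 :] + circle[: (i * 149) % 6000])
        for i in range(40)
    ]
    reads += [(f"n{i}", nuclear) for i in range(4)]
    g, table, vecs = _graph_from(reads)
    clean_graph(g, CleanParams(cov_threshold=20, tip_len=1000, bubble_len=5000))
    drop_small_components(g, 1000)
    # only the high-coverage circle survives
    assert g.alive
    assert all(g.freq(i) >= 20 for i in g.alive)
    ug = build_unitig_graph(g)
    assert len(ug.units) == 1
    u = next(iter(ug.units.values()))
    ov = ug.edges[((u.id, 0), (u.id, 0))].overlap_bp
    core = u.seq[: len(u.seq) - ov]
    assert circle in (core + core) or circle in revcomp(core) + revcomp(core)


def _branchy_reads(rng, branch_len):
    """A circle with a dead-end branch hanging off it."""
    circle = _rand(rng, 9000)
    branch = circle[:1500] + _rand(rng, branch_len)
    reads = [(f"c{i}", circle[j % 9000 :] + circle[: j % 9000]) for i, j in
             enumerate(range(0, 9000 * 10, 900))]
    reads += [(f"b{i}", branch) for i in range(10)]
    return reads


def test_short_tip_removed_long_tip_kept():
    rng = np.random.default_rng(2)
    g, table, vecs = _graph_from(_branchy_reads(rng, 2000))
    clean_graph(g, CleanParams(cov_threshold=3, tip_len=4000, bubble_len=50_000))
    ug = build_unitig_graph(g)
    assert len(ug.units) == 1  # branch trimmed, pure circle remains

    rng = np.random.default_rng(2)
    g2, *_ = _graph_from(_branchy_reads(rng, 6000))
    clean_graph(g2, CleanParams(cov_threshold=3, tip_len=4000, bubble_len=50_000))
    ug2 = build_unitig_graph(g2)
    assert len(ug2.units) > 1  # long branch survives


def test_bubble_popped_keeps_stronger_arm():
    rng = np.random.default_rng(3)
    a = _rand(rng, 3000)
    mid = _rand(rng, 800)
    b = _rand(rng, 3000)
    mid2 = list(mid)
    mid2[400] = "ACGT"[("ACGT".index(mid[400]) + 1) % 4]
    mid2 = "".join(mid2)
    reads = [(f"p{i}", a + mid + b) for i in range(20)]
    reads += [(f"q{i}", a + mid2 + b) for i in range(5)]
    g, table, vecs = _graph_from(reads)
    clean_graph(g, CleanParams(cov_threshold=3, tip_len=100, bubble_len=5000))
    ug = build_unitig_graph(g)
    assert len(ug.units) == 1
    u = next(iter(ug.units.values()))
    assert mid in u.seq or mid in revcomp(u.seq)  # higher-coverage arm kept
    assert mid2 not in u.seq and mid2 not in revcomp(u.seq)


def test_wc_complete_after_cleaning(circle30):
    assert verify_wc_complete(circle30["res"].kgraph)[0]


# ---------------------------------------------------------------------------
# unitig construction


def test_simple_chain_one_unitig_pair():
    rng = np.random.default_rng(4)
    genome = _rand(rng, 4000)
    g, table, vecs = _graph_from([(f"r{i}", genome) for i in range(5)])
    ug = build_unitig_graph(g)
    assert len(ug.units) == 1
    assert len(ug.edges) == 0
    u = next(iter(ug.units.values()))
    assert len(u.path) == len(vecs[0].triples)


def test_isolated_cycle_self_closing(circle30):
    ug = circle30["res"].ugraph
    assert len(ug.units) == 1
    (uid,) = ug.units
    assert ((uid, 0), (uid, 0)) in ug.edges  # v0 = vn closure


def test_circle_sequence_matches_truth(circle30):
    ug = circle30["res"].ugraph
    (u,) = ug.units.values()
    truth = circle30["genomes"].records[0].sequence
    ov = ug.edges[((u.id, 0), (u.id, 0))].overlap_bp
    seq = u.seq[: len(u.seq) - ov]
    assert len(seq) == len(truth)
    assert seq in truth + truth or revcomp(seq) in truth + truth


def test_sequence_length_conservation():
    rng = np.random.default_rng(5)
    genome = _rand(rng, 4000)
    g, table, vecs = _graph_from([(f"r{i}", genome) for i in range(5)])
    ug = build_unitig_graph(g)
    total_vertex = sum(table.entries[i].consensus_length() for i in g.alive)
    overlap_sum = 0
    seen = set()
    for (v, w), e in g.edges.items():
        key = min((v, w), (comp(w), comp(v)))
        if key in seen:
            continue
        seen.add(key)
        ov = g.overlap(v, w)
        runs = table.oriented_consensus_runs(*w)
        overlap_sum += int(runs[:ov].sum())
    total_unitig = sum(u.length for u in ug.units.values())
    assert total_unitig == total_vertex - overlap_sum


# ---------------------------------------------------------------------------
# read mapping


def test_map_read_within_one_unitig(circle30):
    res = circle30["res"]
    gp = map_read_to_unitigs(res.vectors[0], res.ugraph)
    assert gp is not None
    assert len(set(s[0] for s in gp.walk)) == 1


def test_map_read_through_repeat_names_specific_pair(plastome_small):
    res = plastome_small["res"]
    ug = res.ugraph
    ir_uid = max(ug.units, key=lambda u: ug.units[u].cov)
    spanning = [
        gp
        for gp in res.paths
        if any(s[0] == ir_uid for s in gp.walk[1:-1]) and len(gp.walk) >= 3
    ]
    assert spanning, "some reads must span the IR"
    for gp in spanning[:5]:
        t = next(i for i in range(1, len(gp.walk) - 1) if gp.walk[i][0] == ir_uid)
        assert gp.walk[t - 1][0] != ir_uid and gp.walk[t + 1][0] != ir_uid


def test_map_read_with_error_block_unmapped(circle30):
    res = circle30["res"]
    vec = res.vectors[0]
    broken = type(vec)(
        vec.read_id,
        [
            (idx if i != len(vec.triples) // 2 else 10**6, p, o)
            for i, (idx, p, o) in enumerate(vec.triples)
        ],
        vec.hoco,
        vec.runs,
    )
    assert map_read_to_unitigs(broken, res.ugraph) is None


# ---------------------------------------------------------------------------
# disentangling


def _two_circles_sharing_segment():
    spec = GenomeSpec(
        seed=41,
        components=[
            ComponentSpec("p", 30_000, depth=40.0),
            ComponentSpec("m", 40_000, depth=40.0),
        ],
        shared_segments=[SharedSegmentSpec(3000, "p", 10_000, "m", 20_000)],
    )
    genomes = make_genomes(spec)
    reads = simulate_reads(genomes, ReadSimConfig(seed=42))
    return genomes, reads


def test_disentangle_shared_segment_splits_components():
    genomes, reads = _two_circles_sharing_segment()
    res = assemble(
        reads,
        SyncmerParams(301, 31),
        correction=None,
        clean=CleanParams(cov_threshold=8),
        run_disentangle=False,
    )
    assert len(res.ugraph.components()) == 1  # entangled before resolution
    ug = disentangle(res.ugraph, res.vectors)
    comps = ug.components()
    assert len(comps) == 2
    # both components resolve to circles covering the original genomes
    from oasm.pathfinder import resolve_component

    sizes = set()
    for cc in comps:
        sol = resolve_component(ug, cc)
        assert sol.circular
        sizes.add(sol.length)
    assert sizes == {30_000, 40_000}


def _toy_repeat_graph():
    """Center node R with two ins (A, B) and two outs (C, D)."""
    ug = UnitigGraph()
    for uid, name in enumerate("ABRCD"):
        ug.add_unit(
            Unitig(uid, [(100 + uid, 0)], "ACGT" * 500, 2000, 50.0)
        )
    A, B, R, C, D = 0, 1, 2, 3, 4
    ug.add_edge((A, 0), (R, 0))
    ug.add_edge((B, 0), (R, 0))
    ug.add_edge((R, 0), (C, 0))
    ug.add_edge((R, 0), (D, 0))
    return ug, (A, B, R, C, D)


def _paths(counts, A, B, R, C, D):
    out = []
    pairs = [((A, 0), (C, 0)), ((A, 0), (D, 0)), ((B, 0), (C, 0)), ((B, 0), (D, 0))]
    for (a, b), n in zip(pairs, counts):
        for i in range(n):
            out.append(GraphPath(f"r{a}{b}{i}", [a, (R, 0), b]))
    return out


def test_disentangle_dominated_matrix_resolves():
    ug, (A, B, R, C, D) = _toy_repeat_graph()
    paths = _paths([100, 1, 2, 90], A, B, R, C, D)
    changed = disentangle_round(ug, paths, lam=0.1)
    assert changed
    assert R not in ug.units
    comps = ug.components()
    assert len(comps) == 2  # the figure-eight splits


def test_disentangle_balanced_matrix_untouched():
    ug, (A, B, R, C, D) = _toy_repeat_graph()
    paths = _paths([50, 50, 50, 50], A, B, R, C, D)
    changed = disentangle_round(ug, paths, lam=0.1)
    assert not changed
    assert R in ug.units


def test_disentangle_preserves_kmer_content():
    genomes, reads = _two_circles_sharing_segment()
    res = assemble(
        reads,
        SyncmerParams(301, 31),
        correction=None,
        clean=CleanParams(cov_threshold=8),
        run_disentangle=False,
    )
    before = set()
    for u in res.ugraph.units.values():
        before.update(v[0] for v in u.path)
    ug = disentangle(res.ugraph, res.vectors)
    after = set()
    for u in ug.units.values():
        after.update(v[0] for v in u.path)
    assert after == before
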