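import itertools
import math
from collections import Counter

import numpy as np
import pytest

from oasm._dna import revcomp
from oasm.assembly_graph import GraphPath, Unitig, UnitigGraph, comp_su
from oasm.pathfinder import (
    CandidatePath,
    CopyNumberModel,
    SelectionParams,
    _walk_length,
    detect_quadripartite,
    enumerate_candidate_paths,
    estimate_copy_numbers,
    flipflop_support,
    optimize_edge_visits,
    orient_and_rotate_plastome,
    path_sequence,
    reference_gene_order,
    resolve_component,
    select_primary_path,
)
from oasm.simulate import make_genomes, quadripartite_plastome_spec


# ---------------------------------------------------------------------------
# EM copy numbers


def test_em_equal_depths():
    m = estimate_copy_numbers({1: 1000, 2: 2000}, {1: 70.0, 2: 70.0})
    assert m.copy == {1: 1, 2: 1}
    assert m.dbar == pytest.approx(70.0)


def test_em_quadripartite_fixture():
    m = estimate_copy_numbers(
        {1: 80_000, 2: 25_000, 3: 15_000}, {1: 100.0, 2: 200.0, 3: 100.0}
    )
    assert m.copy == {1: 1, 2: 2, 3: 1}
    assert m.dbar == pytest.approx(100.0)


def test_em_noisy_recovery_20_seeds():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0.9, 1.1, size=3)
        m = estimate_copy_numbers(
            {1: 80_000, 2: 25_000, 3: 15_000},
            {1: 100.0 * noise[0], 2: 200.0 * noise[1], 3: 100.0 * noise[2]},
        )
        assert m.copy == {1: 1, 2: 2, 3: 1}, f"seed {seed}"


def test_em_fixpoint_stability():
    m = estimate_copy_numbers(
        {1: 80_000, 2: 25_000, 3: 15_000}, {1: 95.0, 2: 210.0, 3: 103.0}
    )
    l = {1: 80_000, 2: 25_000, 3: 15_000}
    d = {1: 95.0, 2: 210.0, 3: 103.0}
    dbar = sum(l[z] * d[z] for z in l) / sum(l[z] * m.copy[z] for z in l)
    again = {z: max(1, math.floor(d[z] / dbar + 0.5)) for z in l}
    assert again == m.copy


# ---------------------------------------------------------------------------
# enumeration


def _unit_graph(n, lengths=None, seed=None):
    ug = UnitigGraph()
    for uid in range(n):
        ln = 1000 * (uid + 1) if lengths is None else lengths[uid]
        ug.add_unit(Unitig(uid, [(500 + uid, 0)], "A" * ln, ln, 50.0))
    return ug


def _model(copies):
    return CopyNumberModel(dict(copies), 50.0, 1)


def test_simple_cycle_single_candidate():
    ug = _unit_graph(3)
    ug.add_edge((0, 0), (1, 0))
    ug.add_edge((1, 0), (2, 0))
    ug.add_edge((2, 0), (0, 0))
    cands = enumerate_candidate_paths(ug, [0, 1, 2], _model({0: 1, 1: 1, 2: 1}))
    assert len(cands) == 1
    assert cands[0].circular


def _quad_graph():
    """LSC(0) - IR(1, c=2) - SSC(2) quadripartite topology."""
    ug = _unit_graph(3, lengths=[86_000, 25_000, 18_000])
    ug.add_edge((0, 0), (1, 0))
    ug.add_edge((1, 0), (2, 0))
    ug.add_edge((2, 0), (1, 1))
    ug.add_edge((1, 1), (0, 0))
    return ug


def test_quadripartite_two_conformations():
    ug = _quad_graph()
    cands = enumerate_candidate_paths(ug, [0, 1, 2], _model({0: 1, 1: 2, 2: 1}))
    assert len(cands) == 2
    assert all(c.circular for c in cands)
    assert all(c.length == 86_000 + 2 * 25_000 + 18_000 for c in cands)


def _oracle_candidates(ug, uids, copies):
    """Independent brute-force enumeration + canonical dedup."""
    expanded = [u for u in uids for _ in range(copies[u])]
    n = len(expanded)
    uidset = set(uids)
    walks = set()
    for perm in set(itertools.permutations(expanded)):
        for orients in itertools.product((0, 1), repeat=n):
            w = tuple(zip(perm, orients))
            for L in range(1, n + 1):
                walks.add(w[:L])
    complete, partial, linear = set(), set(), set()
    for w in walks:
        if not all((a, b) in ug.edges for a, b in zip(w, w[1:])):
            continue
        used = Counter(u for u, _ in w)
        key = CandidatePath(list(w), True, 0).canonical_key()
        lkey = CandidatePath(list(w), False, 0).canonical_key()
        if (w[-1], w[0]) in ug.edges:
            if all(used[u] == copies[u] for u in uids):
                complete.add(key)
            else:
                partial.add(key)
        can_extend = any(
            s[0] in uidset and used[s[0]] < copies[s[0]]
            for s in ug.successors(w[-1])
        )
        if not can_extend:
            linear.add(lkey)
    return complete, partial, linear


def test_enumeration_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    for trial in range(40):
        n = int(rng.integers(2, 5))
        ug = _unit_graph(n)
        for a in range(n):
            for oa in (0, 1):
                for b in range(n):
                    for ob in (0, 1):
                        if rng.random() < 0.25:
                            ug.add_edge((a, oa), (b, ob))
        copies = {u: int(rng.integers(1, 3)) for u in range(n)}
        if sum(copies.values()) > 6:
            copies = {u: 1 for u in range(n)}
        cands = enumerate_candidate_paths(
            ug, list(range(n)), _model(copies), return_all=True
        )
        got = {
            (c.canonical_key(), c.circular) for c in cands
        }
        complete, partial, linear = _oracle_candidates(ug, list(range(n)), copies)
        want = {(k, True) for k in complete | partial} | {(k, False) for k in linear}
        assert got == want, f"trial {trial}"


# ---------------------------------------------------------------------------
# selection


def test_selection_circular_preference():
    circ = CandidatePath([(0, 0)], True, 95_000)
    lin = CandidatePath([(1, 0)], False, 100_000)
    assert select_primary_path([circ, lin]).circular
    circ2 = CandidatePath([(0, 0)], True, 80_000)
    assert not select_primary_path([circ2, lin]).circular


def test_selection_support_tie_break():
    a = CandidatePath([(0, 0), (1, 0)], False, 50_000)
    b = CandidatePath([(0, 0), (1, 1)], False, 50_000)
    ja = min(((0, 0), (1, 0)), (comp_su((1, 0)), comp_su((0, 0))))
    jb = min(((0, 0), (1, 1)), (comp_su((1, 1)), comp_su((0, 0))))
    sol = select_primary_path([a, b], {ja: 12, jb: 9})
    assert sol.support == 12
    assert sol.walk == a.walk


# ---------------------------------------------------------------------------
# edge-visit optimization


def test_edge_visits_zero_objective_on_consistent_quadripartite():
    ug = _quad_graph()
    assign = optimize_edge_visits(ug, [0, 1, 2], _model({0: 1, 1: 2, 2: 1}))
    assert assign.method == "brute_force"
    assert assign.objective == 0
    assert all(t == 1 for t in assign.visits.values())


def _independent_objective(ug, uids, copies, edges, t):
    left = {u: 0 for u in uids}
    right = {u: 0 for u in uids}
    for ((a, oa), (b, ob)), te in zip(edges, t):
        if oa == 0:
            right[a] += te
        else:
            left[a] += te
        if ob == 0:
            left[b] += te
        else:
            right[b] += te
    return sum(
        (
            abs(copies[z] - left[z]) / 2
            + abs(copies[z] - right[z]) / 2
            + abs(left[z] - right[z])
        )
        * math.log(ug.units[z].length)
        for z in uids
    )


def test_edge_visits_brute_force_is_exhaustive_minimum():
    ug = _quad_graph()
    copies = {0: 1, 1: 3, 2: 1}  # misestimated IR copy number
    assign = optimize_edge_visits(ug, [0, 1, 2], _model(copies))
    edges = sorted(assign.visits)
    lo = [max(0, min(copies[a[0]], copies[b[0]]) - 3) for a, b in edges]
    hi = [max(copies[a[0]], copies[b[0]]) + 3 for a, b in edges]
    best = min(
        _independent_objective(ug, [0, 1, 2], copies, edges, t)
        for t in itertools.product(*[range(l, h + 1) for l, h in zip(lo, hi)])
    )
    assert assign.objective == pytest.approx(best)


def test_edge_visits_sa_matches_brute_force():
    ug = _quad_graph()
    copies = {0: 1, 1: 3, 2: 1}
    bf = optimize_edge_visits(ug, [0, 1, 2], _model(copies))
    sa = optimize_edge_visits(ug, [0, 1, 2], _model(copies), brute_force_cap=0, seed=42)
    assert sa.method == "simulated_annealing"
    assert sa.objective == pytest.approx(bf.objective)


def test_edge_visits_bounds_respected():
    ug = _quad_graph()
    copies = {0: 1, 1: 2, 2: 1}
    for assign in (
        optimize_edge_visits(ug, [0, 1, 2], _model(copies)),
        optimize_edge_visits(ug, [0, 1, 2], _model(copies), brute_force_cap=0),
    ):
        for ((a, _), (b, _)), t in assign.visits.items():
            ca, cb = copies[a], copies[b]
            assert max(0, min(ca, cb) - 3) <= t <= max(ca, cb) + 3


# ---------------------------------------------------------------------------
# orientation, rotation, structure (on the small plastome fixture)


def _plastome_candidates(fix):
    res = fix["res"]
    cc = res.ugraph.components()[0]
    lengths = {u: res.ugraph.units[u].length for u in cc}
    depths = {u: res.ugraph.units[u].cov for u in cc}
    model = estimate_copy_numbers(lengths, depths)
    cands = enumerate_candidate_paths(res.ugraph, cc, model)
    return [c for c in cands if c.circular]


def test_orientation_prefers_reference_order(plastome_small):
    cands = _plastome_candidates(plastome_small)
    assert len(cands) == 2
    res = plastome_small["res"]
    seq, chosen, rho = orient_and_rotate_plastome(res.ugraph, cands, plastome_small["hits"])
    assert rho == pytest.approx(1.0)
    truth = plastome_small["genomes"].records[0].sequence
    assert len(seq) == len(truth)
    assert seq in truth + truth


def test_rotation_starts_at_psbA(plastome_small):
    cands = _plastome_candidates(plastome_small)
    res = plastome_small["res"]
    seq, _, _ = orient_and_rotate_plastome(res.ugraph, cands, plastome_small["hits"])
    truth = plastome_small["genomes"].records[0].sequence
    gene = next(g for g in plastome_small["spec"].genes if g.gene == "psbA")
    assert seq.startswith(truth[gene.start : gene.start + 60])
    assert len(seq) == len(truth)  # rotation preserves length


def test_orientation_deterministic_two_genes(plastome_small):
    cands = _plastome_candidates(plastome_small)
    res = plastome_small["res"]
    hits = [h for h in plastome_small["hits"] if h.gene in ("psbA", "matK")]
    runs = {
        orient_and_rotate_plastome(res.ugraph, cands, hits)[0] for _ in range(3)
    }
    assert len(runs) == 1


def test_resolve_component_circular(plastome_small):
    res = plastome_small["res"]
    cc = res.ugraph.components()[0]
    sol = resolve_component(res.ugraph, cc, res.junctions)
    assert sol.circular
    assert sol.length == 20_000 + 6_000 + 8_000 + 6_000


# ---------------------------------------------------------------------------
# quadripartite detection


def test_detect_quadripartite_planted(plastome_small):
    truth = plastome_small["genomes"].records[0].sequence
    st = detect_quadripartite(truth)
    assert st.classification == "quadripartite"
    assert abs(st.ira[0] - 20_000) <= 3 and abs(st.ira[1] - 26_000) <= 3
    assert abs(st.irb[0] - 34_000) <= 3 and abs(st.irb[1] - 40_000) <= 3
    assert abs(st.ir_length - 6_000) <= 6
    assert st.identity >= 0.99
    lsc_len = (st.lsc[1] - st.lsc[0]) % len(truth)
    ssc_len = (st.ssc[1] - st.ssc[0]) % len(truth)
    assert lsc_len > ssc_len


def test_detect_ir_lacking_on_random_circle():
    rng = np.random.default_rng(9)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
    assert detect_quadripartite(seq).classification == "IR-lacking"


def test_detect_merges_split_ir():
    rng = np.random.default_rng(10)
    lsc = "".join("ACGT"[i] for i in rng.integers(0, 4, 15_000))
    ir = "".join("ACGT"[i] for i in rng.integers(0, 4, 4_000))
    ssc = "".join("ACGT"[i] for i in rng.integers(0, 4, 6_000))
    insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    ira = ir[:2000] + insert + ir[2000:]
    seq = lsc + ira + ssc + revcomp(ir)
    st = detect_quadripartite(seq)
    assert st.classification == "quadripartite"
    # the 30 bp insert (< 50 bp merge distance) does not split the IR call
    assert st.ir_length >= 4_000
    assert st.identity >= 0.95


# ---------------------------------------------------------------------------
# flip-flop support


def _toy_center():
    ug = UnitigGraph()
    for uid in range(5):
        ug.add_unit(Unitig(uid, [(700 + uid, 0)], "A" * 2000, 2000, 50.0))
    A, B, R, C, D = range(5)
    ug.add_edge((A, 0), (R, 0))
    ug.add_edge((B, 0), (R, 0))
    ug.add_edge((R, 0), (C, 0))
    ug.add_edge((R, 0), (D, 0))
    return ug, (A, B, R, C, D)


def test_flipflop_one_form_extreme():
    ug, (A, B, R, C, D) = _toy_center()
    paths = [GraphPath(f"r{i}", [(A, 0), (R, 0), (C, 0)]) for i in range(100)]
    paths += [
        GraphPath(f"q{i}", [comp_su((C, 0)), comp_su((R, 0)), comp_su((A, 0))])
        for i in range(100)
    ]
    n1, n2, p = flipflop_support(ug, paths, R)
    assert {n1, n2} == {200, 0}
    assert p < 1e-50


def test_flipflop_no_spanning_reads():
    ug, (A, B, R, C, D) = _toy_center()
    assert flipflop_support(ug, [], R) == (0, 0, None)


def test_flipflop_balanced():
    ug, (A, B, R, C, D) = _toy_center()
    rng = np.random.default_rng(11)
    paths = []
    for i in range(400):
        if rng.random() < 0.5:
            paths.append(GraphPath(f"r{i}", [(A, 0), (R, 0), (C, 0)]))
        else:
            paths.append(GraphPath(f"r{i}", [(A, 0), (R, 0), (D, 0)]))
    n1, n2, p = flipflop_support(ug, paths, R)
    assert n1 + n2 == 400
    assert p > 0.01
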