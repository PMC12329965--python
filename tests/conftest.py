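"""Shared fixtures: synthetic assemblies reused across test modules.

Test profile: k=301, s=31 (full-scale k=1001 is exercised only in the
sparsification acceptance test); error runs use a HiFi-like profile where
most errors are homopolymer run-length changes.
"""

from __future__ import annotations

import numpy as np
import pytest

from oasm.assembly_graph import CleanParams
from oasm.error_correct import CorrectionParams
from oasm.pipeline import assemble, unitig_records
from oasm.simulate import (
    ReadSimConfig,
    circular_component_spec,
    make_genomes,
    make_hit_table,
    quadripartite_plastome_spec,
    simulate_reads,
)
from oasm.syncmer import SyncmerParams

K_TEST = SyncmerParams(301, 31)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def circle30():
    """Error-free 30 kb circle at 50x, assembled with k=301."""
    spec = circular_component_spec(seed=3, size=30_000, depth=50.0, name="c30")
    genomes = make_genomes(spec)
    reads = simulate_reads(genomes, ReadSimConfig(seed=7))
    res = assemble(
        reads,
        K_TEST,
        correction=None,
        clean=CleanParams(cov_threshold=10),
        run_disentangle=False,
    )
    return {"spec": spec, "genomes": genomes, "reads": reads, "res": res}


@pytest.fixture(scope="session")
def plastome_small():
    """Error-free quadripartite plastome (20k/6k/8k/6k) at 40x, with the
    IR short enough for reads to span (flip-flop testable)."""
    spec = quadripartite_plastome_spec(
        seed=21, lsc=20_000, ir=6_000, ssc=8_000, depth=40.0,
        n_lsc_genes=10, n_ssc_genes=4,
    )
    genomes = make_genomes(spec)
    reads = simulate_reads(genomes, ReadSimConfig(seed=22))
    res = assemble(
        reads,
        K_TEST,
        correction=None,
        clean=CleanParams(cov_threshold=8),
        run_disentangle=False,
    )
    hits = make_hit_table(genomes, unitig_records(res.ugraph), seed=23)
    return {"spec": spec, "genomes": genomes, "reads": reads, "res": res, "hits": hits}


@pytest.fixture(scope="session")
def e2e0():
    """Acceptance-scale end-to-end at 0% error: 154 kb quadripartite
    plastome (86/25/18/25) + 300 kb circular mitogenome, both at 50x."""
    pspec = quadripartite_plastome_spec(seed=101, depth=50.0)
    mspec = circular_component_spec(seed=102, size=300_000, depth=50.0)
    pg = make_genomes(pspec)
    mg = make_genomes(mspec)
    reads = simulate_reads(pg, ReadSimConfig(seed=103)) + simulate_reads(
        mg, ReadSimConfig(seed=104)
    )
    res = assemble(
        reads,
        K_TEST,
        correction=CorrectionParams(),
        clean=CleanParams(cov_threshold=12),
    )
    hits = make_hit_table(pg, unitig_records(res.ugraph), seed=105) + make_hit_table(
        mg, unitig_records(res.ugraph), seed=106
    )
    return {"pg": pg, "mg": mg, "reads": reads, "res": res, "hits": hits}


@pytest.fixture(scope="session")
def e2e1():
    """Same layout at ~1% total error, dominated by homopolymer run-length
    changes as in HiFi data (hoco absorbs those; residual substitutions are
    corrected)."""
    pspec = quadripartite_plastome_spec(seed=111, depth=50.0)
    mspec = circular_component_spec(seed=112, size=300_000, depth=50.0)
    pg = make_genomes(pspec)
    mg = make_genomes(mspec)
    cfg = dict(sub_rate=0.0005, hp_rate=0.0125)
    reads = simulate_reads(pg, ReadSimConfig(seed=113, **cfg)) + simulate_reads(
        mg, ReadSimConfig(seed=114, **cfg)
    )
    res = assemble(
        reads,
        K_TEST,
        correction=CorrectionParams(),
        clean=CleanParams(cov_threshold=12),
    )
    hits = make_hit_table(pg, unitig_records(res.ugraph), seed=115) + make_hit_table(
        mg, unitig_records(res.ugraph), seed=116
    )
    return {"pg": pg, "mg": mg, "reads": reads, "res": res, "hits": hits}
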