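from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import aavsrna as a

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def host_small():
    """A small host reference set: 2 decoy genomes + 5 pre-miRNA hairpins."""
    return a.make_host_reference(
        n_decoys=2, decoy_len=800, n_premirnas=5, seed=11
    )


@pytest.fixture(scope="session")
def itr_genome():
    """A compact AAV-like genome with 145-nt ITRs (62-nt palindromic arms)."""
    genome, annotations = a.make_itr_genome(600, itr_len=145, arm_len=62, seed=7)
    return genome, annotations


@pytest.fixture(scope="session")
def itr_pipeline():
    """A processed 60k-read sample with planted hotspots including one in the ITR.

    Session-scoped because the simulation plus full pipeline run takes a few
    seconds and several test modules inspect different facets of the result.
    """
    bm = a.hotspot_benchmark(
        seed=3,
        total_reads=60_000,
        background_per_position=5.0,
        include_itr_hotspot=True,
    )
    sim = a.simulate_sample(
        bm.design, bm.host_refs, bm.mature_catalog, {"aav": bm.genome}, {"aav": bm.specs}
    )
    result = a.process_reads(
        "itr_sample",
        [seq for _, seq in sim.reads],
        bm.host_refs,
        {"aav": [bm.genome]},
        bm.design.adapter,
    )
    return bm, sim, result
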