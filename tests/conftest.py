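"""Shared fixtures: small synthetic communities and the full-scale
parameter-recovery fixture (session-scoped; built once)."""

from __future__ import annotations

import time

import numpy as np
import pytest

from otutriage import simulate as sim
from otutriage.align import search_databases
from otutriage.chimera import screen_otus
from otutriage.cluster import cluster_reads
from otutriage.prevalence import build_otu_table, prevalence_by_site
from otutriage.triage import build_priority_records

STD_SEED = 101


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def mini_community():
    """10 well-separated sources, ~1k reads, 1% error, no chimeras."""
    pool = sim.generate_source_pool(10, 200, 0.10, seed=11)
    sites = ["gut", "mouth"]
    design = sim.SimulationDesign(
        body_sites=sites,
        samples_per_site=5,
        reads_per_sample=100,
        prevalence_plan={sid: {s: 1.0 for s in sites} for sid in pool.ids},
        abundance_model="power",
        abundance_param=0.3,
        error_rate=0.01,
        indel_rate=0.001,
        chimera_rate=0.0,
        seed=12,
    )
    reads, truth = sim.simulate_samples(pool, design)
    return {"pool": pool, "design": design, "reads": reads, "truth": truth}


@pytest.fixture(scope="session")
def mini_otus(mini_community):
    otus, unincorporated = cluster_reads(mini_community["reads"])
    return otus, unincorporated


@pytest.fixture(scope="session")
def std_community():
    return sim.standard_community(seed=STD_SEED)


@pytest.fixture(scope="session")
def std_results(std_community):
    """Full pipeline over the standard fixture, with wall-clock accounting."""
    com = std_community
    t0 = time.monotonic()
    otus, unincorporated = cluster_reads(com["reads"])
    verdicts = screen_otus(otus, com["dbs"]["gold_all"])
    matches = search_databases([(o.otu_id, o.consensus) for o in otus], com["dbs"])
    membership = {rid: o.otu_id for o in otus for rid in o.member_read_ids}
    table = build_otu_table(membership, com["reads"].meta)
    prev_records = prevalence_by_site(table)
    prev_map = {r.otu_id: (r.max_site, r.max_prevalence) for r in prev_records}
    chimeric = set(verdicts.loc[verdicts["chimeric"], "otu_id"])
    records = build_priority_records(
        matches, prev_map, {o.otu_id: o.region for o in otus}, chimeric
    )
    elapsed = time.monotonic() - t0
    attribution = sim.attribute_otus(otus, com["truth"])
    return {
        "otus": otus,
        "unincorporated": unincorporated,
        "verdicts": verdicts,
        "matches": matches,
        "records": records,
        "chimeric": chimeric,
        "attribution": attribution,
        "elapsed": elapsed,
    }
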