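"""Synthetic community generator: determinism, planted structure, truth table."""

import numpy as np
import pytest
from scipy import stats

from otutriage import simulate as sim
from otutriage.align import pairwise_identity
from otutriage.triage import TriageThresholds, assign_priority


class TestGenerateSourcePool:
    def test_single_source(self):
        pool = sim.generate_source_pool(1, 100, 0.1, seed=7)
        assert len(pool) == 1
        assert len(pool.sources[0][1]) == 100
        assert set(pool.sources[0][1]) <= set("ACGT")

    def test_determinism(self):
        p1 = sim.generate_source_pool(5, 120, 0.1, seed=7)
        p2 = sim.generate_source_pool(5, 120, 0.1, seed=7)
        assert p1.sources == p2.sources
        p3 = sim.generate_source_pool(5, 120, 0.1, seed=8)
        assert p1.sources != p3.sources

    def test_pairwise_divergence_verified_by_alignment(self):
        pool = sim.generate_source_pool(20, 300, 0.10, seed=3)
        seqs = [s for _, s in pool.sources]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) < 0.90

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sim.generate_source_pool(0, 100)
        with pytest.raises(ValueError):
            sim.generate_source_pool(2, 20)


class TestMutateSequence:
    def test_zero_divergence_identity(self):
        seq = "ACGT" * 30
        out, ident = sim.mutate_sequence(seq, 0.0, seed=1)
        assert out == seq and ident == 1.0

    def test_substitution_only_exact_count(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300))
        out, ident = sim.mutate_sequence(seq, 0.05, indel_fraction=0.0, seed=1)
        n_diff = sum(a != b for a, b in zip(seq, out))
        assert n_diff == round(0.05 * 300) == 15
        assert len(out) == len(seq)

    def test_realized_identity_near_target(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 300))
        out, ident = sim.mutate_sequence(seq, 0.12, indel_fraction=0.1, seed=2)
        assert 0.86 <= ident <= 0.90
        # the reported value matches an independent re-measurement
        assert ident == pytest.approx(pairwise_identity(seq, out))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sim.mutate_sequence("ACGT" * 30, 0.7)
        with pytest.raises(ValueError):
            sim.mutate_sequence("ACGN" * 30, 0.1)


def small_design(pool, sites=("gut",), samples=5, reads=200, **kw):
    plan = {sid: {s: kw.pop("presence", 1.0) for s in sites} for sid in pool.ids}
    return sim.SimulationDesign(
        body_sites=list(sites),
        samples_per_site=samples,
        reads_per_sample=reads,
        prevalence_plan=plan,
        seed=kw.pop("seed", 9),
        **kw,
    )


class TestSimulateSamples:
    def test_error_free_reads_are_source_copies(self):
        pool = sim.generate_source_pool(4, 120, seed=4)
        design = small_design(pool, error_rate=0.0, indel_rate=0.0)
        reads, truth = sim.simulate_samples(pool, design)
        sources = dict(pool.sources)
        origins = truth.read_origins.set_index("read_id")
        for rid, seq in reads.records:
            assert seq == sources[origins.at[rid, "source_id"]]

    def test_read_conservation_and_attribution(self):
        pool = sim.generate_source_pool(4, 120, seed=4)
        design = small_design(pool, samples=4, reads=50, chimera_rate=0.1, seed=2)
        reads, truth = sim.simulate_samples(pool, design)
        assert len(reads) == 4 * 50
        assert len(truth.read_origins) == len(reads)
        assert truth.read_origins["read_id"].is_unique
        # every read has a source xor a parent pair
        for row in truth.read_origins.itertuples(index=False):
            if row.source_id:
                assert not row.parent_a and row.breakpoint == -1
            else:
                assert row.parent_a and row.parent_b and row.breakpoint >= 0

    def test_chimera_count_binomial(self):
        pool = sim.generate_source_pool(6, 150, seed=5)
        design = small_design(pool, samples=5, reads=200, chimera_rate=0.1, seed=3)
        reads, truth = sim.simulate_samples(pool, design)
        n = truth.n_chimeric_reads
        lo, hi = stats.binom.interval(0.999, 1000, 0.1)
        assert lo <= n <= hi

    def test_chimera_breakpoints_central(self):
        pool = sim.generate_source_pool(6, 150, seed=5)
        design = small_design(pool, samples=5, reads=200, chimera_rate=0.1, seed=3)
        _, truth = sim.simulate_samples(pool, design)
        bps = truth.read_origins.loc[
            truth.read_origins["source_id"] == "", "breakpoint"
        ]
        assert ((bps >= 30) & (bps < 120)).all()  # central 60% of 150

    def test_planted_prevalence_binomial(self):
        pool = sim.generate_source_pool(5, 150, seed=6)
        sites = ["gut"]
        plan = {sid: {"gut": 1.0} for sid in pool.ids}
        plan[pool.ids[0]] = {"gut": 0.5}
        design = sim.SimulationDesign(
            body_sites=sites, samples_per_site=40, reads_per_sample=100,
            prevalence_plan=plan, seed=10,
        )
        _, truth = sim.simulate_samples(pool, design)
        prev = truth.site_prevalence[pool.ids[0]]["gut"]
        lo, hi = stats.binom.interval(0.95, 40, 0.5)
        assert lo / 40 - 1e-9 <= prev <= hi / 40 + 1e-9

    def test_determinism_byte_identical_outputs(self, tmp_path):
        out = []
        for run in ("a", "b"):
            com = sim.demo_community(seed=33)
            paths = sim.write_simulation(tmp_path / run, com)
            out.append({p.name: p.read_bytes() for p in sorted(paths.values())})
        assert out[0] == out[1]

    def test_empty_design_errors(self):
        pool = sim.generate_source_pool(2, 100, seed=1)
        with pytest.raises(ValueError):
            sim.SimulationDesign(
                body_sites=[], samples_per_site=1, reads_per_sample=1,
                prevalence_plan={},
            )
        with pytest.raises(ValueError):
            sim.simulate_samples(
                sim.SourcePool([], 0), small_design(pool)
            )


class TestGenerateReferenceDatabases:
    def _pool(self):
        return sim.generate_source_pool(4, 200, seed=8)

    def test_verbatim_entry_for_zero_divergence(self):
        pool = self._pool()
        plan = {
            "sequenced_human": {pool.ids[0]: 0.0},
            "cultured_named": {pool.ids[0]: 0.0},
        }
        dbs = sim.generate_reference_databases(pool, plan, seed=1)
        assert dbs["sequenced_human"].records[0][1] == pool.sources[0][1]

    def test_omitted_sources_absent(self):
        pool = self._pool()
        plan = {
            "sequenced_human": {pool.ids[0]: 0.1},
            "cultured_named": {sid: 0.0 for sid in pool.ids},
        }
        dbs = sim.generate_reference_databases(pool, plan, seed=1)
        assert len(dbs["sequenced_human"]) == 1
        assert len(dbs["cultured_named"]) == 4

    def test_unknown_source_errors(self):
        pool = self._pool()
        plan = {
            "sequenced_human": {"nope": 0.1},
            "cultured_named": {pool.ids[0]: 0.0},
        }
        with pytest.raises(ValueError, match="nope"):
            sim.generate_reference_databases(pool, plan, seed=1)

    def test_required_categories_enforced(self):
        pool = self._pool()
        with pytest.raises(ValueError, match="cultured_named"):
            sim.generate_reference_databases(
                pool, {"sequenced_human": {pool.ids[0]: 0.0}}, seed=1
            )

    def test_realized_identities_recorded(self):
        pool = self._pool()
        truth = sim.TruthTable()
        plan = {
            "sequenced_human": {sid: 0.05 for sid in pool.ids},
            "cultured_named": {sid: 0.0 for sid in pool.ids},
        }
        dbs = sim.generate_reference_databases(pool, plan, seed=2, truth=truth)
        for sid in pool.ids:
            ident = truth.db_identity["sequenced_human"][sid]
            assert ident == pytest.approx(0.95, abs=0.02)
            ref = dict(dbs["sequenced_human"].records)[f"sequenced_human|{sid}"]
            assert ident == pytest.approx(
                pairwise_identity(pool.sequence(sid), ref)
            )


class TestPlantedClasses:
    def test_planted_classes_follow_triage_rules(self):
        com = sim.demo_community(seed=21)
        truth = com["truth"]
        t = TriageThresholds()
        assert truth.planted_class  # non-empty
        for sid, cls in truth.planted_class.items():
            expected = assign_priority(
                truth.planted_sequenced_identity(sid),
                truth.planted_max_prevalence(sid),
                t,
            )
            assert cls == expected

    def test_zero_divergence_source_planted_low(self):
        com = sim.demo_community(seed=21)
        truth = com["truth"]
        for sid, ident in truth.db_identity["gold_human"].items():
            if ident == 1.0 and truth.planted_max_prevalence(sid) >= 0.2:
                assert truth.planted_class[sid] == "low"

    def test_identity_bands_planted(self):
        com = sim.standard_community(
            seed=5, n_sources=12, n_sites=2, samples_per_site=4,
            reads_per_sample=30, length=250,
        )
        truth = com["truth"]
        idents = [truth.planted_sequenced_identity(sid) for sid in
                  com["pool"].ids]
        assert any(i < 90 for i in idents)
        assert any(90 < i < 98 for i in idents)
        assert any(i >= 99 for i in idents)
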