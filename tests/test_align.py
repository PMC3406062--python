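"""Alignment, identity and database-search unit + property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otutriage.align import (
    Alignment,
    AlignmentParams,
    RefDb,
    aligning_fraction,
    best_match,
    global_align,
    match_profile,
    match_single_cells,
    pairwise_identity,
    percent_identity,
    reverse_complement,
    search_databases,
)

from _oracles import best_by_enumeration, gotoh_score, random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGlobalAlign:
    def test_identical(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.length == 4
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == 4.0

    def test_internal_gap(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        assert aln.aligned_a == "ACGTACGT"
        assert aln.aligned_b == "ACG-ACGT"

    def test_degapped_inputs_preserved(self):
        aln = global_align("ACGTACGTAA", "TTACGTACGT")
        assert aln.aligned_a.replace("-", "") == "ACGTACGTAA"
        assert aln.aligned_b.replace("-", "") == "TTACGTACGT"

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            global_align("ACGX", "ACGT")
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_scoring_params_validated(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=1.0)
        with pytest.raises(ValueError):
            AlignmentParams(match=-2.0, mismatch=-1.0)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_degapping_property(self, data):
        a = data.draw(dna)
        b = data.draw(dna)
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b
        assert len(aln.aligned_a) == len(aln.aligned_b)


class TestEnumerationOracle:
    """Exhaustive comparison on small pairs, free and penalized end gaps."""

    @pytest.mark.parametrize("free_ends", [True, False])
    def test_matches_enumeration(self, free_ends):
        rng = np.random.default_rng(42)
        params = AlignmentParams(end_gaps_free=free_ends)
        for _ in range(10):
            # one side up to 12 nt, the other small enough that exhaustive
            # path enumeration stays fast (< 20k paths per pair)
            la = int(rng.integers(1, 13))
            lb = int(rng.integers(1, 5)) if la > 6 else int(rng.integers(1, 7))
            a, b = random_dna(rng, la), random_dna(rng, lb)
            if free_ends and not set(a) & set(b):
                continue  # no substitution column possible
            oracle = best_by_enumeration(a, b, free_ends=free_ends)
            aln = global_align(a, b, params)
            assert aln.score == pytest.approx(oracle.best_score), (a, b)
            ident = percent_identity(aln)
            assert any(
                ident == pytest.approx(x) for x in oracle.identities
            ), (a, b, ident, oracle.identities)

    def test_related_pair_unique_optimum(self):
        # a substitution-only mutant has a unique gapless optimum
        a = "ACGTTGCA"
        b = "ACGTTGAA"
        oracle = best_by_enumeration(a, b)
        aln = global_align(a, b)
        assert aln.score == pytest.approx(oracle.best_score)
        assert percent_identity(aln) == pytest.approx(7 / 8)


class TestDPOracle:
    def test_scores_match_independent_dp(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            la = int(rng.integers(20, 201))
            lb = int(rng.integers(20, 201))
            a, b = random_dna(rng, la), random_dna(rng, lb)
            aln = global_align(a, b)
            assert aln.score == pytest.approx(gotoh_score(a, b)), (la, lb)

    def test_scores_match_penalized_ends(self):
        rng = np.random.default_rng(8)
        params = AlignmentParams(end_gaps_free=False)
        for _ in range(30):
            a = random_dna(rng, int(rng.integers(10, 80)))
            b = random_dna(rng, int(rng.integers(10, 80)))
            aln = global_align(a, b, params)
            assert aln.score == pytest.approx(gotoh_score(a, b, free_ends=False))


class TestPercentIdentity:
    def test_identical_20mer(self):
        aln = global_align("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert percent_identity(aln) == 1.0

    def test_one_mismatch_in_ten(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTTCGTAC") == pytest.approx(0.9)

    def test_internal_gap_counts_as_mismatch(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        assert percent_identity(aln) == pytest.approx(7 / 8)

    @given(dna)
    @settings(max_examples=40, deadline=None)
    def test_self_identity(self, a):
        assert pairwise_identity(a, a) == 1.0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, data):
        a = data.draw(dna)
        b = data.draw(dna)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_substitution_only_exact(self):
        # substitutions well separated and away from the ends, so the gapless
        # alignment is optimal and identity is exactly 1 - k/L
        rng = np.random.default_rng(3)
        for _ in range(40):
            L = int(rng.integers(100, 300))
            a = random_dna(rng, L)
            positions = np.arange(3, L - 3, 4)
            rng.shuffle(positions)
            k = int(rng.integers(1, 15))
            arr = list(a)
            for p in positions[:k]:
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            assert pairwise_identity(a, "".join(arr)) == pytest.approx(1 - k / L)


class TestAligningFraction:
    def test_full_length(self):
        aln = global_align("ACGTACGTACGT", "ACGTACGTACGT")
        assert aligning_fraction(aln, 12) == 1.0

    def test_partial_query(self):
        rng = np.random.default_rng(5)
        query = random_dna(rng, 100)
        ref = query[10:90]  # only 80 query bases can align
        aln = global_align(query, ref)
        assert aligning_fraction(aln, 100) == pytest.approx(0.8)

    def test_truncated_queries_match_direct_count(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            ref = random_dna(rng, 150)
            lo = int(rng.integers(0, 40))
            hi = int(rng.integers(110, 151))
            query = ref[lo:hi]
            aln = global_align(query, ref)
            span = aln.aligned_a[aln.lead_cols : aln.length - aln.trail_cols]
            direct = sum(1 for c in span if c != "-") / len(query)
            assert aligning_fraction(aln, len(query)) == pytest.approx(min(direct, 1.0))


class TestBestMatch:
    def _db(self, seqs, name="db", category="comprehensive"):
        return RefDb(name, category, tuple((f"r{i}", s) for i, s in enumerate(seqs)))

    def test_verbatim_hit(self):
        rng = np.random.default_rng(9)
        target = random_dna(rng, 80)
        db = self._db([random_dna(rng, 80), target, random_dna(rng, 80)])
        m = best_match("q", target, db)
        assert m.identity == 1.0 and m.ref_id == "r1"

    def test_tie_prefers_first_record(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        db = self._db([seq, seq])
        assert best_match("q", seq, db).ref_id == "r0"

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            best_match("q", "ACGT", self._db([]))

    def test_brute_force_scan(self):
        rng = np.random.default_rng(10)
        refs = [random_dna(rng, 60) for _ in range(20)]
        db = self._db(refs)
        for _ in range(50):
            q = random_dna(rng, 60)
            expected_idents = [pairwise_identity(q, r) for r in refs]
            best = max(expected_idents)
            first = expected_idents.index(best)
            m = best_match("q", q, db)
            assert m.identity == pytest.approx(best)
            assert m.ref_id == f"r{first}"

    def test_monotone_in_database_growth(self):
        rng = np.random.default_rng(11)
        q = random_dna(rng, 80)
        refs = [random_dna(rng, 80) for _ in range(10)]
        prev = -1.0
        for k in range(1, 11):
            m = best_match("q", q, self._db(refs[:k]))
            assert m.identity >= prev - 1e-12
            prev = m.identity


class TestMatchSingleCells:
    def _otu_db(self, rng):
        otus = [random_dna(rng, 120) for _ in range(5)]
        db = RefDb("otus", "comprehensive",
                   tuple((f"otu_{i}", s) for i, s in enumerate(otus)))
        return otus, db

    def test_exact_read(self, rng):
        otus, db = self._otu_db(rng)
        out = match_single_cells({"cell1": [("rd1", otus[2])]}, db, 0.97)
        row = out.iloc[0]
        assert row.otu_id == "otu_2" and row.identity == 1.0 and row.above_threshold

    def test_highest_aligning_fraction_wins(self, rng):
        otus, db = self._otu_db(rng)
        full = otus[0]  # aligning fraction 1.0
        partial = otus[0][:60] + random_dna(rng, 60)  # fraction ~0.5-ish
        out = match_single_cells({"c": [("partial", partial), ("full", full)]},
                                 db, 0.97)
        assert out.iloc[0].read_id == "full"

    def test_reverse_complement_found(self, rng):
        otus, db = self._otu_db(rng)
        out = match_single_cells({"c": [("rc", reverse_complement(otus[1]))]},
                                 db, 0.97)
        assert out.iloc[0].otu_id == "otu_1" and out.iloc[0].identity == 1.0

    def test_empty_cell_errors(self, rng):
        _, db = self._otu_db(rng)
        with pytest.raises(ValueError):
            match_single_cells({"c": []}, db, 0.97)

    def test_planted_sources_assigned(self, mini_community, mini_otus):
        otus, _ = mini_otus
        db = RefDb("otus", "comprehensive",
                   tuple((o.otu_id, o.consensus) for o in otus))
        pool = mini_community["pool"]
        rng = np.random.default_rng(13)
        cells = {}
        expect = {}
        for i, (sid, seq) in enumerate(pool.sources):
            cells[f"cell_{i}"] = [(f"cell_{i}_fwd", seq)]
            expect[f"cell_{i}"] = sid
        out = match_single_cells(cells, db, 0.97)
        # map each OTU back to its source by identity
        attribution = {}
        for o in otus:
            hits = [(pairwise_identity(o.consensus, s), sid)
                    for sid, s in pool.sources]
            attribution[o.otu_id] = max(hits)[1]
        correct = sum(
            attribution[row.otu_id] == expect[row.cell_id]
            for row in out.itertuples(index=False)
        )
        assert correct >= 0.95 * len(cells)


class TestMatchProfile:
    def test_profile_counts_matches(self):
        q = "ACGTACGT"
        assert match_profile(q, q).sum() == 8
        prof = match_profile("ACGTACGT", "ACGTTCGT")
        assert prof.sum() == 7

    def test_search_databases_shape(self, rng):
        refs = [random_dna(rng, 60) for _ in range(4)]
        dbs = {
            "a": RefDb("a", "sequenced_human", (("x", refs[0]), ("y", refs[1]))),
            "b": RefDb("b", "cultured_named", (("z", refs[2]),)),
        }
        out = search_databases([("q1", refs[0]), ("q2", refs[3])], dbs)
        assert len(out) == 4
        hit = out[(out.query_id == "q1") & (out.db_name == "a")].iloc[0]
        assert hit.identity == 1.0 and hit.category == "sequenced_human"
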