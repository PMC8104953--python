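from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import rbh_oracle
from phagecompare.align import Hit, NUCLEOTIDE_SCHEME, all_vs_all, filter_hits
from phagecompare.cgp import (
    all_binary_comparisons,
    best_hit,
    compare_binary,
    find_paralogs,
)
from phagecompare.errors import ConsistencyError
from phagecompare.genecalls import GeneCall, GeneCallSet, extract_gene_sequences


def calls_for(genome, gene_ids, caller="t"):
    return GeneCallSet.from_calls(
        genome, caller,
        [
            GeneCall(genome, "c1", 100 * i + 1, 100 * i + 90, "+", caller, gid)
            for i, gid in enumerate(gene_ids)
        ],
    )


def hit(q, s, score=100.0, evalue=None, length=90, coverage=90.0):
    return Hit(q, s, 90.0, length, score, evalue, coverage)


class TestBestHit:
    def test_highest_score_wins(self):
        assert best_hit([hit("a", "b1", 500), hit("a", "b2", 300)])[0] == "b1"

    def test_empty_list_gives_none(self):
        assert best_hit([]) is None

    def test_full_tie_resolves_to_lexicographically_smallest_subject(self):
        hits = [hit("a", "b3"), hit("a", "b1"), hit("a", "b2")]
        assert best_hit(hits)[0] == "b1"

    def test_evalue_breaks_score_tie_before_length(self):
        hits = [hit("a", "b1", evalue=1e-3, length=200), hit("a", "b2", evalue=1e-9, length=10)]
        assert best_hit(hits)[0] == "b2"

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            best_hit([hit("a", "b"), hit("z", "b")])


class TestCompareBinary:
    def test_reciprocal_best_pair_marked_mutual_both_ways(self):
        a, b = calls_for("A", ["a1"]), calls_for("B", ["b1"])
        rep_ab, rep_ba = compare_binary(
            a, b, [hit("a1", "b1")], [hit("b1", "a1")], 60, 75
        )
        assert rep_ab.records[0].status == "mutual"
        assert rep_ab.records[0].partner_gene == "b1"
        assert rep_ba.records[0].status == "mutual"
        assert rep_ba.records[0].partner_gene == "a1"

    def test_nonreciprocal_best_is_singular(self):
        # a1 -> b1, but b1's best is a2; a2 <-> b1 are each other's best
        a, b = calls_for("A", ["a1", "a2"]), calls_for("B", ["b1"])
        hits_ab = [hit("a1", "b1", 100), hit("a2", "b1", 200)]
        hits_ba = [hit("b1", "a2", 200), hit("b1", "a1", 100)]
        rep_ab, rep_ba = compare_binary(a, b, hits_ab, hits_ba, 60, 75)
        by_gene = {r.query_gene: r for r in rep_ab.records}
        assert by_gene["a1"].status == "singular"
        assert by_gene["a2"].status == "mutual"
        assert rep_ba.records[0].status == "mutual"

    def test_gene_without_hits_is_loner_with_no_partner(self):
        a, b = calls_for("A", ["a1", "a2"]), calls_for("B", ["b1"])
        rep_ab, _ = compare_binary(a, b, [hit("a1", "b1")], [hit("b1", "a1")], 60, 75)
        loner = {r.query_gene: r for r in rep_ab.records}["a2"]
        assert loner.status == "loner"
        assert loner.partner_gene is None and loner.hit is None

    def test_hit_naming_unknown_gene_rejected(self):
        a, b = calls_for("A", ["a1"]), calls_for("B", ["b1"])
        with pytest.raises(ConsistencyError):
            compare_binary(a, b, [hit("ghost", "b1")], [], 60, 75)

    def test_records_ordered_by_query_position(self):
        a = GeneCallSet.from_calls(
            "A", "t",
            [
                GeneCall("A", "c1", 500, 590, "+", "t", "late"),
                GeneCall("A", "c1", 1, 90, "+", "t", "early"),
            ],
        )
        b = calls_for("B", ["b1"])
        rep_ab, _ = compare_binary(a, b, [], [], 60, 75)
        assert [r.query_gene for r in rep_ab.records] == ["early", "late"]


hit_table = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=9),
        st.integers(min_value=0, max_value=9),
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=5),
    ),
    max_size=40,
)


@given(hit_table, hit_table)
def test_statuses_match_reciprocal_best_hit_oracle(raw_ab, raw_ba):
    """Classification equals the brute-force oracle and mutuality is symmetric."""
    a_genes = [f"a{i}" for i in range(10)]
    b_genes = [f"b{i}" for i in range(10)]
    # dedupe query/subject pairs: at most one hit per pair
    hits_ab = list({
        (a_genes[q], b_genes[s]): hit(a_genes[q], b_genes[s], float(sc), length=ln)
        for q, s, sc, ln in raw_ab
    }.values())
    hits_ba = list({
        (b_genes[q], a_genes[s]): hit(b_genes[q], a_genes[s], float(sc), length=ln)
        for q, s, sc, ln in raw_ba
    }.values())
    rep_ab, rep_ba = compare_binary(
        calls_for("A", a_genes), calls_for("B", b_genes), hits_ab, hits_ba, 0, 0
    )
    expected = rbh_oracle(a_genes, b_genes, hits_ab, hits_ba)
    got = {r.query_gene: (r.status, r.partner_gene) for r in rep_ab.records}
    assert got == expected
    # partition: every query exactly once
    assert sorted(got) == sorted(a_genes)
    # symmetry of mutuality across the directed pair
    mutual_ab = {(r.query_gene, r.partner_gene) for r in rep_ab.records if r.status == "mutual"}
    mutual_ba = {(r.partner_gene, r.query_gene) for r in rep_ba.records if r.status == "mutual"}
    assert mutual_ab == mutual_ba


@given(hit_table, st.integers(min_value=0, max_value=40))
def test_raising_cutoffs_never_revives_a_loner(raw_ab, ident):
    a_genes = [f"a{i}" for i in range(10)]
    b_genes = [f"b{i}" for i in range(10)]
    hits_ab = list({
        (a_genes[q], b_genes[s]): Hit(
            a_genes[q], b_genes[s], float(sc + 60), 90, float(sc), None, 90.0
        )
        for q, s, sc, _ in raw_ab
    }.values())
    loose, _ = compare_binary(
        calls_for("A", a_genes), calls_for("B", b_genes),
        filter_hits(hits_ab, 60, 0), [], 60, 0,
    )
    strict, _ = compare_binary(
        calls_for("A", a_genes), calls_for("B", b_genes),
        filter_hits(hits_ab, 60 + ident, 0), [], 60 + ident, 0,
    )
    loose_loners = {r.query_gene for r in loose.records if r.status == "loner"}
    strict_loners = {r.query_gene for r in strict.records if r.status == "loner"}
    assert loose_loners <= strict_loners


class TestFindParalogs:
    def test_planted_duplicate_gives_one_pair(self):
        calls = calls_for("A", ["a1", "a2"])
        pairs = find_paralogs(calls, [hit("a1", "a2"), hit("a2", "a1")])
        assert len(pairs) == 1
        assert (pairs[0].gene_a, pairs[0].gene_b) == ("a1", "a2")

    def test_self_hits_discarded(self):
        calls = calls_for("A", ["a1"])
        assert find_paralogs(calls, [hit("a1", "a1")]) == []

    def test_dissimilar_genome_has_no_paralogs(self):
        assert find_paralogs(calls_for("A", ["a1", "a2"]), []) == []

    def test_tandem_triplication_gives_three_pairs(self):
        calls = calls_for("A", ["a1", "a2", "a3"])
        hits = [
            hit(x, y)
            for x in ("a1", "a2", "a3")
            for y in ("a1", "a2", "a3")
        ]
        pairs = find_paralogs(calls, hits)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            ("a1", "a2"), ("a1", "a3"), ("a2", "a3")
        }

    def test_one_directional_hit_is_enough(self):
        calls = calls_for("A", ["a1", "a2"])
        pairs = find_paralogs(calls, [hit("a2", "a1")])
        assert len(pairs) == 1


class TestAllBinaryComparisons:
    def _inputs(self, truth, genome_ids):
        call_sets, seqs = {}, {}
        for genome in truth.genomes:
            gid = genome.genome_id
            if gid not in genome_ids:
                continue
            call_sets[gid] = truth.true_calls[gid]
            seqs[gid] = extract_gene_sequences(genome, truth.true_calls[gid])
        return call_sets, seqs

    def test_three_genomes_give_six_directed_reports(self, truth3):
        gids = truth3.genome_ids
        call_sets, seqs = self._inputs(truth3, gids)
        reports = all_binary_comparisons(
            gids, call_sets, seqs, NUCLEOTIDE_SCHEME, 60, 75
        )
        assert len(reports) == 6
        assert {(r.query_genome, r.subject_genome) for r in reports} == {
            (a, b) for a in gids for b in gids if a != b
        }

    def test_single_genome_skips_with_empty_result(self, truth3):
        gids = truth3.genome_ids[:1]
        call_sets, seqs = self._inputs(truth3, gids)
        assert all_binary_comparisons(
            gids, call_sets, seqs, NUCLEOTIDE_SCHEME, 60, 75
        ) == []

    def test_identical_genomes_are_fully_mutual(self, truth3):
        genome = truth3.genomes[1]
        gid = genome.genome_id
        calls = truth3.true_calls[gid]
        seqs = extract_gene_sequences(genome, calls)
        twin_calls = GeneCallSet.from_calls(
            "twin", "t",
            [GeneCall("twin", c.contig_id, c.left, c.right, c.strand, "t", c.gene_id + "x")
             for c in calls],
        )
        twin_seqs = {c.gene_id + "x": seqs[c.gene_id] for c in calls}
        reports = all_binary_comparisons(
            [gid, "twin"],
            {gid: calls, "twin": twin_calls},
            {gid: seqs, "twin": twin_seqs},
            NUCLEOTIDE_SCHEME, 60, 75,
        )
        for rep in reports:
            for rec in rep.records:
                assert rec.status == "mutual"
                assert rec.partner_gene.rstrip("x") == rec.query_gene.rstrip("x")

    def test_worker_count_does_not_change_results(self, truth3):
        gids = truth3.genome_ids
        call_sets, seqs = self._inputs(truth3, gids)
        serial = all_binary_comparisons(
            gids, call_sets, seqs, NUCLEOTIDE_SCHEME, 60, 75, workers=1
        )
        parallel = all_binary_comparisons(
            gids, call_sets, seqs, NUCLEOTIDE_SCHEME, 60, 75, workers=4
        )
        assert serial == parallel
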