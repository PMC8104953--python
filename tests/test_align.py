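from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import sw_local_score
from phagecompare.align import (
    Hit,
    NUCLEOTIDE_SCHEME,
    PROTEIN_SCHEME,
    ScoringScheme,
    all_vs_all,
    filter_hits,
    hit_sort_key,
    local_align,
    read_blast_tabular,
    write_blast_tabular,
)
from phagecompare.errors import ConfigError, ParseError


class TestLocalAlign:
    def test_identical_sequences_score_length_times_match(self):
        hit = local_align("ACGT", "ACGT", NUCLEOTIDE_SCHEME)
        assert hit.score == 8.0
        assert hit.pct_identity == 100.0
        assert hit.q_coverage == 100.0

    def test_fully_dissimilar_sequences_give_no_hit(self):
        assert local_align("AAAA", "GGGG", NUCLEOTIDE_SCHEME) is None

    def test_empty_sequence_gives_no_hit(self):
        assert local_align("", "ACGT", NUCLEOTIDE_SCHEME) is None
        assert local_align("ACGT", "", NUCLEOTIDE_SCHEME) is None

    def test_protein_self_alignment_positive(self):
        hit = local_align("MKVLA", "MKVLA", PROTEIN_SCHEME)
        assert hit.pct_identity == 100.0
        assert hit.score > 0

    def test_partial_overlap_coverage_below_full(self):
        # only the shared 6-mer aligns; query is 12 long
        hit = local_align("ACGTACTTTTTT", "ACGTAC", NUCLEOTIDE_SCHEME)
        assert hit.q_coverage == 50.0

    @given(
        st.text(alphabet="AC", min_size=1, max_size=8),
        st.text(alphabet="AC", min_size=1, max_size=8),
    )
    def test_score_matches_recursion_oracle(self, a, b):
        expected = sw_local_score(a, b, NUCLEOTIDE_SCHEME)
        hit = local_align(a, b, NUCLEOTIDE_SCHEME)
        got = hit.score if hit is not None else 0.0
        assert got == expected

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=12),
        st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_score_is_symmetric(self, a, b):
        ha = local_align(a, b, NUCLEOTIDE_SCHEME)
        hb = local_align(b, a, NUCLEOTIDE_SCHEME)
        assert (ha.score if ha else 0.0) == (hb.score if hb else 0.0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_self_alignment_is_gapless_full_identity(self, a):
        hit = local_align(a, a, NUCLEOTIDE_SCHEME)
        assert hit.score == len(a) * NUCLEOTIDE_SCHEME.match
        assert hit.pct_identity == 100.0

    def test_gap_penalties_must_be_nonpositive(self):
        with pytest.raises(ValueError):
            ScoringScheme("nucleotide", match=1, mismatch=-1, gap_open=1)


class TestAllVsAll:
    def test_dissimilar_maps_give_no_hits(self):
        assert all_vs_all({"q": "AAAA"}, {"s": "GGGG"}, NUCLEOTIDE_SCHEME) == []

    def test_identical_singletons_give_one_perfect_hit(self):
        hits = all_vs_all({"g": "ATGACGT"}, {"h": "ATGACGT"}, NUCLEOTIDE_SCHEME)
        assert len(hits) == 1
        assert hits[0].pct_identity == 100.0

    def test_planted_similar_pair_is_top_hit_among_decoys(self):
        rng = random.Random(1)
        base = "".join(rng.choice("ACGT") for _ in range(60))
        near = base[:30] + "T" + base[31:]  # ~98% identical
        queries = {"q": base}
        subjects = {
            "near": near,
            "decoy1": "".join(rng.choice("ACGT") for _ in range(60)),
            "decoy2": "".join(rng.choice("ACGT") for _ in range(60)),
        }
        hits = all_vs_all(queries, subjects, NUCLEOTIDE_SCHEME)
        per_pair = {
            h.subject_id: h.score
            for h in hits
        }
        assert hits[0].subject_id == "near"
        # agrees with direct per-pair alignment
        for sid, seq in subjects.items():
            direct = local_align(base, seq, NUCLEOTIDE_SCHEME)
            assert per_pair.get(sid, 0.0) == (direct.score if direct else 0.0)

    def test_hits_sorted_by_query_then_descending_score(self):
        queries = {"a": "ATGACGTACGT", "b": "ATGACGTACGT"}
        subjects = {"x": "ATGACGTACGT", "y": "ATGACG"}
        hits = all_vs_all(queries, subjects, NUCLEOTIDE_SCHEME)
        order = [(h.query_id, h.score) for h in hits]
        assert order == sorted(order, key=lambda t: (t[0], -t[1]))


def make_hit(**kw):
    base = dict(
        query_id="q", subject_id="s", pct_identity=90.0, aln_length=100,
        score=200.0, q_coverage=80.0,
    )
    base.update(kw)
    return Hit(**base)


class TestFilterHits:
    def test_identity_just_below_cutoff_is_removed(self):
        hits = [make_hit(pct_identity=59.9), make_hit(pct_identity=60.0)]
        assert filter_hits(hits, 60, 0) == [hits[1]]

    def test_zero_cutoffs_pass_everything_in_order(self):
        hits = [make_hit(score=s) for s in (5.0, 3.0, 9.0)]
        assert filter_hits(hits, 0, 0) == hits

    def test_mixed_fixture_keeps_exactly_qualifying_subset(self):
        hits = [
            make_hit(subject_id="s1", pct_identity=75.0, q_coverage=90.0),  # keep
            make_hit(subject_id="s2", pct_identity=55.0, q_coverage=90.0),  # low id
            make_hit(subject_id="s3", pct_identity=75.0, q_coverage=60.0),  # low cov
            make_hit(subject_id="s4", pct_identity=60.0, q_coverage=75.0),  # boundary
            make_hit(subject_id="s5", pct_identity=99.0, q_coverage=10.0),  # low cov
        ]
        kept = filter_hits(hits, 60, 75)
        assert [h.subject_id for h in kept] == ["s1", "s4"]

    def test_unknown_coverage_skips_coverage_test(self):
        hits = [make_hit(q_coverage=None)]
        assert filter_hits(hits, 60, 75) == hits

    def test_out_of_range_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            filter_hits([], -1, 0)
        with pytest.raises(ConfigError):
            filter_hits([], 0, 101)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=100),
                st.floats(min_value=0.1, max_value=100),
            ),
            max_size=20,
        ),
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=50),
    )
    def test_raising_cutoffs_never_adds_hits(self, specs, ident, cov, bump):
        hits = [
            make_hit(subject_id=f"s{i}", pct_identity=pi, q_coverage=qc)
            for i, (pi, qc) in enumerate(specs)
        ]
        base = filter_hits(hits, ident, cov)
        stricter = filter_hits(
            hits, min(ident + bump, 100.0), min(cov + bump, 100.0)
        )
        assert len(stricter) <= len(base)
        assert set(h.subject_id for h in stricter) <= set(h.subject_id for h in base)


class TestBlastTabular:
    LINE = "g1\tg2\t98.5\t300\t4\t0\t1\t300\t1\t300\t1e-50\t550\n"

    def test_outfmt6_line_maps_to_hit(self, tmp_path):
        p = tmp_path / "hits.tab"
        p.write_text(self.LINE)
        hits = read_blast_tabular(p, {"g1": 300})
        assert len(hits) == 1
        h = hits[0]
        assert (h.query_id, h.subject_id) == ("g1", "g2")
        assert (h.pct_identity, h.aln_length, h.score, h.evalue) == (98.5, 300, 550.0, 1e-50)
        assert h.q_coverage == 100.0

    def test_coverage_unset_without_query_lengths(self, tmp_path):
        p = tmp_path / "hits.tab"
        p.write_text(self.LINE)
        assert read_blast_tabular(p)[0].q_coverage is None

    def test_empty_file_gives_no_hits(self, tmp_path):
        p = tmp_path / "hits.tab"
        p.write_text("")
        assert read_blast_tabular(p) == []

    @pytest.mark.parametrize(
        "line", ["g1\tg2\t98.5\t300\t4\t0\t1\t300\t1\t300\t1e-50",  # 11 columns
                 "g1\tg2\thigh\t300\t4\t0\t1\t300\t1\t300\t1e-50\t550"]  # non-numeric
    )
    def test_malformed_line_raises_with_line_number(self, tmp_path, line):
        p = tmp_path / "hits.tab"
        p.write_text(line + "\n")
        with pytest.raises(ParseError, match=":1"):
            read_blast_tabular(p)

    def test_internal_hits_round_trip_losslessly(self, tmp_path):
        seqs = {f"g{i}": "ATGACGTACGTAGCTAGCTAAGCTT" for i in range(3)}
        subjects = {"h1": "ATGACGTACGTAGCAAGCTAAGCTT", "h2": "ATGACGTAC"}
        hits = all_vs_all(seqs, subjects, NUCLEOTIDE_SCHEME)
        assert hits
        p = tmp_path / "hits.tab"
        write_blast_tabular(hits, p)
        lengths = {k: len(v) for k, v in seqs.items()}
        assert read_blast_tabular(p, lengths) == hits


def test_best_hit_ordering_chain_is_total():
    """score desc, then e-value asc, then length desc, then subject id asc."""
    hits = [
        make_hit(subject_id="b", score=10.0, evalue=None, aln_length=50),
        make_hit(subject_id="a", score=10.0, evalue=None, aln_length=50),
        make_hit(subject_id="c", score=10.0, evalue=1e-5, aln_length=10),
        make_hit(subject_id="d", score=12.0, evalue=None, aln_length=5),
    ]
    ranked = sorted(hits, key=hit_sort_key)
    assert [h.subject_id for h in ranked] == ["d", "c", "a", "b"]
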