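import numpy as np
import pytest

from splicescreen import (
    ONE_ANCHOR,
    TWO_ANCHOR,
    FlankAlignment,
    GenomeIndex,
    GeometryParams,
    Junction,
    ScoringParams,
    align_flanks,
    classify,
    extract_flanks,
)
from splicescreen.flank import FlankPair

from conftest import random_dna
from _oracles import sw_oracle_score


def pair(ref, query):
    return FlankPair(ref, query, 0, 0, "c", False)


class TestExtractFlanks:
    def test_window_arithmetic(self, rng, geometry):
        genome = GenomeIndex({"c": random_dna(rng, 300)})
        fp = extract_flanks(Junction("c", 60, 160), genome, geometry)
        assert not fp.clipped
        assert fp.ref_origin == 10 and fp.query_origin == 110
        assert fp.ref_seq == genome.contigs["c"][10:110]
        assert fp.query_seq == genome.contigs["c"][110:210]

    def test_clipping_near_contig_start(self, rng, geometry):
        genome = GenomeIndex({"c": random_dna(rng, 300)})
        fp = extract_flanks(Junction("c", 20, 120), genome, geometry)
        assert fp.clipped
        assert len(fp.ref_seq) == 70
        assert fp.ref_origin == 0

    def test_short_intron_windows_overlap_genomically(self, rng, geometry):
        # a 54 bp intron leaves 46 bp of genomic overlap between the windows
        genome = GenomeIndex({"c": random_dna(rng, 400)})
        fp = extract_flanks(Junction("c", 150, 204), genome, geometry)
        assert fp.query_origin - fp.ref_origin == 54
        assert fp.ref_seq[54:] == fp.query_seq[:46]


class TestAlignFlanks:
    def test_identical_sequences_full_score(self, rng, scoring):
        seq = random_dna(rng, 100)
        a = align_flanks(pair(seq, seq), scoring)
        assert (a.score, a.ref_start, a.query_start) == (300, 0, 0)
        assert (a.ref_end, a.query_end) == (100, 100)
        assert a.cigar == "100M"
        assert a.blocks == [(0, 0, 100)]

    def test_single_mismatch_costs_match_plus_penalty(self, rng, scoring):
        seq = random_dna(rng, 100)
        other = "A" if seq[50] != "A" else "C"
        mut = seq[:50] + other + seq[51:]
        a = align_flanks(pair(seq, mut), scoring)
        assert a.score == 300 - 3 - 4
        assert (a.ref_start, a.ref_end) == (0, 100)

    def test_single_shared_8mer_below_chain_threshold(self, scoring):
        # one exact 8-mer (24 points) in otherwise dissimilar sequences
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ref, query = random_dna(rng, 100), random_dna(rng, 100)
            blk = random_dna(rng, 8)
            ref = ref[:20] + blk + ref[28:]
            query = query[:70] + blk + query[78:]
            if sw_oracle_score(ref, query) < scoring.min_chain_score:
                assert align_flanks(pair(ref, query), scoring) is None
                return
        pytest.fail("no draw produced an oracle optimum below the threshold")

    def test_no_alignment_for_empty_window(self, rng, scoring):
        assert align_flanks(pair("", random_dna(rng, 100)), scoring) is None

    def test_gap_cost_is_two_piece(self, rng, scoring):
        # 40 exact + one 30 bp deletion + 40 exact: long-piece gap is cheaper
        left, right = random_dna(rng, 40), random_dna(rng, 40)
        gap = random_dna(rng, 30)
        ref = left + gap + right
        query = left + right
        a = align_flanks(pair(ref, query), scoring)
        expected = 80 * 3 - min(12 + 2 * 30, 32 + 30)
        assert a.score == expected == sw_oracle_score(ref, query)

    def test_matches_bruteforce_oracle_on_planted_blocks(self, scoring):
        rng = np.random.default_rng(5)
        for _ in range(60):
            ref, query = random_dna(rng, 100), random_dna(rng, 100)
            blk = random_dna(rng, int(rng.integers(10, 41)))
            i = int(rng.integers(0, 101 - len(blk)))
            j = int(rng.integers(0, 101 - len(blk)))
            ref = ref[:i] + blk + ref[i + len(blk):]
            query = query[:j] + blk + query[j + len(blk):]
            oracle = sw_oracle_score(ref, query)
            a = align_flanks(pair(ref, query), scoring)
            if a is None:
                assert oracle < scoring.min_chain_score
            else:
                assert a.score == oracle

    def test_n_never_matches(self, scoring):
        a = align_flanks(pair("N" * 100, "N" * 100), scoring)
        assert a is None


class TestClassify:
    def full_end(self):
        return dict(ref_end=100, query_end=100)

    def make(self, rs, qs, re=100, qe=100):
        return FlankAlignment(ref_start=rs, ref_end=re, query_start=qs,
                              query_end=qe, score=100)

    def test_two_anchor_within_all_criteria(self, geometry):
        a = FlankAlignment(10, 95, 12, 93, 200)
        assert classify(a, geometry) == TWO_ANCHOR

    def test_large_shift_is_one_anchor(self, geometry):
        assert classify(self.make(0, 45), geometry) == ONE_ANCHOR

    def test_late_start_is_one_anchor(self, geometry):
        assert classify(self.make(44, 10), geometry) == ONE_ANCHOR

    @pytest.mark.parametrize("rs,qs,expected", [
        (43, 43, TWO_ANCHOR),   # start at boundary passes
        (44, 43, ONE_ANCHOR),   # one base past fails
        (0, 13, TWO_ANCHOR),    # shift 13 < 14 passes
        (0, 14, ONE_ANCHOR),    # shift 14 fails
    ])
    def test_start_and_shift_boundaries(self, geometry, rs, qs, expected):
        assert classify(self.make(rs, qs), geometry) == expected

    @pytest.mark.parametrize("re,expected", [
        (57, TWO_ANCHOR),  # last aligned offset 56 passes
        (56, ONE_ANCHOR),  # last aligned offset 55 fails
    ])
    def test_end_rule_boundary(self, geometry, re, expected):
        a = FlankAlignment(10, re, 10, 100, 100)
        assert classify(a, geometry) == expected

    def test_symmetric_under_ref_query_swap(self, geometry):
        rng = np.random.default_rng(11)
        for _ in range(200):
            rs, qs = rng.integers(0, 60, 2)
            re = int(rng.integers(rs + 1, 101))
            qe = int(rng.integers(qs + 1, 101))
            a = FlankAlignment(int(rs), re, int(qs), qe, 100)
            b = FlankAlignment(int(qs), qe, int(rs), re, 100)
            assert classify(a, geometry) == classify(b, geometry)

    def test_identical_flanks_always_two_anchor(self, rng, geometry, scoring):
        seq = random_dna(rng, 100)
        a = align_flanks(pair(seq, seq), scoring)
        assert classify(a, geometry) == TWO_ANCHOR
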