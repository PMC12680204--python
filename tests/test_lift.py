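from __future__ import annotations

import pytest

from flanklift.align import Alignment, AlignParams, FlankQuery
from flanklift.lift import (
    Chain,
    ChainBlock,
    LiftStatus,
    alignment_blocks,
    build_chains,
    classify_hits,
    lift_alleles,
    lift_by_chain,
    map_snp_position,
    read_chain_file,
    write_chain_file,
)


def _aln(tstart, score, tname="chr1", strand="+", colmap=(), qlen=101):
    return Alignment(
        marker_id="m", tname=tname, tstart0=tstart, tend0=tstart + qlen,
        strand=strand, qstart0=0, qend0=qlen, matches=score, mismatches=0,
        q_gap_bases=0, t_gap_bases=0, q_gap_openings=0, t_gap_openings=0,
        score=score, identity_pct=100.0, colmap=tuple(colmap),
    )


class TestClassifyHits:
    def test_empty_is_unmapped(self):
        assert classify_hits([], AlignParams()) is LiftStatus.UNMAPPED

    def test_tied_best_is_multi(self):
        a = _aln(100, 101, tname="chr1")
        b = _aln(5000, 101, tname="chr2")
        assert classify_hits([a, b], AlignParams()) is LiftStatus.MULTI_MAPPED

    def test_margin_zero_keeps_strict_best(self):
        a = _aln(100, 101)
        b = _aln(5000, 100)
        assert classify_hits([a, b], AlignParams()) is a

    def test_configurable_margin(self):
        a = _aln(100, 101)
        b = _aln(5000, 100)
        p = AlignParams(multi_margin=1)
        assert classify_hits([a, b], p) is LiftStatus.MULTI_MAPPED


class TestMapSnpPosition:
    def _query(self, snp_offset=50):
        return FlankQuery("m", "A" * 101, snp_offset, snp_offset, 100 - snp_offset, "src", 0)

    def test_ungapped_plus(self):
        colmap = tuple((i, 1000 + i) for i in range(101))
        a = _aln(1000, 101, colmap=colmap)
        assert map_snp_position(a, self._query()) == ("chr1", 1050, "+")

    def test_three_bp_target_deletion_before_snp(self):
        # query indices 47..49 are unaligned (target gap), shifting the SNP
        colmap = (
            tuple((i, 1000 + i) for i in range(47))
            + tuple((i, None) for i in range(47, 50))
            + tuple((i, 1000 + i - 3) for i in range(50, 101))
        )
        a = _aln(1000, 95, colmap=colmap)
        assert map_snp_position(a, self._query()) == ("chr1", 1047, "+")

    def test_minus_strand_full_cover(self):
        colmap = tuple((i, 2100 - i) for i in range(101))
        a = _aln(2000, 101, strand="-", colmap=colmap)
        assert map_snp_position(a, self._query()) == ("chr1", 2050, "-")

    def test_snp_in_target_gap_is_none(self):
        colmap = tuple((i, 1000 + i) for i in range(50)) + ((50, None),)
        a = _aln(1000, 49, colmap=colmap)
        assert map_snp_position(a, self._query()) is None

    def test_snp_outside_span_is_none(self):
        colmap = tuple((i, 1000 + i) for i in range(40))
        a = _aln(1000, 40, colmap=colmap)
        assert map_snp_position(a, self._query()) is None


class TestLiftAlleles:
    @pytest.mark.parametrize(
        "ref,alt,strand,expected",
        [
            ("A", "G", "+", ("A", "G")),
            ("A", "G", "-", ("T", "C")),
            ("C", "T", "-", ("G", "A")),
        ],
    )
    def test_examples(self, ref, alt, strand, expected):
        assert lift_alleles(ref, alt, strand) == expected


def _pair(src_start, tgt_start, length=101, chrom="chrA", tname="chr1", strand="+", score=101):
    """(Alignment, FlankQuery) with a fully aligned ungapped span."""
    if strand == "+":
        colmap = tuple((i, tgt_start + i) for i in range(length))
    else:
        colmap = tuple((i, tgt_start + length - 1 - i) for i in range(length))
    a = Alignment(
        marker_id="m", tname=tname, tstart0=tgt_start, tend0=tgt_start + length,
        strand=strand, qstart0=0, qend0=length, matches=length, mismatches=0,
        q_gap_bases=0, t_gap_bases=0, q_gap_openings=0, t_gap_openings=0,
        score=score, identity_pct=100.0, colmap=colmap,
    )
    q = FlankQuery("m", "A" * length, length // 2, length // 2,
                   length - length // 2 - 1, chrom, src_start)
    return a, q


class TestBuildChains:
    def test_three_collinear_blocks_one_chain(self):
        accepted = [_pair(0, 1000), _pair(201, 1201), _pair(402, 1402)]
        chains = build_chains(accepted, merge_gap=0)
        assert len(chains) == 1
        assert len(chains[0].blocks) == 3
        assert chains[0].score == 303

    def test_different_target_chroms_two_chains(self):
        accepted = [_pair(0, 1000, tname="chr1"), _pair(300, 1000, tname="chr2")]
        assert len(build_chains(accepted)) == 2

    def test_large_source_gap_splits(self):
        accepted = [_pair(0, 1000), _pair(50_101, 51_101)]
        chains = build_chains(accepted, max_gap=10_000)
        assert len(chains) == 2

    def test_equal_gap_same_diagonal_merges(self):
        # two blocks on one diagonal separated by a 1 bp substitution-only gap
        accepted = [_pair(0, 1000), _pair(102, 1102)]
        (chain,) = build_chains(accepted, merge_gap=2000)
        (block,) = chain.blocks
        assert (block.src_start0, block.src_end0) == (0, 203)
        assert (block.tgt_start0, block.tgt_end0) == (1000, 1203)

    def test_unequal_gap_never_merges(self):
        # source gap 1, target gap 4: different diagonals
        accepted = [_pair(0, 1000), _pair(102, 1105)]
        (chain,) = build_chains(accepted, merge_gap=2000)
        assert len(chain.blocks) == 2

    def test_overlapping_same_diagonal_merges(self):
        accepted = [_pair(0, 1000), _pair(50, 1050)]
        (chain,) = build_chains(accepted)
        (block,) = chain.blocks
        assert (block.src_start0, block.src_end0) == (0, 151)

    def test_minus_strand_collinearity(self):
        # consecutive source blocks map to decreasing target positions
        accepted = [_pair(0, 2000, strand="-"), _pair(150, 1850, strand="-")]
        (chain,) = build_chains(accepted, merge_gap=0)
        assert chain.strand == "-"
        assert len(chain.blocks) == 2

    def test_blocks_from_gapped_alignment_split(self):
        colmap = (
            tuple((i, 1000 + i) for i in range(50))
            + tuple((i, None) for i in range(50, 53))
            + tuple((i, 1000 + i - 3) for i in range(53, 101))
        )
        a = _aln_with(colmap)
        q = FlankQuery("m", "A" * 101, 50, 50, 50, "chrA", 0)
        blocks = alignment_blocks(a, q)
        assert len(blocks) == 2
        assert blocks[0].src_end0 - blocks[0].src_start0 == 50
        assert blocks[1].src_start0 == 53


def _aln_with(colmap):
    return Alignment(
        marker_id="m", tname="chr1", tstart0=1000, tend0=1098, strand="+",
        qstart0=0, qend0=101, matches=95, mismatches=0, q_gap_bases=3,
        t_gap_bases=0, q_gap_openings=1, t_gap_openings=0, score=94,
        identity_pct=96.9, colmap=colmap,
    )


class TestLiftByChain:
    def _chains(self):
        plus = Chain(
            "c1",
            [ChainBlock("chrA", 10, 30, "chr1", 110, 130, "+"),
             ChainBlock("chrA", 40, 60, "chr1", 140, 160, "+")],
            score=100,
        )
        minus = Chain(
            "c2", [ChainBlock("chrB", 10, 30, "chr1", 200, 220, "-")], score=50
        )
        return [plus, minus]

    def test_inside_block_offset(self):
        assert lift_by_chain("chrA", 15, self._chains()) == ("chr1", 115, "+")

    def test_between_blocks_unmapped(self):
        assert lift_by_chain("chrA", 35, self._chains()) is None

    def test_minus_block_mirrored_offset(self):
        assert lift_by_chain("chrB", 15, self._chains()) == ("chr1", 214, "-")

    def test_overlapping_chains_highest_score_wins(self):
        low = Chain("lo", [ChainBlock("chrA", 0, 100, "chr1", 0, 100, "+")], score=10)
        high = Chain("hi", [ChainBlock("chrA", 0, 100, "chr2", 500, 600, "+")], score=99)
        assert lift_by_chain("chrA", 50, [low, high]) == ("chr2", 550, "+")


class TestChainFile:
    def test_header_format(self, tmp_path):
        chains = [
            Chain("c1", [ChainBlock("chrA", 10, 30, "chr1", 110, 130, "+"),
                         ChainBlock("chrA", 40, 60, "chr1", 140, 160, "+")], score=77)
        ]
        p = tmp_path / "x.chain"
        write_chain_file(chains, {"chrA": 1000}, {"chr1": 2000}, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "chain 77 chrA 1000 + 10 60 chr1 2000 + 110 160 1"
        assert lines[1] == "20\t10\t10"
        assert lines[2] == "20"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_roundtrip_projection(self, tmp_path, strand):
        if strand == "+":
            blocks = [ChainBlock("chrA", 10, 30, "chr1", 110, 130, "+"),
                      ChainBlock("chrA", 40, 60, "chr1", 140, 160, "+")]
        else:
            blocks = [ChainBlock("chrA", 10, 30, "chr1", 180, 200, "-"),
                      ChainBlock("chrA", 40, 60, "chr1", 140, 160, "-")]
        chains = [Chain("c1", blocks, score=5)]
        p = tmp_path / "x.chain"
        write_chain_file(chains, {"chrA": 1000}, {"chr1": 2000}, p)
        back = read_chain_file(p)
        for pos in (10, 15, 29, 40, 59):
            assert lift_by_chain("chrA", pos, back) == lift_by_chain("chrA", pos, chains)
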