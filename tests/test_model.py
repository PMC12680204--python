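from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flanklift.dna import complement, revcomp
from flanklift.lift import LiftResult, LiftStatus
from flanklift.model import (
    FormatError,
    GenomeAssembly,
    GenotypeMatrix,
    InternalConsistencyError,
    Interval,
    Marker,
    load_genome,
    load_intervals,
    load_markers,
    read_lifted_vcf,
    write_intervals_bed,
    write_intervals_gff3,
    write_lifted_vcf,
    write_markers_tsv,
)


class TestLoadGenome:
    def test_two_record_lengths(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\n" + "A" * 60 + "\n>chr2\n" + "C" * 40 + "\n")
        g = load_genome(fa)
        assert g.lengths == {"chr1": 60, "chr2": 40}

    def test_lowercase_uppercased(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nacgtACGTn\n")
        g = load_genome(fa)
        assert g.sequences["chr1"] == "ACGTACGTN"
        assert g.lengths["chr1"] == 9

    def test_empty_file_errors(self, tmp_path):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        with pytest.raises(FormatError, match="no records"):
            load_genome(fa)

    def test_duplicate_name_errors(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGT\n>chr1\nACGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            load_genome(fa)

    def test_scaffold_detection_by_prefix_and_override(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGT\n>scaffold_9\nACGT\n")
        g = load_genome(fa)
        assert g.is_scaffold == {"chr1": False, "scaffold_9": True}
        g2 = load_genome(fa, scaffold_names=["chr1"])
        assert g2.is_scaffold == {"chr1": True, "scaffold_9": False}

    def test_invariant_lengths_match(self, small_genome):
        for s, seq in small_genome.sequences.items():
            assert small_genome.lengths[s] == len(seq)


class TestLoadMarkers:
    def test_tsv_one_based_conversion(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tchrom\tpos\tref\talt\nm1\tchr1\t51\tA\tG\n")
        (m,) = load_markers(p)
        assert (m.pos0, m.ref_allele, m.alt_allele) == (50, "A", "G")

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "id\tchrom\tpos\tref\talt\nm1\tchr1\t51\tA\tG\nm1\tchr1\t61\tC\tT\n"
        )
        with pytest.raises(FormatError, match="duplicate marker id"):
            load_markers(p)

    def test_vcf_equivalence(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t51\tm1\tA\tG\t.\t.\t.\n"
        )
        (m,) = load_markers(vcf)
        assert (m.id, m.chrom, m.pos0, m.ref_allele, m.alt_allele) == (
            "m1", "chr1", 50, "A", "G",
        )

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(FormatError, match="identical"):
            Marker("m1", "chr1", 10, "A", "A")

    def test_pos_beyond_end_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tchrom\tpos\tref\talt\nm1\tchr1\t9999\tA\tG\n")
        genome = GenomeAssembly("g", {"chr1": "ACGT" * 10})
        with pytest.raises(FormatError, match="beyond end"):
            load_markers(p, genome=genome)

    def test_roundtrip_tsv(self, tmp_path):
        markers = [Marker("m1", "chr1", 50, "A", "G"), Marker("m2", "chr2", 0, "C", "T")]
        p = tmp_path / "m.tsv"
        write_markers_tsv(markers, p)
        assert load_markers(p) == markers


class TestLoadIntervals:
    def test_bed_native(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tg1\t.\t+\n")
        (iv,) = load_intervals(p)
        assert (iv.start0, iv.end0, iv.name, iv.strand) == (10, 20, "g1", "+")

    def test_gff3_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\nchr1\tsrc\tgene\t11\t20\t.\t+\t.\tID=g1\n"
        )
        (iv,) = load_intervals(p, kind_filter="gene")
        assert (iv.start0, iv.end0, iv.kind) == (10, 20, "gene")

    def test_gff3_mrna_filtered_out(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\tmRNA\t11\t20\t.\t+\t.\tID=t1\n")
        assert load_intervals(p, kind_filter="gene") == []

    def test_te_class_prefix(self, tmp_path):
        p = tmp_path / "te.bed"
        p.write_text("chr1\t0\t100\tI_gypsy1\nchr1\t200\t300\tII_hAT2\n")
        a, b = load_intervals(p)
        assert a.kind == "te_class_I" and b.kind == "te_class_II"

    def test_empty_interval_errors(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t20\t20\tg1\n")
        with pytest.raises(FormatError):
            load_intervals(p)

    @given(
        start=st.integers(min_value=0, max_value=10_000),
        length=st.integers(min_value=1, max_value=5_000),
        fmt=st.sampled_from(["bed", "gff3"]),
    )
    @settings(max_examples=40, deadline=None)
    def test_coordinate_roundtrip_property(self, tmp_path_factory, start, length, fmt):
        """Internal half-open 0-based coordinates survive a write/load cycle
        through either external convention."""
        iv = Interval("chr1", start, start + length, name="f1", strand="+", kind="gene")
        d = tmp_path_factory.mktemp("ivs")
        p = d / f"x.{fmt}"
        if fmt == "bed":
            write_intervals_bed([iv], p)
            (back,) = load_intervals(p)
        else:
            write_intervals_gff3([iv], p)
            (back,) = load_intervals(p, kind_filter="gene")
        assert (back.chrom, back.start0, back.end0) == (iv.chrom, iv.start0, iv.end0)


class TestGenotypeMatrix:
    def test_shape_and_codes_enforced(self):
        with pytest.raises(FormatError):
            GenotypeMatrix(["m1"], ["a1", "a2"], np.array([[0]]))
        with pytest.raises(FormatError):
            GenotypeMatrix(["m1"], ["a1"], np.array([[5]]))

    def test_tsv_roundtrip(self, tmp_path):
        gm = GenotypeMatrix(
            ["m1", "m2"], ["a1", "a2", "a3"],
            np.array([[0, 1, 2], [-1, 0, 1]], dtype=np.int8),
        )
        p = tmp_path / "g.tsv"
        gm.to_tsv(p)
        back = GenotypeMatrix.from_tsv(p)
        assert back.marker_ids == gm.marker_ids
        assert back.accession_ids == gm.accession_ids
        assert (back.calls == gm.calls).all()


class TestWriteLiftedVcf:
    def _genome(self):
        return GenomeAssembly("t", {"chr1": "A" * 10 + "G" + "C" * 10})

    def test_count_conservation(self, tmp_path):
        target = self._genome()
        markers = [
            Marker("m1", "c", 1, "G", "T"),
            Marker("m2", "c", 2, "G", "T"),
            Marker("m3", "c", 3, "G", "T"),
            Marker("m4", "c", 4, "A", "C"),
        ]
        results = [
            LiftResult("m1", LiftStatus.LIFTED, "chr1", 10, "+", "G", "T"),
            LiftResult("m2", LiftStatus.LIFTED, "chr1", 10, "+", "G", "T"),
            LiftResult("m3", LiftStatus.LIFTED, "chr1", 10, "+", "G", "T"),
            LiftResult("m4", LiftStatus.UNMAPPED),
        ]
        out, rej = tmp_path / "o.vcf", tmp_path / "r.tsv"
        n = write_lifted_vcf(results, markers, target, out, rej)
        assert n == 3
        assert len(read_lifted_vcf(out)) == 3
        assert "m4\tUNMAPPED" in rej.read_text()

    def test_minus_strand_complemented_alleles(self, tmp_path):
        # target carries T at the site; marker alleles A/G on '-' lift to T/C
        target = GenomeAssembly("t", {"chr1": "C" * 5 + "T" + "C" * 5})
        markers = [Marker("m1", "c", 1, "A", "G")]
        results = [LiftResult("m1", LiftStatus.LIFTED, "chr1", 5, "-", "T", "C")]
        out = tmp_path / "o.vcf"
        write_lifted_vcf(results, markers, target, out)
        (back,) = read_lifted_vcf(out)
        assert (back.ref_allele, back.alt_allele) == ("T", "C")
        assert back.ref_allele == complement(markers[0].ref_allele)

    def test_empty_results_header_only(self, tmp_path):
        out = tmp_path / "o.vcf"
        n = write_lifted_vcf([], [], self._genome(), out)
        assert n == 0
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body == []

    def test_ref_disagreement_raises(self, tmp_path):
        target = GenomeAssembly("t", {"chr1": "AAAA"})
        markers = [Marker("m1", "c", 1, "G", "T")]
        results = [LiftResult("m1", LiftStatus.LIFTED, "chr1", 1, "+", "G", "T")]
        with pytest.raises(InternalConsistencyError):
            write_lifted_vcf(results, markers, target, tmp_path / "o.vcf")

    def test_marker_roundtrip_through_vcf(self, tmp_path):
        """load -> write -> load preserves id, coordinate and alleles when the
        target carries the ref allele."""
        seq = "ACGTACGTACGT"
        target = GenomeAssembly("t", {"chr1": seq})
        markers = [Marker("m1", "chr1", 6, seq[6], "A" if seq[6] != "A" else "C")]
        results = [
            LiftResult("m1", LiftStatus.LIFTED, "chr1", 6, "+",
                       markers[0].ref_allele, markers[0].alt_allele)
        ]
        out = tmp_path / "o.vcf"
        write_lifted_vcf(results, markers, target, out)
        assert read_lifted_vcf(out) == markers


def test_revcomp_basics():
    assert revcomp("ACGTN") == "NACGT"
    assert complement("A") == "T"
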