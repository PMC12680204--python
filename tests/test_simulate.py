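from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from flanklift.lift import LiftStatus, lift_by_chain
from flanklift.maf import compute_maf
from flanklift.simulate import (
    SimConfig,
    derive_target,
    generate_source,
    plant_markers,
    simulate_genotypes,
    simulate_pair,
    write_fixture,
)

SMALL = SimConfig(
    seed=11,
    chrom_lengths={"chr1": 60_000, "chr2": 40_000},
    scaffold_lengths={"scaffold_1": 8_000},
    n_markers=80,
    fate_quotas={
        "MULTI_MAPPED": 5,
        "UNMAPPED": 5,
        "ALLELE_DIVERGENT": 4,
        "LOW_IDENTITY": 4,
    },
    n_genes=10,
    n_tes=12,
)


@pytest.fixture(scope="module")
def fixture():
    return simulate_pair(SMALL)


class TestGenerateSource:
    def test_same_seed_identical(self):
        a, _, _ = generate_source(SMALL)
        b, _, _ = generate_source(SMALL)
        assert a.sequences == b.sequences

    def test_annotations_disjoint(self, fixture):
        by_chrom = {}
        for iv in fixture.genes + fixture.tes:
            by_chrom.setdefault(iv.chrom, []).append((iv.start0, iv.end0))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_annotated_bases_within_genome(self, fixture):
        total = sum(len(iv) for iv in fixture.genes + fixture.tes)
        assert total <= sum(fixture.source.lengths.values())

    def test_te_classes_split(self, fixture):
        kinds = {t.kind for t in fixture.tes}
        assert kinds == {"te_class_I", "te_class_II"}


class TestDeriveTarget:
    def test_no_edits_identity(self):
        cfg = SimConfig(
            seed=5,
            chrom_lengths={"chr1": 30_000},
            scaffold_lengths={},
            n_markers=10,
            fate_quotas={},
            background_sub_rate=0.0,
        )
        source, _, _ = generate_source(cfg)
        target, chains, _ = derive_target(source, cfg)
        assert target.sequences["chr1"] == source.sequences["chr1"]
        (chain,) = chains
        (block,) = chain.blocks
        assert (block.src_start0, block.src_end0) == (0, 30_000)
        assert (block.tgt_start0, block.tgt_end0) == (0, 30_000)

    def test_deletion_leaves_source_gap_in_truth_chain(self, fixture):
        log = fixture.edits_log
        assert log.deletions
        chrom, s, e = log.deletions[0]
        chain = next(c for c in fixture.truth_chain if c.tname_src == chrom)
        covered = any(b.src_start0 <= s < b.src_end0 for b in chain.blocks)
        assert not covered
        assert lift_by_chain(chrom, (s + e) // 2, fixture.truth_chain) is None

    def test_inverted_chrom_blocks_minus(self):
        cfg = SimConfig(
            seed=5,
            chrom_lengths={"chr1": 30_000, "chr2": 30_000},
            scaffold_lengths={},
            n_markers=10,
            fate_quotas={},
            invert_chrom="chr2",
        )
        source, _, _ = generate_source(cfg)
        _, chains, log = derive_target(source, cfg)
        assert log.inverted_chroms == ["chr2"]
        chain2 = next(c for c in chains if c.tname_src == "chr2")
        assert all(b.strand == "-" for b in chain2.blocks)

    def test_scaffold_anchored_into_chromosome(self, fixture):
        assert fixture.edits_log.anchored_scaffolds == [("scaffold_1", "chr1")]
        assert "scaffold_1" not in fixture.target.sequences
        sc_chain = next(c for c in fixture.truth_chain if c.tname_src == "scaffold_1")
        assert sc_chain.blocks[0].tname_tgt == "chr1"

    def test_truth_chain_collinearity_invariants(self, fixture):
        for chain in fixture.truth_chain:
            blocks = chain.blocks
            assert len({(b.tname_src, b.tname_tgt, b.strand) for b in blocks}) == 1
            for a, b in zip(blocks, blocks[1:]):
                assert a.src_end0 <= b.src_start0
                if chain.strand == "+":
                    assert a.tgt_end0 <= b.tgt_start0
                else:
                    assert b.tgt_end0 <= a.tgt_start0
            for b in blocks:
                assert b.src_end0 - b.src_start0 == b.tgt_end0 - b.tgt_start0


class TestPlantMarkers:
    def test_quota_counts(self, fixture):
        counts = Counter(t.expected_status for t in fixture.truth)
        assert counts[LiftStatus.MULTI_MAPPED] == 5
        assert counts[LiftStatus.UNMAPPED] == 5
        assert counts[LiftStatus.ALLELE_DIVERGENT] == 4
        assert counts[LiftStatus.LOW_IDENTITY] == 4
        assert counts[LiftStatus.LIFTED] == 80 - 18
        assert len(fixture.truth) == len(fixture.markers) == 80

    def test_one_truth_record_per_marker(self, fixture):
        assert {t.marker_id for t in fixture.truth} == {m.id for m in fixture.markers}

    def test_ref_allele_matches_source(self, fixture):
        for m in fixture.markers:
            assert m.ref_allele == fixture.source.base(m.chrom, m.pos0)
            assert m.ref_allele != m.alt_allele

    def test_lifted_truth_agrees_with_truth_chain(self, fixture):
        by_id = {m.id: m for m in fixture.markers}
        for t in fixture.truth:
            if t.expected_status is not LiftStatus.LIFTED:
                continue
            m = by_id[t.marker_id]
            assert lift_by_chain(m.chrom, m.pos0, fixture.truth_chain) == (
                t.expected_tname, t.expected_tpos0, t.expected_strand,
            )

    def test_divergent_target_base_outside_pair(self, fixture):
        by_pos = {(c, p): new for c, p, new in fixture.edits_log.divergent_sites}
        n = 0
        for m, t in zip(fixture.markers, fixture.truth):
            if t.expected_status is LiftStatus.ALLELE_DIVERGENT:
                new = by_pos[(m.chrom, m.pos0)]
                assert new not in {m.ref_allele, m.alt_allele}
                n += 1
        assert n == 4

    def test_unmapped_markers_inside_deletions(self, fixture):
        dels = fixture.edits_log.deletions
        for m, t in zip(fixture.markers, fixture.truth):
            if t.expected_status is LiftStatus.UNMAPPED:
                assert any(c == m.chrom and s <= m.pos0 < e for c, s, e in dels)

    def test_multi_markers_inside_duplications(self, fixture):
        dups = fixture.edits_log.dup_segments
        for m, t in zip(fixture.markers, fixture.truth):
            if t.expected_status is LiftStatus.MULTI_MAPPED:
                assert any(c == m.chrom and s <= m.pos0 < e for c, s, e in dups)


class TestSimulateGenotypes:
    def test_monomorphic_spectrum(self):
        gm = simulate_genotypes(
            [f"m{i}" for i in range(50)], 40, [("Monomorphic", 1.0)], seed=3
        )
        for mid in gm.marker_ids:
            assert compute_maf(gm.row(mid)) == 0.0

    def test_same_seed_identical(self):
        ids = [f"m{i}" for i in range(20)]
        a = simulate_genotypes(ids, 30, seed=9)
        b = simulate_genotypes(ids, 30, seed=9)
        assert (a.calls == b.calls).all()

    def test_half_frequency_calibration(self):
        """Binomial sampling at p=0.5 with n=1000 accessions: mean computed
        MAF over replicates is within 3 SE of 0.5."""
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, 0.5, size=(200, 1000)).astype(np.int8)
        mafs = [compute_maf(row) for row in calls]
        se = np.sqrt(0.5 * 0.5 / (2 * 1000))
        assert abs(np.mean(mafs) - 0.5) <= 3 * se

    def test_missing_rate_applied(self):
        gm = simulate_genotypes([f"m{i}" for i in range(30)], 50,
                                seed=2, missing_rate=0.2)
        frac = (gm.calls == -1).mean()
        assert 0.1 < frac < 0.3

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_genotypes(["m1"], 10, [("Monomorphic", 0.5)], seed=1)


class TestWriteFixture:
    def test_fixture_files_and_determinism(self, tmp_path):
        cfg = SimConfig(
            seed=21,
            chrom_lengths={"chr1": 40_000},
            scaffold_lengths={},
            n_markers=30,
            fate_quotas={"UNMAPPED": 3},
            n_genes=5,
            n_tes=6,
        )
        fx1 = write_fixture(cfg, tmp_path / "a")
        write_fixture(cfg, tmp_path / "b")
        for name in ("source.fa", "target.fa", "markers.tsv", "truth.tsv",
                     "genes.gff3", "tes.bed", "truth.chain", "genotypes_a.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name
        assert len(fx1.markers) == 30
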