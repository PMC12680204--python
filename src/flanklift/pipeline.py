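"""End-to-end orchestration: extract -> align -> classify -> lift -> validate.

The cascade order is fixed and each stage only downgrades results.  A
FilterCascade log records in/out counts at every stage so summary tables can
be cross-checked against the per-marker results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .align import AlignParams, align_flank, build_index, extract_flank
from .annotate import classify_failure, classify_region, scan_low_identity
from .lift import (
    Chain,
    LiftResult,
    LiftStatus,
    build_chains,
    classify_hits,
    lift_alleles,
    lift_by_chain,
    map_snp_position,
)
from .model import (
    GenomeAssembly,
    Marker,
    load_genome,
    load_intervals,
    load_markers,
    write_intervals_bed,
    write_json,
    write_lifted_vcf,
)
from .summary import FilterCascade, LiftoverSummary, check_consistency, summarize_liftover
from .validate import (
    ValidationParams,
    check_allele,
    validate_flank_identity,
    write_validation_report,
)
from .lift import write_chain_file


@dataclass
class PipelineConfig:
    flank: int = 50
    align: AlignParams = field(default_factory=AlignParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    chain_max_gap: int = 10_000
    chain_merge_gap: int = 2_000
    chain_fallback: bool = True
    near_window: int = 5_000


@dataclass
class PipelineResult:
    results: List[LiftResult]
    chains: List[Chain]
    cascade: FilterCascade
    summary: Optional[LiftoverSummary] = None


def lift_markers(
    markers: Sequence[Marker],
    source: GenomeAssembly,
    target: GenomeAssembly,
    cfg: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Lift every marker and run the validation cascade.

    Every input marker receives exactly one result; status counts partition
    the marker set.  Markers without an acceptable direct alignment get one
    chain-lift attempt through chains built from the accepted alignments of
    the other markers (multi-mapping markers stay failed: an ambiguous flank
    is ambiguous regardless of the chain).
    """
    cfg = cfg or PipelineConfig()
    index = build_index(target, cfg.align.k)

    queries = {m.id: extract_flank(m, source, cfg.flank) for m in markers}
    classified: Dict[str, object] = {}
    accepted = []
    for m in markers:
        q = queries[m.id]
        alns = align_flank(q, index, target, cfg.align)
        verdict = classify_hits(alns, cfg.align)
        classified[m.id] = verdict
        if not isinstance(verdict, LiftStatus):
            accepted.append((verdict, q))

    chains = build_chains(accepted, max_gap=cfg.chain_max_gap, merge_gap=cfg.chain_merge_gap)

    results: List[LiftResult] = []
    n_direct = n_chain = 0
    for m in markers:
        verdict = classified[m.id]
        if isinstance(verdict, LiftStatus):
            if verdict is LiftStatus.UNMAPPED and cfg.chain_fallback:
                hit = lift_by_chain(m.chrom, m.pos0, chains)
                if hit is not None:
                    tname, tpos0, strand = hit
                    ref, alt = lift_alleles(m.ref_allele, m.alt_allele, strand)
                    results.append(
                        LiftResult(
                            m.id, LiftStatus.LIFTED, tname, tpos0, strand,
                            ref, alt, provenance="chain",
                        )
                    )
                    n_chain += 1
                    continue
            results.append(LiftResult(m.id, verdict))
        else:
            q = queries[m.id]
            projected = map_snp_position(verdict, q)
            if projected is None:
                results.append(LiftResult(m.id, LiftStatus.GAP_AT_SITE))
                continue
            tname, tpos0, strand = projected
            ref, alt = lift_alleles(m.ref_allele, m.alt_allele, strand)
            results.append(
                LiftResult(
                    m.id, LiftStatus.LIFTED, tname, tpos0, strand,
                    ref, alt, provenance="direct_alignment",
                )
            )
            n_direct += 1

    cascade = FilterCascade(initial=len(markers))
    lifted0 = sum(1 for r in results if r.status is LiftStatus.LIFTED)
    cascade.remove("alignment_and_chain_lift", len(markers) - lifted0)

    by_id = {m.id: m for m in markers}
    results = [
        check_allele(r, by_id[r.marker_id], target) if r.status is LiftStatus.LIFTED else r
        for r in results
    ]
    lifted1 = sum(1 for r in results if r.status is LiftStatus.LIFTED)
    cascade.remove("allele_divergence", lifted0 - lifted1)

    results = [
        validate_flank_identity(r, by_id[r.marker_id], source, target, cfg.validation)
        if r.status is LiftStatus.LIFTED
        else r
        for r in results
    ]
    lifted2 = sum(1 for r in results if r.status is LiftStatus.LIFTED)
    cascade.remove("flank_identity", lifted1 - lifted2)

    return PipelineResult(results=results, chains=chains, cascade=cascade)


def run_pipeline(
    source_fasta: str | Path,
    target_fasta: str | Path,
    markers_path: str | Path,
    outdir: str | Path,
    genes_path: Optional[str | Path] = None,
    tes_path: Optional[str | Path] = None,
    cfg: Optional[PipelineConfig] = None,
    source_label: str = "source",
    target_label: str = "target",
) -> PipelineResult:
    """File-level pipeline: load inputs, lift, validate, annotate, write
    artifacts (lifted VCF + rejects, chain file, reports, summary JSON)."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    source = load_genome(source_fasta, name=source_label)
    target = load_genome(target_fasta, name=target_label)
    markers = load_markers(markers_path, genome=source)

    out = lift_markers(markers, source, target, cfg)
    out.summary = summarize_liftover(out.results, markers, source, target_label)
    check_consistency(out.results, out.summary)

    write_lifted_vcf(
        out.results, markers, target, outdir / "lifted.vcf", outdir / "rejects.tsv"
    )
    write_chain_file(out.chains, source.lengths, target.lengths, outdir / "lift.chain")
    write_validation_report(out.results, outdir / "results.tsv")

    payload: Dict[str, object] = {
        "cascade": out.cascade.as_dict(),
        "summary": {
            "version": out.summary.version_label,
            "total": out.summary.total,
            "lifted": out.summary.lifted,
            "failed": out.summary.failed,
            "lifted_pct": out.summary.lifted_pct,
            "failed_pct": out.summary.failed_pct,
            "failure_breakdown": out.summary.failure_breakdown,
            "strand_breakdown": out.summary.strand_breakdown,
            "rows": out.summary.rows,
        },
    }

    if genes_path is not None:
        genes = load_intervals(genes_path, kind_filter="gene")
        labels = {
            m.id: classify_region(
                m.chrom, m.pos0, genes, near_window=cfg.near_window, directional=True
            )
            for m in markers
        }
        payload["regions"] = {
            m.id: labels[m.id].value for m in markers
        }
    if tes_path is not None:
        tes = load_intervals(tes_path)
        low_idy = scan_low_identity(source, target, out.chains)
        write_intervals_bed(low_idy, outdir / "low_identity.bed")
        by_id = {m.id: m for m in markers}
        causes = {
            r.marker_id: classify_failure(by_id[r.marker_id], r, tes, low_idy).value
            for r in out.results
            if r.status is not LiftStatus.LIFTED
        }
        payload["failure_causes"] = causes

    write_json(payload, outdir / "summary.json")
    return out
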