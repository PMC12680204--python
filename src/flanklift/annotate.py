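"""Positional classification of markers and failure-cause analysis.

Markers are labelled genic / near-genic (upstream/downstream) / intergenic
against a gene interval set; failed markers are attributed to transposable
element classes or cross-assembly low-identity windows by a fixed priority.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .dna import revcomp
from .lift import Chain, LiftResult, LiftStatus, lift_by_chain
from .model import GenomeAssembly, Interval, Marker


@dataclass(frozen=True)
class RegionLabel:
    """Positional label of one marker relative to the gene annotation."""

    value: str  # genic | near_genic | upstream | downstream | intergenic
    nearest_gene: Optional[str] = None
    distance: Optional[int] = None


@dataclass(frozen=True)
class FailureCause:
    value: str  # te_class_I | te_class_II | low_identity_vs_target | other
    te_name: Optional[str] = None


def _distance(pos0: int, g: Interval) -> int:
    """bp from a position to the nearest gene boundary; 0 when inside."""
    if g.contains(pos0):
        return 0
    if pos0 < g.start0:
        return g.start0 - pos0
    return pos0 - (g.end0 - 1)


def classify_region(
    chrom: str,
    pos0: int,
    genes: Sequence[Interval],
    near_window: int = 5000,
    directional: bool = False,
) -> RegionLabel:
    """Label a position as genic, near-genic or intergenic.

    A position inside any gene is genic (distance 0).  Otherwise, within
    ``near_window`` bp (inclusive) of a gene boundary it is near-genic —
    refined to upstream/downstream of the nearest gene's strand when
    ``directional`` — else intergenic.  The nearest gene is chosen by minimal
    distance with ties broken by smaller start; direction ties resolve as
    upstream.
    """
    best: Optional[Tuple[int, int, Interval]] = None  # (distance, start, gene)
    for g in genes:
        if g.chrom != chrom:
            continue
        d = _distance(pos0, g)
        key = (d, g.start0, g)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return RegionLabel("intergenic", None, None)
    d, _, gene = best
    if d == 0:
        return RegionLabel("genic", gene.name, 0)
    if d > near_window:
        return RegionLabel("intergenic", gene.name, d)
    if not directional:
        return RegionLabel("near_genic", gene.name, d)
    # directional refinement; among equidistant genes prefer an upstream call
    directions = set()
    for g in genes:
        if g.chrom != chrom or _distance(pos0, g) != d:
            continue
        left_of_gene = pos0 < g.start0
        strand = g.strand if g.strand in {"+", "-"} else "+"
        upstream = (strand == "+" and left_of_gene) or (strand == "-" and not left_of_gene)
        directions.add("upstream" if upstream else "downstream")
    value = "upstream" if "upstream" in directions else "downstream"
    return RegionLabel(value, gene.name, d)


DEFAULT_PRIORITY = ("te_class_I", "te_class_II", "low_identity_vs_target", "other")


def classify_failure(
    marker: Marker,
    result: LiftResult,
    tes: Sequence[Interval],
    low_identity_regions: Sequence[Interval],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> FailureCause:
    """Attribute a failed marker to the first matching cause class.

    Membership is tested at the marker's source position; the first class in
    ``priority`` whose interval set contains it wins, else ``other``.
    """
    if result.status is LiftStatus.LIFTED:
        raise ValueError("classify_failure applies to failed markers only")
    by_class: Dict[str, Sequence[Interval]] = {
        "te_class_I": [t for t in tes if t.kind == "te_class_I"],
        "te_class_II": [t for t in tes if t.kind == "te_class_II"],
        "low_identity_vs_target": low_identity_regions,
    }
    for cls in priority:
        if cls == "other":
            break
        for iv in by_class.get(cls, ()):
            if iv.chrom == marker.chrom and iv.contains(marker.pos0):
                te_name = iv.name if cls.startswith("te_") else None
                return FailureCause(cls, te_name)
    return FailureCause("other")


def scan_low_identity(
    source: GenomeAssembly,
    target: GenomeAssembly,
    chains: Sequence[Chain],
    window: int = 1000,
    threshold_pct: float = 95.0,
) -> List[Interval]:
    """Tile the source genome and emit windows of low cross-assembly identity.

    Each window's midpoint is lifted through the chains; the corresponding
    target window is extracted in the mapped orientation and compared base by
    base (N matches nothing).  Windows below ``threshold_pct`` (strict) or
    with no chain projection are emitted; adjacent qualifying windows merge.
    """
    raw: List[Interval] = []
    for chrom, length in source.lengths.items():
        for ws in range(0, length, window):
            we = min(ws + window, length)
            mid = (ws + we) // 2
            hit = lift_by_chain(chrom, mid, chains)
            emit = False
            if hit is None:
                emit = True
            else:
                tname, tmid, strand = hit
                tlen = target.lengths[tname]
                left, right = mid - ws, we - mid
                src_win = source.fetch(chrom, ws, we)
                if strand == "+":
                    ts, te = tmid - left, tmid + right
                    if ts < 0 or te > tlen:
                        emit = True
                    else:
                        tgt_win = target.fetch(tname, ts, te)
                else:
                    ts, te = tmid - right + 1, tmid + left + 1
                    if ts < 0 or te > tlen:
                        emit = True
                    else:
                        tgt_win = revcomp(target.fetch(tname, ts, te))
                if not emit:
                    n = min(len(src_win), len(tgt_win))
                    matched = sum(
                        1
                        for a, b in zip(src_win[:n], tgt_win[:n])
                        if a == b and a != "N"
                    )
                    identity = 100.0 * matched / n if n else 0.0
                    emit = identity < threshold_pct
            if emit:
                raw.append(Interval(chrom, ws, we, name="low_identity", kind="low_identity"))

    merged: List[Interval] = []
    for iv in raw:
        if merged and merged[-1].chrom == iv.chrom and merged[-1].end0 == iv.start0:
            last = merged.pop()
            merged.append(
                Interval(last.chrom, last.start0, iv.end0, name="low_identity", kind="low_identity")
            )
        else:
            merged.append(iv)
    return merged


def scaffold_placement_report(
    markers: Sequence[Marker],
    results: Sequence[LiftResult],
    source: GenomeAssembly,
    target: GenomeAssembly,
) -> Dict[str, Dict[str, int]]:
    """Count marker placements by scaffold/chromosome origin and destination.

    Returns two partitions, one for scaffold-origin and one for
    chromosome-origin markers: lifted to a chromosome, lifted to a scaffold,
    or failed.
    """
    by_id = {r.marker_id: r for r in results}
    out = {
        "scaffold_origin": {"to_chromosome": 0, "to_scaffold": 0, "failed": 0},
        "chromosome_origin": {"to_chromosome": 0, "to_scaffold": 0, "failed": 0},
    }
    for m in markers:
        origin = "scaffold_origin" if source.is_scaffold.get(m.chrom) else "chromosome_origin"
        r = by_id[m.id]
        if r.status is not LiftStatus.LIFTED:
            out[origin]["failed"] += 1
        elif target.is_scaffold.get(r.tname):
            out[origin]["to_scaffold"] += 1
        else:
            out[origin]["to_chromosome"] += 1
    return out
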