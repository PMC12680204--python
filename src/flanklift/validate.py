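"""Post-liftover validation cascade.

Order is fixed: hit classification -> SNP projection -> allele check ->
flank-identity check.  Each filter can only downgrade a LIFTED result, never
resurrect a failed one, so the final statuses always partition the marker
set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .dna import complement, revcomp
from .lift import LiftResult, LiftStatus
from .model import GenomeAssembly, Marker


@dataclass
class ValidationParams:
    """Flank-identity validation settings.

    The SNP base itself is excluded from the identity computation by default:
    the array's polymorphic site legitimately differs between assemblies, and
    penalising it would fail valid markers whose target carries the alternate
    allele.
    """

    flank: int = 50
    identity_threshold_pct: float = 100.0
    exclude_snp_base: bool = True

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if not 0 <= self.identity_threshold_pct <= 100:
            raise ValueError("identity threshold must be in [0, 100]")


def check_allele(
    result: LiftResult, marker: Marker, target: GenomeAssembly
) -> LiftResult:
    """Verify the target base at the lifted position is one of the marker's
    two alleles (strand-normalized); otherwise downgrade to ALLELE_DIVERGENT.

    ``N`` in the target matches nothing and therefore fails the check.
    """
    if result.status is not LiftStatus.LIFTED:
        return result
    b = target.base(result.tname, result.tpos0)
    if result.strand == "-":
        b = complement(b)
    if b in (marker.ref_allele, marker.alt_allele):
        return result.downgrade(LiftStatus.LIFTED, target_allele=b)
    return result.downgrade(LiftStatus.ALLELE_DIVERGENT, target_allele=b)


def flank_identity(
    marker: Marker,
    result: LiftResult,
    source: GenomeAssembly,
    target: GenomeAssembly,
    p: ValidationParams,
) -> Tuple[float, int]:
    """Base-by-base identity between source and target flank windows.

    Windows are truncated at sequence ends; the comparison covers the overlap
    of the realized flank lengths on each side, orienting the target window
    by the lifted strand.  Returns (identity_pct, compared_positions).
    """
    f = p.flank
    src_len = source.lengths[marker.chrom]
    tgt_len = target.lengths[result.tname]
    up_s = min(f, marker.pos0)
    down_s = min(f, src_len - marker.pos0 - 1)
    tp = result.tpos0
    if result.strand == "+":
        up_t = min(f, tp)
        down_t = min(f, tgt_len - tp - 1)
    else:
        up_t = min(f, tgt_len - tp - 1)
        down_t = min(f, tp)
    up = min(up_s, up_t)
    down = min(down_s, down_t)

    src_win = source.fetch(marker.chrom, marker.pos0 - up, marker.pos0 + down + 1)
    if result.strand == "+":
        tgt_win = target.fetch(result.tname, tp - up, tp + down + 1)
    else:
        tgt_win = revcomp(target.fetch(result.tname, tp - down, tp + up + 1))

    matched = compared = 0
    for i, (a, b) in enumerate(zip(src_win, tgt_win)):
        if p.exclude_snp_base and i == up:
            continue
        compared += 1
        if a == b and a != "N":
            matched += 1
    identity = 100.0 * matched / compared if compared else 0.0
    return identity, compared


def validate_flank_identity(
    result: LiftResult,
    marker: Marker,
    source: GenomeAssembly,
    target: GenomeAssembly,
    p: ValidationParams,
) -> LiftResult:
    """Downgrade LIFTED results whose flank identity falls below threshold."""
    if result.status is not LiftStatus.LIFTED:
        return result
    identity, compared = flank_identity(marker, result, source, target, p)
    if compared == 0 or identity < p.identity_threshold_pct:
        return result.downgrade(LiftStatus.LOW_IDENTITY, identity_pct=identity)
    return result.downgrade(LiftStatus.LIFTED, identity_pct=identity)


# ---------------------------------------------------------------------------
# Cross-version comparison
# ---------------------------------------------------------------------------

def compare_versions(
    results_a: Sequence[LiftResult],
    results_b: Sequence[LiftResult],
    label_a: str = "a",
    label_b: str = "b",
    drop_multi_in_either: bool = False,
) -> Dict[str, int]:
    """Venn counts of final LIFTED status over a shared marker universe.

    With ``drop_multi_in_either``, a marker that multi-mapped in *either*
    version counts as lifted in neither (the stricter cross-version
    redundancy filter).
    """
    ids_a = {r.marker_id for r in results_a}
    ids_b = {r.marker_id for r in results_b}
    if ids_a != ids_b:
        raise ValueError("compare_versions requires the same marker universe")
    lifted_a = {r.marker_id for r in results_a if r.status is LiftStatus.LIFTED}
    lifted_b = {r.marker_id for r in results_b if r.status is LiftStatus.LIFTED}
    if drop_multi_in_either:
        multi = {
            r.marker_id
            for r in list(results_a) + list(results_b)
            if r.status is LiftStatus.MULTI_MAPPED
        }
        lifted_a -= multi
        lifted_b -= multi
    both = len(lifted_a & lifted_b)
    only_a = len(lifted_a - lifted_b)
    only_b = len(lifted_b - lifted_a)
    neither = len(ids_a) - both - only_a - only_b
    return {
        "both": both,
        f"only_{label_a}": only_a,
        f"only_{label_b}": only_b,
        "neither": neither,
    }


def compare_many(
    results_by_label: Dict[str, Sequence[LiftResult]]
) -> Dict[Tuple[bool, ...], int]:
    """Generalized membership table: one count per region of the Venn diagram
    over any number of result sets (2^n regions, summing to the universe)."""
    labels = list(results_by_label)
    universes = [
        {r.marker_id for r in results_by_label[lab]} for lab in labels
    ]
    universe = universes[0]
    if any(u != universe for u in universes[1:]):
        raise ValueError("compare_many requires the same marker universe")
    lifted = {
        lab: {r.marker_id for r in results_by_label[lab] if r.status is LiftStatus.LIFTED}
        for lab in labels
    }
    counts: Dict[Tuple[bool, ...], int] = {
        pattern: 0 for pattern in product((False, True), repeat=len(labels))
    }
    for mid in universe:
        pattern = tuple(mid in lifted[lab] for lab in labels)
        counts[pattern] += 1
    return counts


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["marker_id", "status", "tname", "tpos", "strand", "identity_pct", "reason"]


def write_validation_report(results: Sequence[LiftResult], path: str | Path) -> None:
    """TSV report of per-marker outcomes (tpos is 1-based in the file)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for r in results:
            w.writerow(
                [
                    r.marker_id,
                    r.status.name,
                    r.tname or "",
                    "" if r.tpos0 is None else r.tpos0 + 1,
                    r.strand or "",
                    "" if r.identity_pct is None else f"{r.identity_pct:.4f}",
                    "" if r.status is LiftStatus.LIFTED else r.status.name,
                ]
            )


def read_validation_report(path: str | Path) -> List[LiftResult]:
    results: List[LiftResult] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            results.append(
                LiftResult(
                    marker_id=row["marker_id"],
                    status=LiftStatus[row["status"]],
                    tname=row["tname"] or None,
                    tpos0=int(row["tpos"]) - 1 if row["tpos"] else None,
                    strand=row["strand"] or None,
                    identity_pct=float(row["identity_pct"]) if row["identity_pct"] else None,
                )
            )
    return results
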