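"""Aggregate per-marker results into summary tables and cascade accounting.

All percentages are rounded half-up at two decimals, which reproduces the
arithmetic of hand-checked count/denominator pairs (e.g. 175,202/180,950 ->
96.82; 756/1,354 -> 55.83).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Mapping, Optional, Sequence

from .annotate import FailureCause, RegionLabel
from .lift import FAILURE_STATUSES, LiftResult, LiftStatus
from .model import GenomeAssembly, Marker


def pct(count: int, denom: int) -> float:
    """``100 * count / denom`` rounded half-up to 2 decimals."""
    if denom == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# Filter cascade accounting
# ---------------------------------------------------------------------------

@dataclass
class FilterCascade:
    """Stage-by-stage accounting of a filter cascade.

    Start from a count of markers entering the cascade, remove per-stage
    counts, and read off the retained total; the log reproduces a
    flowchart-style in/out record for each stage.
    """

    initial: int
    stages: List[Dict[str, int]] = field(default_factory=list)

    def remove(self, stage: str, count: int) -> "FilterCascade":
        before = self.retained
        if count < 0 or count > before:
            raise ValueError(f"stage {stage!r} removes {count} of {before}")
        self.stages.append({"stage": stage, "in": before, "removed": count, "out": before - count})
        return self

    @property
    def retained(self) -> int:
        return self.initial - sum(s["removed"] for s in self.stages)

    def as_dict(self) -> Dict[str, object]:
        return {"initial": self.initial, "stages": list(self.stages), "retained": self.retained}


def failure_total(breakdown: Mapping[str, int]) -> int:
    """Sum of failure-category counts (the failed-total invariant)."""
    return sum(breakdown.values())


# ---------------------------------------------------------------------------
# Liftover summary (Table-1 shape)
# ---------------------------------------------------------------------------

@dataclass
class LiftoverSummary:
    version_label: str
    rows: List[Dict[str, object]]  # per source chromosome; scaffolds pooled
    total: int
    lifted: int
    failed: int
    lifted_pct: float
    failed_pct: float
    failure_breakdown: Dict[str, int]
    strand_breakdown: Dict[str, int]

    def check(self) -> None:
        assert self.lifted + self.failed == self.total
        assert failure_total(self.failure_breakdown) == self.failed
        assert self.strand_breakdown["forward"] + self.strand_breakdown["reverse"] == self.lifted
        for row in self.rows:
            assert row["lifted"] + row["failed"] == row["total"]


def summarize_liftover(
    results: Sequence[LiftResult],
    markers: Sequence[Marker],
    source: GenomeAssembly,
    version_label: str,
) -> LiftoverSummary:
    """Per-source-chromosome and total lifted/failed counts.

    Scaffold-origin markers are pooled into a single "Scaffolds" row.  All
    percentages use the grand marker total as denominator.
    """
    by_id = {r.marker_id: r for r in results}
    if set(by_id) != {m.id for m in markers}:
        raise ValueError("results and markers must cover the same marker set")

    groups: Dict[str, Dict[str, int]] = {}
    order: List[str] = []
    failure = {s.name: 0 for s in FAILURE_STATUSES}
    strands = {"forward": 0, "reverse": 0}
    for m in markers:
        key = "Scaffolds" if source.is_scaffold.get(m.chrom) else m.chrom
        if key not in groups:
            groups[key] = {"total": 0, "lifted": 0, "failed": 0}
            order.append(key)
        r = by_id[m.id]
        groups[key]["total"] += 1
        if r.status is LiftStatus.LIFTED:
            groups[key]["lifted"] += 1
            strands["forward" if r.strand == "+" else "reverse"] += 1
        else:
            groups[key]["failed"] += 1
            failure[r.status.name] += 1

    # chromosomes in source order, scaffolds pooled last
    ordered = [k for k in order if k != "Scaffolds"] + (
        ["Scaffolds"] if "Scaffolds" in groups else []
    )
    grand = len(markers)
    rows = []
    for key in ordered:
        g = groups[key]
        rows.append(
            {
                "chrom": key,
                "total": g["total"],
                "total_pct": pct(g["total"], grand),
                "lifted": g["lifted"],
                "lifted_pct": pct(g["lifted"], grand),
                "failed": g["failed"],
                "failed_pct": pct(g["failed"], grand),
            }
        )
    lifted = sum(g["lifted"] for g in groups.values())
    failed = grand - lifted
    summary = LiftoverSummary(
        version_label=version_label,
        rows=rows,
        total=grand,
        lifted=lifted,
        failed=failed,
        lifted_pct=pct(lifted, grand),
        failed_pct=pct(failed, grand),
        failure_breakdown=failure,
        strand_breakdown=strands,
    )
    summary.check()
    return summary


# ---------------------------------------------------------------------------
# Region and failure-cause tables (Tables 4-6 shapes)
# ---------------------------------------------------------------------------

LIFTED_REGION_ROWS = ("genic", "intergenic", "near_genic")
FAILED_REGION_ROWS = ("upstream", "genic", "intergenic", "downstream")


def summarize_regions(
    results: Sequence[LiftResult],
    labels: Mapping[str, RegionLabel],
    array_total: Optional[int] = None,
) -> Dict[str, Dict[str, Dict[str, object]]]:
    """Region tables for lifted and failed markers.

    The lifted table pools upstream/downstream into near-genic and uses the
    array grand total as percentage denominator; the failed table keeps the
    four directional rows and uses the failed-category total.
    """
    lifted_counts = {k: 0 for k in LIFTED_REGION_ROWS}
    failed_counts = {k: 0 for k in FAILED_REGION_ROWS}
    n_failed = 0
    for r in results:
        lab = labels.get(r.marker_id)
        if lab is None:
            continue
        if r.status is LiftStatus.LIFTED:
            value = "near_genic" if lab.value in {"upstream", "downstream", "near_genic"} else lab.value
            lifted_counts[value] += 1
        else:
            n_failed += 1
            # directional labels expected here; a non-directional near-genic
            # falls back to upstream (documented tie rule)
            value = "upstream" if lab.value == "near_genic" else lab.value
            failed_counts[value] += 1
    denom = array_total if array_total is not None else len(results)
    lifted_table = {
        k: {"count": v, "pct": pct(v, denom) if denom else "-"}
        for k, v in lifted_counts.items()
    }
    failed_table = {
        k: {"count": v, "pct": pct(v, n_failed) if n_failed else "-"}
        for k, v in failed_counts.items()
    }
    return {"lifted": lifted_table, "failed": failed_table}


FAILURE_CAUSE_ROWS = ("te_class_I", "te_class_II", "low_identity_vs_target", "other")


def summarize_failure_causes(
    causes_by_group: Mapping[str, Sequence[FailureCause]]
) -> Dict[str, Dict[str, Dict[str, object]]]:
    """Failure-cause counts per group with per-column percentages."""
    out: Dict[str, Dict[str, Dict[str, object]]] = {}
    for group, causes in causes_by_group.items():
        counts = {k: 0 for k in FAILURE_CAUSE_ROWS}
        for c in causes:
            counts[c.value] += 1
        total = len(causes)
        table = {
            k: {"count": v, "pct": pct(v, total) if total else "-"}
            for k, v in counts.items()
        }
        table["Total"] = {"count": total, "pct": "-"}
        out[group] = table
    return out


# ---------------------------------------------------------------------------
# Consistency checker
# ---------------------------------------------------------------------------

def check_consistency(results: Sequence[LiftResult], summary: LiftoverSummary) -> None:
    """Re-derive the summary counts from per-marker results and assert they
    agree; raises AssertionError on any discrepancy."""
    lifted = sum(1 for r in results if r.status is LiftStatus.LIFTED)
    assert lifted == summary.lifted, "lifted count mismatch"
    assert len(results) == summary.total, "total count mismatch"
    for status in FAILURE_STATUSES:
        derived = sum(1 for r in results if r.status is status)
        assert derived == summary.failure_breakdown[status.name], status.name
    summary.check()
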