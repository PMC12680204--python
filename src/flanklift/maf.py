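"""Minor-allele-frequency computation, spectrum binning and cross-collection
rare-allele comparison.

Conventions: a heterozygote contributes one alternate allele; missing
genotypes are excluded from the denominator.  Bin edges are lower-inclusive
half-open intervals except the top bin, and a MAF of exactly 0.40 belongs to
the 0.30~0.40 bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional

import numpy as np

from .model import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class MafBin:
    label: str
    lower: float  # inclusive (except Monomorphic/0.40> sentinels, see BINS)
    upper: float


#: Spectrum bins in display order.  Monomorphic holds exactly MAF == 0;
#: "<0.01" is (0, 0.01); interior bins are [lower, upper); "0.40>" is
#: (0.40, 0.5].
BINS: List[MafBin] = [
    MafBin("Monomorphic", 0.0, 0.0),
    MafBin("<0.01", 0.0, 0.01),
    MafBin("0.01~0.05", 0.01, 0.05),
    MafBin("0.05~0.10", 0.05, 0.10),
    MafBin("0.10~0.20", 0.10, 0.20),
    MafBin("0.20~0.30", 0.20, 0.30),
    MafBin("0.30~0.40", 0.30, 0.40),
    MafBin("0.40>", 0.40, 0.50),
]

BIN_LABELS = [b.label for b in BINS]


def compute_maf(calls: np.ndarray) -> Optional[float]:
    """MAF of one marker's genotype row (codes 0/1/2/-1).

    Returns ``None`` when every genotype is missing.
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    n = int(called.sum())
    if n == 0:
        return None
    alt = int(calls[called].sum())
    f = alt / (2 * n)
    return min(f, 1.0 - f)


def bin_maf(maf: float) -> MafBin:
    """Spectrum bin covering a MAF value in [0, 0.5]."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    if maf == 0.0:
        return BINS[0]
    if maf < 0.01:
        return BINS[1]
    for b in BINS[2:7]:
        if b.lower <= maf < b.upper:
            return b
    if maf <= 0.40:  # exactly 0.40 stays in 0.30~0.40
        return BINS[6]
    return BINS[7]


def percentage(count: int, denom: int) -> float:
    """``100 * count / denom`` rounded half-up to 2 decimals."""
    if denom == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def maf_table(
    matrix: GenotypeMatrix, lifted_ids: Iterable[str]
) -> Dict[str, Dict[str, object]]:
    """Per-bin marker counts and percentages over the lifted marker set.

    Percentages use the lifted-marker total as denominator and are reported
    as "-" when that total is zero.  Markers whose genotypes are entirely
    missing are tallied under ``missing`` and not binned.
    """
    wanted = set(lifted_ids)
    lifted = [m for m in matrix.marker_ids if m in wanted]
    counts = {label: 0 for label in BIN_LABELS}
    missing = 0
    for mid in lifted:
        maf = compute_maf(matrix.row(mid))
        if maf is None:
            missing += 1
        else:
            counts[bin_maf(maf).label] += 1
    total = len(lifted)
    table: Dict[str, Dict[str, object]] = {}
    for label in BIN_LABELS:
        pct = percentage(counts[label], total) if total else "-"
        table[label] = {"count": counts[label], "pct": pct}
    table["Total"] = {"count": total, "pct": "-"}
    if missing:
        table["missing"] = {"count": missing, "pct": "-"}
    return table


def cross_collection_rare(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    lifted_ids: Iterable[str],
) -> Dict[str, int]:
    """For markers rare (0 < MAF < 0.01) in collection A, their spectrum in B.

    The output bins partition A's rare set exactly; swapping the arguments
    gives the reciprocal table.
    """
    lifted = set(lifted_ids)
    out = {label: 0 for label in BIN_LABELS}
    out["missing_in_b"] = 0
    rare_total = 0
    for mid in matrix_a.marker_ids:
        if mid not in lifted or mid not in matrix_b:
            continue
        maf_a = compute_maf(matrix_a.row(mid))
        if maf_a is None or not (0.0 < maf_a < 0.01):
            continue
        rare_total += 1
        maf_b = compute_maf(matrix_b.row(mid))
        if maf_b is None:
            out["missing_in_b"] += 1
        else:
            out[bin_maf(maf_b).label] += 1
    out["rare_in_a_total"] = rare_total
    return out
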