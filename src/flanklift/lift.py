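"""Turn per-marker alignments into lifted coordinates; chain collinear blocks.

Two lifting paths exist, mirroring a flank-based liftover pipeline:

* **direct**: the marker's own flank alignment projects its SNP base through
  the alignment column map;
* **chain**: markers with no acceptable flank alignment of their own may
  still fall inside a collinear chain block built from the accepted
  alignments of neighbouring markers, and are then projected by block offset.

Direct alignment always takes precedence.  Positions falling between chain
blocks are never interpolated, with one carefully scoped exception: at chain
build time, consecutive collinear blocks separated by an *equal-length* gap
(same number of skipped source and target bases, i.e. the same alignment
diagonal) are merged into a single ungapped block when the gap is at most
``merge_gap`` bases.  Such regions differ from their counterpart only by
substitutions, so the positional projection through them is exact; this is
what lets markers whose own flank fails on a substitution (e.g. a diverged
SNP base) be lifted positionally and then judged by the downstream filters.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .align import Alignment, AlignParams, FlankQuery
from .dna import complement


class LiftStatus(enum.Enum):
    LIFTED = "LIFTED"
    UNMAPPED = "UNMAPPED"
    MULTI_MAPPED = "MULTI_MAPPED"
    ALLELE_DIVERGENT = "ALLELE_DIVERGENT"
    LOW_IDENTITY = "LOW_IDENTITY"
    GAP_AT_SITE = "GAP_AT_SITE"


FAILURE_STATUSES = (
    LiftStatus.UNMAPPED,
    LiftStatus.MULTI_MAPPED,
    LiftStatus.ALLELE_DIVERGENT,
    LiftStatus.LOW_IDENTITY,
    LiftStatus.GAP_AT_SITE,
)


@dataclass(frozen=True)
class LiftResult:
    """Per-marker liftover fate.

    Coordinates/alleles are present when the marker reached LIFTED at some
    point in the cascade; markers downgraded by a later filter (allele or
    identity check) keep them for diagnostics.
    """

    marker_id: str
    status: LiftStatus
    tname: Optional[str] = None
    tpos0: Optional[int] = None
    strand: Optional[str] = None
    lifted_ref: Optional[str] = None
    lifted_alt: Optional[str] = None
    identity_pct: Optional[float] = None
    provenance: Optional[str] = None  # direct_alignment | chain
    target_allele: Optional[str] = None

    def downgrade(self, status: LiftStatus, **kw) -> "LiftResult":
        return replace(self, status=status, **kw)


# ---------------------------------------------------------------------------
# Hit classification and SNP projection
# ---------------------------------------------------------------------------

def classify_hits(
    alignments: Sequence[Alignment], p: AlignParams
) -> Union[Alignment, LiftStatus]:
    """Resolve a marker's threshold-passing alignments to a unique hit.

    No hits -> UNMAPPED.  Two or more hits whose scores are within
    ``p.multi_margin`` of the best (default margin 0, i.e. exact ties) at
    distinct loci -> MULTI_MAPPED.  Otherwise the single best hit.
    """
    if not alignments:
        return LiftStatus.UNMAPPED
    best = max(a.score for a in alignments)
    top = [a for a in alignments if a.score >= best - p.multi_margin]
    if len(top) >= 2:
        return LiftStatus.MULTI_MAPPED
    return top[0]


def map_snp_position(
    a: Alignment, q: FlankQuery
) -> Optional[Tuple[str, int, str]]:
    """Project the SNP base through the alignment column map.

    Returns (tname, tpos0, strand) in target-forward coordinates, or ``None``
    when the SNP column is a target gap or lies outside the aligned span
    (the caller reports GAP_AT_SITE).
    """
    qs = [c[0] for c in a.colmap]
    i = bisect_left(qs, q.snp_offset)
    if i == len(qs) or qs[i] != q.snp_offset:
        return None
    t = a.colmap[i][1]
    if t is None:
        return None
    return a.tname, t, a.strand


def lift_alleles(ref: str, alt: str, strand: str) -> Tuple[str, str]:
    """Allele pair in target-forward orientation: identity on '+',
    base-complement of both on '-'."""
    if strand == "+":
        return ref, alt
    return complement(ref), complement(alt)


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainBlock:
    """One ungapped block mapping a source interval onto a target interval.

    Source and target intervals have equal length.  On '-' blocks the first
    source base maps to the *last* target base (target-forward coordinates).
    """

    tname_src: str
    src_start0: int
    src_end0: int
    tname_tgt: str
    tgt_start0: int
    tgt_end0: int
    strand: str

    def __post_init__(self) -> None:
        if self.src_end0 - self.src_start0 != self.tgt_end0 - self.tgt_start0:
            raise ValueError("chain block source/target lengths differ")

    def project(self, pos0: int) -> int:
        off = pos0 - self.src_start0
        if self.strand == "+":
            return self.tgt_start0 + off
        return self.tgt_end0 - 1 - off


@dataclass
class Chain:
    id: str
    blocks: List[ChainBlock]
    score: int

    @property
    def tname_src(self) -> str:
        return self.blocks[0].tname_src

    @property
    def tname_tgt(self) -> str:
        return self.blocks[0].tname_tgt

    @property
    def strand(self) -> str:
        return self.blocks[0].strand


def alignment_blocks(a: Alignment, q: FlankQuery) -> List[ChainBlock]:
    """Split one alignment into maximal ungapped source->target blocks."""
    blocks: List[ChainBlock] = []
    run: List[Tuple[int, int]] = []
    step = 1 if a.strand == "+" else -1

    def flush() -> None:
        if not run:
            return
        q0, t0 = run[0]
        q1, t1 = run[-1]
        ss, se = q.start0 + q0, q.start0 + q1 + 1
        ts, te = (t0, t1 + 1) if a.strand == "+" else (t1, t0 + 1)
        blocks.append(
            ChainBlock(q.chrom, ss, se, a.tname, ts, te, a.strand)
        )
        run.clear()

    for oq, t in a.colmap:
        if t is None:
            flush()
            continue
        if run and not (oq == run[-1][0] + 1 and t == run[-1][1] + step):
            flush()
        run.append((oq, t))
    flush()
    return blocks


def _diag_key(b: ChainBlock) -> int:
    # '+' blocks on one diagonal share tgt_start - src_start; '-' blocks
    # share the anti-diagonal tgt_end + src_start.
    if b.strand == "+":
        return b.tgt_start0 - b.src_start0
    return b.tgt_end0 + b.src_start0


def build_chains(
    accepted: Sequence[Tuple[Alignment, FlankQuery]],
    max_gap: int = 10_000,
    merge_gap: int = 2_000,
) -> List[Chain]:
    """Greedily chain the ungapped blocks of accepted alignments.

    Blocks are sorted by source position and linked into the current chain
    when they share (source seq, target seq, strand), remain collinear and
    both gaps are <= ``max_gap``; otherwise a new chain starts.  Consecutive
    blocks on the *same diagonal* whose gap is <= ``merge_gap`` are merged
    into a single ungapped block (see module docstring).  Chain score is the
    sum of its member alignments' scores.
    """
    tagged: List[Tuple[ChainBlock, int, int]] = []  # (block, aln_idx, score)
    for idx, (a, q) in enumerate(accepted):
        for b in alignment_blocks(a, q):
            tagged.append((b, idx, a.score))
    tagged.sort(
        key=lambda t: (t[0].tname_src, t[0].src_start0, t[0].src_end0, t[0].tname_tgt)
    )

    chains: List[Chain] = []
    cur_blocks: List[ChainBlock] = []
    cur_alns: Dict[int, int] = {}

    def close() -> None:
        nonlocal cur_blocks, cur_alns
        if cur_blocks:
            chains.append(
                Chain(
                    id=f"chain{len(chains) + 1}",
                    blocks=cur_blocks,
                    score=sum(cur_alns.values()),
                )
            )
        cur_blocks, cur_alns = [], {}

    for b, idx, score in tagged:
        if not cur_blocks:
            cur_blocks, cur_alns = [b], {idx: score}
            continue
        prev = cur_blocks[-1]
        same_pair = (
            b.tname_src == prev.tname_src
            and b.tname_tgt == prev.tname_tgt
            and b.strand == prev.strand
        )
        if same_pair and _diag_key(b) == _diag_key(prev):
            # same diagonal: overlap, abutment or an equal-length gap
            gap = b.src_start0 - prev.src_end0
            if gap <= merge_gap:
                if b.src_end0 > prev.src_end0:
                    merged = _merge_same_diag(prev, b)
                    cur_blocks[-1] = merged
                cur_alns[idx] = score
                continue
        src_gap = b.src_start0 - prev.src_end0
        if same_pair and src_gap >= 0 and src_gap <= max_gap:
            if b.strand == "+":
                tgt_gap = b.tgt_start0 - prev.tgt_end0
            else:
                tgt_gap = prev.tgt_start0 - b.tgt_end0
            if 0 <= tgt_gap <= max_gap:
                cur_blocks.append(b)
                cur_alns[idx] = score
                continue
        close()
        cur_blocks, cur_alns = [b], {idx: score}
    close()
    return chains


def _merge_same_diag(a: ChainBlock, b: ChainBlock) -> ChainBlock:
    ss = min(a.src_start0, b.src_start0)
    se = max(a.src_end0, b.src_end0)
    if a.strand == "+":
        ts = min(a.tgt_start0, b.tgt_start0)
        te = max(a.tgt_end0, b.tgt_end0)
    else:
        ts = min(a.tgt_start0, b.tgt_start0)
        te = max(a.tgt_end0, b.tgt_end0)
    return ChainBlock(a.tname_src, ss, se, a.tname_tgt, ts, te, a.strand)


def lift_by_chain(
    chrom: str, pos0: int, chains: Sequence[Chain]
) -> Optional[Tuple[str, int, str]]:
    """Project a source position through chain blocks.

    Positions between blocks are not interpolated (``None``); overlapping
    chains are resolved by the highest chain score.
    """
    best: Optional[Tuple[int, Tuple[str, int, str]]] = None
    for chain in chains:
        if chain.tname_src != chrom:
            continue
        for b in chain.blocks:
            if b.src_start0 <= pos0 < b.src_end0:
                cand = (chain.score, (b.tname_tgt, b.project(pos0), b.strand))
                if best is None or cand[0] > best[0]:
                    best = cand
                break
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# UCSC-style chain file writer
# ---------------------------------------------------------------------------

def write_chain_file(
    chains: Sequence[Chain],
    src_lengths: Dict[str, int],
    tgt_lengths: Dict[str, int],
    path: str | Path,
) -> None:
    """Write chains in UCSC chain format.

    The header is ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; here tName is the *source* sequence (always
    '+') and qName the target.  For '-' chains, q coordinates follow the
    UCSC convention of being measured on the reverse-complemented strand.
    """
    with open(path, "w") as fh:
        for i, chain in enumerate(chains, start=1):
            blocks = chain.blocks
            t_name = chain.tname_src
            q_name = chain.tname_tgt
            t_size = src_lengths[t_name]
            q_size = tgt_lengths[q_name]
            t_start = blocks[0].src_start0
            t_end = blocks[-1].src_end0
            strand = chain.strand
            if strand == "+":
                q_start = blocks[0].tgt_start0
                q_end = blocks[-1].tgt_end0
            else:
                q_start = q_size - blocks[0].tgt_end0
                q_end = q_size - blocks[-1].tgt_start0
            fh.write(
                f"chain {chain.score} {t_name} {t_size} + {t_start} {t_end} "
                f"{q_name} {q_size} {strand} {q_start} {q_end} {i}\n"
            )
            for j, b in enumerate(blocks):
                size = b.src_end0 - b.src_start0
                if j + 1 < len(blocks):
                    nb = blocks[j + 1]
                    dt = nb.src_start0 - b.src_end0
                    if strand == "+":
                        dq = nb.tgt_start0 - b.tgt_end0
                    else:
                        dq = b.tgt_start0 - nb.tgt_end0
                    fh.write(f"{size}\t{dt}\t{dq}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


def read_chain_file(path: str | Path) -> List[Chain]:
    """Parse a UCSC chain file written by :func:`write_chain_file`."""
    chains: List[Chain] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("chain "):
            raise ValueError(f"unexpected chain line: {line!r}")
        f = line.split()
        (_, score, t_name, _t_size, _t_strand, t_start, _t_end,
         q_name, q_size, q_strand, q_start, _q_end, cid) = f
        t_pos = int(t_start)
        q_size_i = int(q_size)
        blocks: List[ChainBlock] = []
        if q_strand == "+":
            q_pos = int(q_start)
        else:
            q_pos = int(q_start)  # reverse-strand coordinate
        i += 1
        while i < len(lines) and lines[i].strip():
            parts = lines[i].split()
            size = int(parts[0])
            if q_strand == "+":
                blocks.append(
                    ChainBlock(t_name, t_pos, t_pos + size, q_name, q_pos, q_pos + size, "+")
                )
            else:
                fwd_end = q_size_i - q_pos
                blocks.append(
                    ChainBlock(
                        t_name, t_pos, t_pos + size, q_name, fwd_end - size, fwd_end, "-"
                    )
                )
            t_pos += size
            q_pos += size
            if len(parts) == 3:
                t_pos += int(parts[1])
                q_pos += int(parts[2])
            i += 1
        chains.append(Chain(id=f"chain{cid}", blocks=blocks, score=int(score)))
    return chains
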