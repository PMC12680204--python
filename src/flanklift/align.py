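"""K-mer seeded, banded-extended local alignment of marker flank queries.

The aligner extracts a +/-50 bp flank window around each marker, seeds exact
k-mer hits against a forward-strand index of the target assembly (reverse
strand hits are found by aligning the reverse-complemented query), clusters
seeds by diagonal, and runs a local alignment over each cluster's implied
target window.

Scoring is deliberately simple and BLAT-psl-like:

* match +1, mismatch -1;
* each gap *opening* costs 1 regardless of length (extensions are free);
* ``score = matches - mismatches - q_gap_openings - t_gap_openings``;
* ``identity_pct = 100 * matches / (matches + mismatches + q_gap_bases +
  t_gap_bases)``.

Under the default thresholds (``min_score=100`` on a 101 bp query) this
reproduces the practical behaviour that acceptance demands a near-perfect
hit: a single substitution inside the aligned span already fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dna import encode, revcomp
from .model import GenomeAssembly, Marker

NEG_INF = np.int32(-(10 ** 6))


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankQuery:
    """The up+SNP+down flank window of one marker, taken verbatim from the
    source genome.  ``start0`` is the source coordinate of ``seq[0]`` so that
    query offsets can be projected back to source coordinates."""

    marker_id: str
    seq: str
    snp_offset: int
    up_len: int
    down_len: int
    chrom: str
    start0: int

    def __post_init__(self) -> None:
        assert len(self.seq) == self.up_len + 1 + self.down_len
        assert self.seq[self.snp_offset] == self.seq[self.up_len]


def extract_flank(marker: Marker, genome: GenomeAssembly, flank: int = 50) -> FlankQuery:
    """Extract the flank query for ``marker``; truncates at sequence ends."""
    chrom_len = genome.lengths[marker.chrom]
    if not 0 <= marker.pos0 < chrom_len:
        raise IndexError(f"marker {marker.id} position outside {marker.chrom}")
    up_len = min(flank, marker.pos0)
    down_len = min(flank, chrom_len - marker.pos0 - 1)
    start0 = marker.pos0 - up_len
    seq = genome.fetch(marker.chrom, start0, marker.pos0 + down_len + 1)
    return FlankQuery(
        marker_id=marker.id,
        seq=seq,
        snp_offset=up_len,
        up_len=up_len,
        down_len=down_len,
        chrom=marker.chrom,
        start0=start0,
    )


# ---------------------------------------------------------------------------
# Parameters and alignment record
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    """Aligner thresholds; defaults mirror BLAT's -tileSize/-minScore/-minIdentity."""

    k: int = 12
    min_score: int = 100
    min_identity_pct: float = 98.0
    max_seed_diag_gap: int = 5
    band: int = 10
    multi_margin: int = 0  # score margin for calling a multi-mapping tie

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31]")
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in [0, 100]")


@dataclass
class Alignment:
    """A scored local alignment of a flank query against the target.

    ``colmap`` pairs each aligned query index (original, forward-query
    coordinates) with a target index, or ``None`` where the target has a gap.
    Query indices are strictly increasing; target indices are strictly
    increasing on '+' and strictly decreasing on '-'.
    """

    marker_id: str
    tname: str
    tstart0: int
    tend0: int
    strand: str
    qstart0: int
    qend0: int
    matches: int
    mismatches: int
    q_gap_bases: int
    t_gap_bases: int
    q_gap_openings: int
    t_gap_openings: int
    score: int
    identity_pct: float
    colmap: Tuple[Tuple[int, Optional[int]], ...] = field(repr=False, default=())


def compute_identity(a: Alignment) -> float:
    """Percent identity of an alignment; errors on a zero-column alignment."""
    denom = a.matches + a.mismatches + a.q_gap_bases + a.t_gap_bases
    if denom == 0:
        raise ValueError("alignment has no columns; identity undefined")
    return 100.0 * a.matches / denom


# ---------------------------------------------------------------------------
# K-mer index
# ---------------------------------------------------------------------------

def _kmer_codes(enc: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every length-k window of an encoded sequence.

    ``codes[i]`` is the base-4 integer code of the k-mer starting at i;
    windows containing N are flagged invalid.
    """
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    clipped = np.where(enc < 0, 0, enc).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for off in range(k):
        codes = codes * 4 + clipped[off : off + n]
    bad = (enc < 0).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Forward-strand k-mer position index over a target assembly.

    Every overlapping k-mer (step 1) of every sequence is indexed; k-mers
    containing N are excluded.  Lookups are binary searches over per-sequence
    sorted code arrays, so memory stays proportional to the genome size.
    """

    def __init__(self, genome: GenomeAssembly, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.genome = genome
        self._tables: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for sname, seq in genome.sequences.items():
            codes, valid = _kmer_codes(encode(seq), k)
            pos = np.nonzero(valid)[0]
            vc = codes[pos]
            order = np.argsort(vc, kind="stable")
            self._tables[sname] = (vc[order], pos[order].astype(np.int64))

    def positions(self, kmer: str) -> List[Tuple[str, int]]:
        """All (tname, tpos) occurrences of an exact k-mer (testing helper)."""
        enc = encode(kmer)
        if enc.size != self.k or (enc < 0).any():
            return []
        code = np.int64(0)
        for b in enc:
            code = code * 4 + int(b)
        out = []
        for sname, (sc, sp) in self._tables.items():
            lo = np.searchsorted(sc, code, side="left")
            hi = np.searchsorted(sc, code, side="right")
            out.extend((sname, int(p)) for p in sp[lo:hi])
        return sorted(out)

    def seed_hits(self, qseq: str) -> Dict[str, List[Tuple[int, int]]]:
        """Per-sequence exact seed hits for ``qseq``: lists of (qpos, tpos)."""
        qcodes, qvalid = _kmer_codes(encode(qseq), self.k)
        hits: Dict[str, List[Tuple[int, int]]] = {}
        if qcodes.size == 0:
            return hits
        qidx = np.nonzero(qvalid)[0]
        qc = qcodes[qidx]
        for sname, (sc, sp) in self._tables.items():
            lo = np.searchsorted(sc, qc, side="left")
            hi = np.searchsorted(sc, qc, side="right")
            found = np.nonzero(hi > lo)[0]
            if found.size == 0:
                continue
            lst = []
            for j in found:
                qpos = int(qidx[j])
                for t in sp[lo[j] : hi[j]]:
                    lst.append((qpos, int(t)))
            if lst:
                hits[sname] = lst
        return hits


def build_index(genome: GenomeAssembly, k: int) -> KmerIndex:
    return KmerIndex(genome, k)


# ---------------------------------------------------------------------------
# Local alignment DP
# ---------------------------------------------------------------------------

def _local_align(qseq: str, tseq: str):
    """Best local alignment of ``qseq`` vs ``tseq`` under the package scoring.

    Returns (score, columns) where columns is a list of (qi, tj) pairs with
    ``qi is None`` for target-insertion columns and ``tj is None`` for
    query-insertion columns.  Returns (0, []) when no positive-scoring
    alignment exists.

    Three-state Gotoh with free gap extension.  The per-row recurrences are
    vectorised: the in-row gap state reduces to a shifted running maximum
    because extensions cost nothing.
    """
    n, m = len(qseq), len(tseq)
    if n == 0 or m == 0:
        return 0, []
    q = encode(qseq).astype(np.int32)
    t = encode(tseq).astype(np.int32)
    # match score row template: +1 where equal and unambiguous, else -1
    tmat = t[None, :]  # (1, m)

    D = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # ends in aligned pair
    P = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # ends in target-base gap col
    Q = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # ends in query-base gap col

    for i in range(1, n + 1):
        qi = q[i - 1]
        s = np.where((tmat[0] == qi) & (qi >= 0), 1, -1).astype(np.int32)
        dp, pp, qp = D[i - 1], P[i - 1], Q[i - 1]
        best_prev = np.maximum(np.maximum(dp, pp), qp)
        diag = np.maximum(best_prev[:-1], 0)
        D[i, 1:] = s + diag
        Q[i, 1:] = np.maximum(dp[1:] - 1, np.maximum(qp[1:], pp[1:] - 1))
        a = np.maximum(D[i], Q[i]) - 1
        P[i, 1:] = np.maximum.accumulate(a[:-1])

    score = int(D.max())
    if score <= 0:
        return 0, []

    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    i, j = int(i), int(j)
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    state = "D"
    while True:
        if state == "D":
            cols.append((i - 1, j - 1))
            s = 1 if (q[i - 1] == t[j - 1] and q[i - 1] >= 0) else -1
            prev = D[i, j] - s
            if prev == 0 and max(D[i - 1, j - 1], P[i - 1, j - 1], Q[i - 1, j - 1]) <= 0:
                break
            if D[i - 1, j - 1] == prev:
                state = "D"
            elif P[i - 1, j - 1] == prev:
                state = "P"
            else:
                state = "Q"
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
        elif state == "P":
            cols.append((None, j - 1))
            v = P[i, j]
            # prefer closing the gap (shortest gap run wins on identity)
            if D[i, j - 1] - 1 == v:
                state = "D"
            elif Q[i, j - 1] - 1 == v:
                state = "Q"
            else:
                state = "P"
            j -= 1
        else:  # Q
            cols.append((i - 1, None))
            v = Q[i, j]
            if D[i - 1, j] - 1 == v:
                state = "D"
            elif P[i - 1, j] - 1 == v:
                state = "P"
            else:
                state = "Q"
            i -= 1
    cols.reverse()
    return score, cols


def _columns_to_alignment(
    marker_id: str,
    qseq_oriented: str,
    qlen: int,
    tname: str,
    window_start: int,
    window_seq: str,
    strand: str,
    dp_result,
) -> Optional[Alignment]:
    """Turn DP columns into an :class:`Alignment` in forward coordinates."""
    score, cols = dp_result
    if not cols:
        return None
    matches = mismatches = 0
    q_gap_bases = t_gap_bases = 0
    q_gap_openings = t_gap_openings = 0
    prev_gap = None
    colmap: List[Tuple[int, Optional[int]]] = []
    t_indices: List[int] = []
    q_indices: List[int] = []
    for qi, tj in cols:
        if qi is not None and tj is not None:
            if qseq_oriented[qi] == window_seq[tj] and qseq_oriented[qi] != "N":
                matches += 1
            else:
                mismatches += 1
            prev_gap = None
        elif qi is None:  # target base unaligned (gap in query)
            t_gap_bases += 1
            if prev_gap != "t":
                t_gap_openings += 1
            prev_gap = "t"
        else:  # query base unaligned (gap in target)
            q_gap_bases += 1
            if prev_gap != "q":
                q_gap_openings += 1
            prev_gap = "q"
        # forward-coordinate bookkeeping
        if qi is not None:
            oq = qi if strand == "+" else qlen - 1 - qi
            q_indices.append(oq)
            if tj is not None:
                colmap.append((oq, window_start + tj))
            else:
                colmap.append((oq, None))
        if tj is not None:
            t_indices.append(window_start + tj)

    if strand == "-":
        colmap.reverse()
    qs, qe = min(q_indices), max(q_indices) + 1
    ts, te = min(t_indices), max(t_indices) + 1
    denom = matches + mismatches + q_gap_bases + t_gap_bases
    identity = 100.0 * matches / denom if denom else 0.0
    return Alignment(
        marker_id=marker_id,
        tname=tname,
        tstart0=ts,
        tend0=te,
        strand=strand,
        qstart0=qs,
        qend0=qe,
        matches=matches,
        mismatches=mismatches,
        q_gap_bases=q_gap_bases,
        t_gap_bases=t_gap_bases,
        q_gap_openings=q_gap_openings,
        t_gap_openings=t_gap_openings,
        score=score,
        identity_pct=identity,
        colmap=tuple(colmap),
    )


# ---------------------------------------------------------------------------
# Seed clustering and alignment of one query
# ---------------------------------------------------------------------------

def _cluster_windows(
    seeds: List[Tuple[int, int]], qlen: int, tlen: int, p: AlignParams
) -> List[Tuple[int, int]]:
    """Cluster seeds on nearby diagonals and return target DP windows."""
    diags = sorted((t - qpos, t) for qpos, t in seeds)
    windows = []
    cur = [diags[0]]
    for d in diags[1:]:
        if d[0] - cur[-1][0] <= p.max_seed_diag_gap:
            cur.append(d)
        else:
            windows.append(cur)
            cur = [d]
    windows.append(cur)
    out = []
    for grp in windows:
        dmin = grp[0][0]
        dmax = grp[-1][0]
        w0 = max(0, dmin - p.band)
        w1 = min(tlen, dmax + qlen + p.band)
        if w1 > w0:
            out.append((w0, w1))
    return out


def align_flank(
    q: FlankQuery, index: KmerIndex, genome: GenomeAssembly, p: AlignParams
) -> List[Alignment]:
    """Align a flank query against the indexed target assembly.

    Returns threshold-passing alignments (score >= min_score and identity >=
    min_identity_pct), deduplicated at >= 50% reciprocal target-span overlap
    and sorted by descending score (ties by (tname, tstart0)).  An empty list
    is a valid return.
    """
    if index.k != p.k:
        raise ValueError("index was built with a different k than AlignParams.k")
    qlen = len(q.seq)
    candidates: List[Alignment] = []
    seen_windows = set()
    for strand, oriented in (("+", q.seq), ("-", revcomp(q.seq))):
        for tname, seeds in index.seed_hits(oriented).items():
            tlen = genome.lengths[tname]
            for w0, w1 in _cluster_windows(seeds, qlen, tlen, p):
                key = (strand, tname, w0, w1)
                if key in seen_windows:
                    continue
                seen_windows.add(key)
                window_seq = genome.fetch(tname, w0, w1)
                result = _local_align(oriented, window_seq)
                aln = _columns_to_alignment(
                    q.marker_id, oriented, qlen, tname, w0, window_seq, strand, result
                )
                if aln is not None:
                    candidates.append(aln)

    passing = [
        a
        for a in candidates
        if a.score >= p.min_score and a.identity_pct >= p.min_identity_pct
    ]
    kept = _dedup_overlapping(passing)
    kept.sort(key=lambda a: (-a.score, a.tname, a.tstart0))
    return kept


def _dedup_overlapping(alignments: List[Alignment]) -> List[Alignment]:
    """Drop alignments whose target span reciprocally overlaps a kept,
    higher-scoring alignment by >= 50%."""
    ordered = sorted(alignments, key=lambda a: (-a.score, a.tname, a.tstart0))
    kept: List[Alignment] = []
    for a in ordered:
        dup = False
        for b in kept:
            if a.tname != b.tname:
                continue
            ov = min(a.tend0, b.tend0) - max(a.tstart0, b.tstart0)
            if ov <= 0:
                continue
            la, lb = a.tend0 - a.tstart0, b.tend0 - b.tstart0
            if ov >= 0.5 * la and ov >= 0.5 * lb:
                dup = True
                break
        if not dup:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# Debug dump
# ---------------------------------------------------------------------------

PSL_COLUMNS = [
    "marker_id", "tname", "tstart0", "tend0", "strand", "qstart0", "qend0",
    "matches", "mismatches", "q_gap_bases", "t_gap_bases",
    "q_gap_openings", "t_gap_openings", "score", "identity_pct",
]


def write_psl_like(alignments: Sequence[Alignment], path: str | Path) -> None:
    """PSL-like TSV dump of alignments for debugging."""
    with open(path, "w") as fh:
        fh.write("\t".join(PSL_COLUMNS) + "\n")
        for a in alignments:
            fh.write(
                "\t".join(str(getattr(a, c)) for c in PSL_COLUMNS[:-1])
                + f"\t{a.identity_pct:.4f}\n"
            )
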