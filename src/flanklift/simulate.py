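"""Seeded simulator of source/target assembly pairs with known edit structure.

The simulator plants markers whose liftover fate is known by construction:

* LIFTED markers sit in regions untouched by any edit (their expected target
  coordinate comes from the truth chain);
* MULTI_MAPPED markers sit inside a segment that is duplicated verbatim
  elsewhere, so two loci tie at full score;
* UNMAPPED markers sit inside segments deleted from the target;
* ALLELE_DIVERGENT markers sit at sites whose target base was substituted to
  a base outside the marker's allele pair.  Two anchor markers are planted
  just outside the site's flank window so the chain built from accepted
  alignments spans the site and the position can be lifted before the allele
  filter rejects it;
* LOW_IDENTITY markers sit inside windows given a 3% per-base substitution
  rate, likewise bracketed by anchor markers.

All edit footprints are placed disjointly by rejection sampling, so each
marker's fate has a single cause, and every random draw derives from one
root seed through fixed labelled streams.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dna import revcomp
from .lift import Chain, ChainBlock, LiftStatus, lift_by_chain, write_chain_file
from .model import (
    GenomeAssembly,
    GenotypeMatrix,
    Interval,
    Marker,
    write_intervals_bed,
    write_intervals_gff3,
    write_markers_tsv,
)

_BASES = np.array(list("ACGT"))

# fixed stream labels so any stage can be regenerated independently
_STREAMS = {"source": 1, "annotations": 2, "edits": 3, "markers": 4, "genotypes": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 300_000, "chr2": 200_000, "chr3": 150_000}
    )
    scaffold_lengths: Dict[str, int] = field(
        default_factory=lambda: {"scaffold_1": 20_000}
    )
    n_markers: int = 500
    #: target counts per failure fate; None derives 3%/3%/3%/2% of n_markers
    #: (the 500-marker default thus gets 15/15/15/10)
    fate_quotas: Optional[Dict[str, int]] = None
    background_sub_rate: float = 0.0005
    dup_length: int = 2_000
    deletion_length: int = 3_000
    diverged_window: int = 1_000
    diverged_sub_rate: float = 0.03
    n_genes: int = 60
    n_tes: int = 80
    flank: int = 50
    edge_margin: int = 500
    markers_per_segment: int = 5  # fate markers hosted per dup/del/window
    anchor_scaffold: bool = True
    invert_chrom: Optional[str] = None  # reverse-complement this target chrom
    scaffold_gap_n: int = 100

    def __post_init__(self) -> None:
        if self.fate_quotas is None:
            n = self.n_markers
            self.fate_quotas = {
                "MULTI_MAPPED": round(0.03 * n),
                "UNMAPPED": round(0.03 * n),
                "ALLELE_DIVERGENT": round(0.03 * n),
                "LOW_IDENTITY": round(0.02 * n),
            }
        quota = sum(self.fate_quotas.values())
        if quota > self.n_markers:
            raise ValueError("fate quotas exceed n_markers")
        # anchors planted next to divergent sites / diverged windows count
        # against the LIFTED quota
        n_anchors = 2 * self.fate_quotas.get("ALLELE_DIVERGENT", 0) + 2 * _n_segments(
            self.fate_quotas.get("LOW_IDENTITY", 0), self.markers_per_segment
        )
        if self.lifted_quota < n_anchors:
            raise ValueError(
                f"n_markers too small: {n_anchors} anchor markers exceed the "
                f"LIFTED quota of {self.lifted_quota}"
            )

    @property
    def lifted_quota(self) -> int:
        return self.n_markers - sum(self.fate_quotas.values())


@dataclass(frozen=True)
class TruthRecord:
    marker_id: str
    expected_status: LiftStatus
    expected_tname: Optional[str] = None
    expected_tpos0: Optional[int] = None
    expected_strand: Optional[str] = None


@dataclass
class EditsLog:
    """Planned edits, all in source coordinates."""

    dup_segments: List[Tuple[str, int, int]] = field(default_factory=list)
    dup_insertions: List[Tuple[str, int, str, int, int]] = field(default_factory=list)
    # (host_chrom, insert_pos, src_chrom, src_start, src_end)
    deletions: List[Tuple[str, int, int]] = field(default_factory=list)
    divergent_sites: List[Tuple[str, int, str]] = field(default_factory=list)
    diverged_windows: List[Tuple[str, int, int]] = field(default_factory=list)
    window_subs: Dict[str, List[int]] = field(default_factory=dict)  # chrom -> positions
    background_subs: Dict[str, List[int]] = field(default_factory=dict)
    anchored_scaffolds: List[Tuple[str, str]] = field(default_factory=list)  # (scaffold, host)
    inverted_chroms: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Source generation
# ---------------------------------------------------------------------------

def generate_source(
    config: SimConfig,
) -> Tuple[GenomeAssembly, List[Interval], List[Interval]]:
    """Uniform-random source assembly plus non-overlapping gene/TE intervals."""
    rng = _rng(config.seed, "source")
    sequences: Dict[str, str] = {}
    for name, length in {**config.chrom_lengths, **config.scaffold_lengths}.items():
        sequences[name] = "".join(rng.choice(_BASES, size=length))
    genome = GenomeAssembly(name="sim_source", sequences=sequences)

    arng = _rng(config.seed, "annotations")
    chroms = list(config.chrom_lengths)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in sequences}

    def place(length_range: Tuple[int, int]) -> Optional[Tuple[str, int, int]]:
        for _ in range(200):
            chrom = chroms[int(arng.integers(len(chroms)))]
            clen = config.chrom_lengths[chrom]
            flen = int(arng.integers(*length_range))
            if clen <= flen:
                continue
            s = int(arng.integers(0, clen - flen))
            if all(e <= s or s + flen <= b for b, e in occupied[chrom]):
                occupied[chrom].append((s, s + flen))
                return chrom, s, s + flen
        return None

    genes: List[Interval] = []
    for i in range(config.n_genes):
        spot = place((500, 3000))
        if spot is None:
            break
        chrom, s, e = spot
        strand = "+" if arng.random() < 0.5 else "-"
        genes.append(Interval(chrom, s, e, name=f"gene{i + 1:04d}", strand=strand, kind="gene"))

    tes: List[Interval] = []
    for i in range(config.n_tes):
        spot = place((200, 1500))
        if spot is None:
            break
        chrom, s, e = spot
        cls = "I" if i % 2 == 0 else "II"
        kind = "te_class_I" if cls == "I" else "te_class_II"
        tes.append(Interval(chrom, s, e, name=f"{cls}_te{i + 1:04d}", strand=".", kind=kind))
    return genome, genes, tes


# ---------------------------------------------------------------------------
# Target derivation
# ---------------------------------------------------------------------------

def _n_segments(quota: int, per: int) -> int:
    return math.ceil(quota / per) if quota > 0 else 0


def derive_target(
    source: GenomeAssembly, config: SimConfig
) -> Tuple[GenomeAssembly, List[Chain], EditsLog]:
    """Apply the configured edits to the source and return the edited target,
    the exact source->target truth chain, and the edit log."""
    rng = _rng(config.seed, "edits")
    log = EditsLog()
    q = config.fate_quotas
    flank = config.flank
    reserve_margin = 4 * flank  # keeps anchors and their flanks clear of other edits

    chroms = [c for c in source.sequences if not source.is_scaffold[c]]
    reserved: Dict[str, List[Tuple[int, int]]] = {c: [] for c in source.sequences}

    def reserve(chrom: str, span: int) -> Tuple[int, int]:
        clen = source.lengths[chrom]
        for _ in range(1000):
            s = int(rng.integers(config.edge_margin, clen - config.edge_margin - span))
            lo, hi = s - reserve_margin, s + span + reserve_margin
            if all(e <= lo or hi <= b for b, e in reserved[chrom]):
                reserved[chrom].append((lo, hi))
                return s, s + span
        raise RuntimeError(f"could not place an edit of {span} bp on {chrom}")

    def pick_chrom() -> str:
        return chroms[int(rng.integers(len(chroms)))]

    # --- plan structural edits -------------------------------------------
    for _ in range(_n_segments(q.get("MULTI_MAPPED", 0), config.markers_per_segment)):
        src_chrom = pick_chrom()
        s, e = reserve(src_chrom, config.dup_length)
        log.dup_segments.append((src_chrom, s, e))
        host = pick_chrom()
        ip, _ = reserve(host, 1)
        log.dup_insertions.append((host, ip, src_chrom, s, e))

    for _ in range(_n_segments(q.get("UNMAPPED", 0), config.markers_per_segment)):
        chrom = pick_chrom()
        s, e = reserve(chrom, config.deletion_length)
        log.deletions.append((chrom, s, e))

    for _ in range(q.get("ALLELE_DIVERGENT", 0)):
        chrom = pick_chrom()
        s, _ = reserve(chrom, 1)
        old = source.base(chrom, s)
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        log.divergent_sites.append((chrom, s, new))

    for _ in range(_n_segments(q.get("LOW_IDENTITY", 0), config.markers_per_segment)):
        chrom = pick_chrom()
        s, e = reserve(chrom, config.diverged_window)
        log.diverged_windows.append((chrom, s, e))
        positions = [
            int(p)
            for p in range(s, e)
            if rng.random() < config.diverged_sub_rate
        ]
        log.window_subs.setdefault(chrom, []).extend(positions)

    # --- background substitutions (clear of all reserved zones) ----------
    for chrom, seq in source.sequences.items():
        clen = len(seq)
        n_subs = rng.binomial(clen, config.background_sub_rate)
        zones = sorted(reserved[chrom])
        positions: List[int] = []
        attempts = 0
        while len(positions) < n_subs and attempts < 50 * n_subs + 100:
            attempts += 1
            p = int(rng.integers(0, clen))
            if any(b <= p < e for b, e in zones):
                continue
            positions.append(p)
        log.background_subs[chrom] = sorted(set(positions))

    # --- build the target -------------------------------------------------
    target_seqs: Dict[str, str] = {}
    truth_blocks: Dict[str, List[ChainBlock]] = {}

    mutated: Dict[str, np.ndarray] = {}
    for chrom, seq in source.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for p in log.background_subs.get(chrom, []):
            arr[p] = _substitute(arr[p], rng)
        for p in log.window_subs.get(chrom, []):
            arr[p] = _substitute(arr[p], rng)
        mutated[chrom] = arr
    for chrom, p, new in log.divergent_sites:
        mutated[chrom][p] = ord(new)

    for chrom in source.sequences:
        if source.is_scaffold[chrom]:
            continue  # scaffolds handled via anchoring below
        arr = mutated[chrom]
        dels = sorted(
            [(s, e) for c, s, e in log.deletions if c == chrom]
        )
        inserts = sorted(
            [(ip, sc, ss, se) for host, ip, sc, ss, se in log.dup_insertions if host == chrom]
        )
        pieces: List[str] = []
        blocks: List[ChainBlock] = []
        cursor = 0
        tpos = 0
        events: List[Tuple[int, str, tuple]] = []
        for s, e in dels:
            events.append((s, "del", (s, e)))
        for ip, sc, ss, se in inserts:
            events.append((ip, "ins", (sc, ss, se)))
        events.sort(key=lambda t: t[0])
        for pos, kind, payload in events:
            if pos > cursor:
                seg = arr[cursor:pos].tobytes().decode("ascii")
                pieces.append(seg)
                blocks.append(
                    ChainBlock(chrom, cursor, pos, chrom, tpos, tpos + len(seg), "+")
                )
                tpos += len(seg)
            if kind == "del":
                cursor = payload[1]
            else:
                sc, ss, se = payload
                copy = mutated[sc][ss:se].tobytes().decode("ascii")
                pieces.append(copy)
                tpos += len(copy)
                cursor = pos
        if cursor < len(arr):
            seg = arr[cursor:].tobytes().decode("ascii")
            pieces.append(seg)
            blocks.append(
                ChainBlock(chrom, cursor, len(arr), chrom, tpos, tpos + len(seg), "+")
            )
            tpos += len(seg)
        target_seqs[chrom] = "".join(pieces)
        truth_blocks[chrom] = blocks

    # --- scaffold anchoring ----------------------------------------------
    if config.anchor_scaffold and config.scaffold_lengths:
        host = chroms[0]
        for scaffold in config.scaffold_lengths:
            offset = len(target_seqs[host]) + config.scaffold_gap_n
            sc_seq = mutated[scaffold].tobytes().decode("ascii")
            target_seqs[host] = (
                target_seqs[host] + "N" * config.scaffold_gap_n + sc_seq
            )
            truth_blocks[scaffold] = [
                ChainBlock(scaffold, 0, len(sc_seq), host, offset, offset + len(sc_seq), "+")
            ]
            log.anchored_scaffolds.append((scaffold, host))
    else:
        for scaffold in config.scaffold_lengths:
            sc_seq = mutated[scaffold].tobytes().decode("ascii")
            target_seqs[scaffold] = sc_seq
            truth_blocks[scaffold] = [
                ChainBlock(scaffold, 0, len(sc_seq), scaffold, 0, len(sc_seq), "+")
            ]

    # --- optional whole-chromosome inversion ------------------------------
    if config.invert_chrom:
        chrom = config.invert_chrom
        length = len(target_seqs[chrom])
        target_seqs[chrom] = revcomp(target_seqs[chrom])
        log.inverted_chroms.append(chrom)
        for src_name, blocks in truth_blocks.items():
            flipped = []
            for b in blocks:
                if b.tname_tgt != chrom:
                    flipped.append(b)
                    continue
                ns, ne = length - b.tgt_end0, length - b.tgt_start0
                strand = "-" if b.strand == "+" else "+"
                flipped.append(
                    ChainBlock(b.tname_src, b.src_start0, b.src_end0, chrom, ns, ne, strand)
                )
            truth_blocks[src_name] = flipped

    chains: List[Chain] = []
    for i, (src_name, blocks) in enumerate(sorted(truth_blocks.items()), start=1):
        if not blocks:
            continue
        score = sum(b.src_end0 - b.src_start0 for b in blocks)
        chains.append(Chain(id=f"truth{i}", blocks=blocks, score=score))

    target = GenomeAssembly(name="sim_target", sequences=target_seqs)
    return target, chains, log


def _substitute(byte: int, rng: np.random.Generator) -> int:
    old = chr(byte)
    choices = [b for b in "ACGT" if b != old]
    return ord(str(rng.choice(choices)))


# ---------------------------------------------------------------------------
# Marker planting
# ---------------------------------------------------------------------------

def plant_markers(
    source: GenomeAssembly,
    target: GenomeAssembly,
    truth_chain: Sequence[Chain],
    edits_log: EditsLog,
    config: SimConfig,
) -> Tuple[List[Marker], List[TruthRecord]]:
    """Place markers whose fate is forced by the edit structure."""
    rng = _rng(config.seed, "markers")
    flank = config.flank
    q = config.fate_quotas
    placements: List[Tuple[str, int, LiftStatus]] = []

    # forbidden zones for LIFTED markers: any edit footprint widened by a
    # full flank, plus each background substitution's flank reach
    forbidden: Dict[str, List[Tuple[int, int]]] = {c: [] for c in source.sequences}
    pad = flank + 2

    def forbid(chrom: str, s: int, e: int) -> None:
        forbidden[chrom].append((s - pad, e + pad))

    for c, s, e in edits_log.dup_segments:
        forbid(c, s, e)
    for host, ip, *_ in edits_log.dup_insertions:
        forbid(host, ip, ip + 1)
    for c, s, e in edits_log.deletions:
        forbid(c, s, e)
    for c, p, _ in edits_log.divergent_sites:
        forbid(c, p - 2 * flank, p + 2 * flank + 1)  # keep anchors exclusive
    for c, s, e in edits_log.diverged_windows:
        forbid(c, s - 2 * flank, e + 2 * flank)
    sub_positions = {
        c: np.array(
            sorted(
                set(edits_log.background_subs.get(c, []))
                | set(edits_log.window_subs.get(c, []))
            ),
            dtype=np.int64,
        )
        for c in source.sequences
    }

    def clear_of_subs(chrom: str, pos: int) -> bool:
        subs = sub_positions[chrom]
        if subs.size == 0:
            return True
        i = np.searchsorted(subs, pos - flank)
        return not (i < subs.size and subs[i] <= pos + flank)

    def in_forbidden(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in forbidden[chrom])

    taken: set = set()

    def add(chrom: str, pos: int, fate: LiftStatus) -> None:
        key = (chrom, pos)
        if key in taken:
            raise RuntimeError("duplicate marker position planted")
        taken.add(key)
        placements.append((chrom, pos, fate))

    def plant_anchor(chrom: str, pos: int) -> None:
        # anchors are ordinary LIFTED markers at deterministic offsets
        if (chrom, pos) not in taken:
            add(chrom, pos, LiftStatus.LIFTED)

    # MULTI_MAPPED: inside duplicated segments, full flank inside
    remaining = q.get("MULTI_MAPPED", 0)
    for chrom, s, e in edits_log.dup_segments:
        n = min(remaining, config.markers_per_segment)
        for pos in _spread(s + flank + 2, e - flank - 2, n):
            add(chrom, pos, LiftStatus.MULTI_MAPPED)
        remaining -= n
    # UNMAPPED: inside deleted segments
    remaining = q.get("UNMAPPED", 0)
    for chrom, s, e in edits_log.deletions:
        n = min(remaining, config.markers_per_segment)
        for pos in _spread(s + flank + 2, e - flank - 2, n):
            add(chrom, pos, LiftStatus.UNMAPPED)
        remaining -= n
    # ALLELE_DIVERGENT: at the mutated sites, with two anchors
    for chrom, p, _new in edits_log.divergent_sites:
        add(chrom, p, LiftStatus.ALLELE_DIVERGENT)
        plant_anchor(chrom, p - flank - 1)
        plant_anchor(chrom, p + flank + 1)
    # LOW_IDENTITY: inside diverged windows (no sub at the site itself,
    # at least one sub within the flank), with two anchors per window
    remaining = q.get("LOW_IDENTITY", 0)
    for chrom, s, e in edits_log.diverged_windows:
        n = min(remaining, config.markers_per_segment)
        subs = np.array(sorted(p for p in edits_log.window_subs.get(chrom, []) if s <= p < e))
        placed = 0
        attempts = 0
        while placed < n and attempts < 2000:
            attempts += 1
            pos = int(rng.integers(s + flank + 2, e - flank - 2))
            if (chrom, pos) in taken or pos in subs:
                continue
            near = subs[(subs >= pos - flank) & (subs <= pos + flank)]
            if near.size == 0:
                continue
            add(chrom, pos, LiftStatus.LOW_IDENTITY)
            placed += 1
        if placed < n:
            raise RuntimeError("could not place low-identity markers; raise diverged_sub_rate")
        remaining -= n
        plant_anchor(chrom, s - flank - 11)
        plant_anchor(chrom, e + flank + 10)

    # LIFTED: scatter over all sequences proportionally to length
    n_lifted_planted = sum(1 for _, _, f in placements if f is LiftStatus.LIFTED)
    n_scatter = config.lifted_quota - n_lifted_planted
    seq_names = list(source.sequences)
    lengths = np.array([source.lengths[c] for c in seq_names], dtype=float)
    weights = lengths / lengths.sum()
    attempts = 0
    placed = 0
    while placed < n_scatter and attempts < 100 * n_scatter + 1000:
        attempts += 1
        chrom = seq_names[int(rng.choice(len(seq_names), p=weights))]
        clen = source.lengths[chrom]
        if clen < 2 * flank + 2:
            continue
        pos = int(rng.integers(flank, clen - flank - 1))
        if (chrom, pos) in taken or in_forbidden(chrom, pos) or not clear_of_subs(chrom, pos):
            continue
        add(chrom, pos, LiftStatus.LIFTED)
        placed += 1
    if placed < n_scatter:
        raise RuntimeError("could not scatter the requested number of lifted markers")

    # assemble markers sorted by coordinate, assign ids, derive truth
    placements.sort(key=lambda t: (t[0], t[1]))
    markers: List[Marker] = []
    truths: List[TruthRecord] = []
    divergent_new = {(c, p): new for c, p, new in edits_log.divergent_sites}
    for i, (chrom, pos, fate) in enumerate(placements, start=1):
        ref = source.base(chrom, pos)
        banned = {ref}
        if (chrom, pos) in divergent_new:
            banned.add(divergent_new[(chrom, pos)])
        alt = str(rng.choice([b for b in "ACGT" if b not in banned]))
        mid = f"m{i:05d}"
        markers.append(Marker(id=mid, chrom=chrom, pos0=pos, ref_allele=ref, alt_allele=alt))
        if fate is LiftStatus.LIFTED:
            hit = lift_by_chain(chrom, pos, truth_chain)
            if hit is None:
                raise RuntimeError("planted LIFTED marker not covered by truth chain")
            tname, tpos, strand = hit
            truths.append(TruthRecord(mid, fate, tname, tpos, strand))
        else:
            truths.append(TruthRecord(mid, fate))
    return markers, truths


def _spread(lo: int, hi: int, n: int) -> List[int]:
    """n distinct roughly-even integer positions in [lo, hi]."""
    if n <= 0:
        return []
    if hi < lo:
        raise ValueError("empty placement range")
    return sorted({int(round(lo + (hi - lo) * i / max(n - 1, 1))) for i in range(n)})


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

DEFAULT_MAF_SPECTRUM: List[Tuple[str, float]] = [
    ("Monomorphic", 0.18),
    ("<0.01", 0.20),
    ("0.01~0.05", 0.14),
    ("0.05~0.10", 0.10),
    ("0.10~0.20", 0.15),
    ("0.20~0.30", 0.09),
    ("0.30~0.40", 0.08),
    ("0.40>", 0.06),
]

_BIN_BOUNDS = {
    "Monomorphic": (0.0, 0.0),
    "<0.01": (0.001, 0.01),
    "0.01~0.05": (0.01, 0.05),
    "0.05~0.10": (0.05, 0.10),
    "0.10~0.20": (0.10, 0.20),
    "0.20~0.30": (0.20, 0.30),
    "0.30~0.40": (0.30, 0.40),
    "0.40>": (0.40, 0.50),
}


def simulate_genotypes(
    marker_ids: Sequence[str],
    n_accessions: int,
    maf_spectrum: Optional[Sequence[Tuple[str, float]]] = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    accession_prefix: str = "acc",
) -> GenotypeMatrix:
    """Draw a diploid genotype matrix with a specified MAF spectrum.

    Each marker draws a true alternate-allele frequency from its assigned
    spectrum bin (Monomorphic -> 0) and genotypes are binomial(2, p) per
    accession; everything is deterministic under ``seed``.
    """
    spectrum = list(maf_spectrum or DEFAULT_MAF_SPECTRUM)
    weights = np.array([w for _, w in spectrum], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("maf spectrum weights must sum to 1")
    rng = np.random.default_rng([seed, _STREAMS["genotypes"]])
    labels = [lab for lab, _ in spectrum]
    assignment = rng.choice(len(labels), size=len(marker_ids), p=weights)
    calls = np.zeros((len(marker_ids), n_accessions), dtype=np.int8)
    for i, bin_idx in enumerate(assignment):
        lo, hi = _BIN_BOUNDS[labels[bin_idx]]
        p = 0.0 if hi == 0.0 else float(rng.uniform(lo, hi))
        calls[i] = rng.binomial(2, p, size=n_accessions).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    accession_ids = [f"{accession_prefix}{j + 1:04d}" for j in range(n_accessions)]
    return GenotypeMatrix(list(marker_ids), accession_ids, calls)


# ---------------------------------------------------------------------------
# One-call fixture
# ---------------------------------------------------------------------------

@dataclass
class SimFixture:
    config: SimConfig
    source: GenomeAssembly
    target: GenomeAssembly
    genes: List[Interval]
    tes: List[Interval]
    markers: List[Marker]
    truth: List[TruthRecord]
    truth_chain: List[Chain]
    edits_log: EditsLog


def simulate_pair(config: SimConfig) -> SimFixture:
    """Run the full simulation and return all artifacts in memory."""
    source, genes, tes = generate_source(config)
    target, truth_chain, edits_log = derive_target(source, config)
    markers, truth = plant_markers(source, target, truth_chain, edits_log, config)
    return SimFixture(
        config=config,
        source=source,
        target=target,
        genes=genes,
        tes=tes,
        markers=markers,
        truth=truth,
        truth_chain=truth_chain,
        edits_log=edits_log,
    )


def write_fixture(
    config: SimConfig,
    outdir: str | Path,
    n_accessions_a: int = 60,
    n_accessions_b: int = 80,
) -> SimFixture:
    """Write the full fixture set (FASTA, marker table, annotations, truth,
    chain, genotype matrices, config) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = simulate_pair(config)
    fx.source.to_fasta(outdir / "source.fa")
    fx.target.to_fasta(outdir / "target.fa")
    write_markers_tsv(fx.markers, outdir / "markers.tsv")
    write_intervals_gff3(fx.genes, outdir / "genes.gff3")
    write_intervals_bed(fx.tes, outdir / "tes.bed")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("marker_id\texpected_status\texpected_tname\texpected_tpos\texpected_strand\n")
        for t in fx.truth:
            fh.write(
                f"{t.marker_id}\t{t.expected_status.name}\t{t.expected_tname or ''}\t"
                f"{'' if t.expected_tpos0 is None else t.expected_tpos0 + 1}\t"
                f"{t.expected_strand or ''}\n"
            )
    write_chain_file(
        fx.truth_chain, fx.source.lengths, fx.target.lengths, outdir / "truth.chain"
    )
    ids = [m.id for m in fx.markers]
    simulate_genotypes(ids, n_accessions_a, seed=config.seed).to_tsv(
        outdir / "genotypes_a.tsv"
    )
    simulate_genotypes(ids, n_accessions_b, seed=config.seed + 1).to_tsv(
        outdir / "genotypes_b.tsv"
    )
    cfg = asdict(config)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
        fh.write("\n")
    return fx


def read_truth_tsv(path: str | Path) -> List[TruthRecord]:
    import csv

    out: List[TruthRecord] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRecord(
                    marker_id=row["marker_id"],
                    expected_status=LiftStatus[row["expected_status"]],
                    expected_tname=row["expected_tname"] or None,
                    expected_tpos0=(
                        int(row["expected_tpos"]) - 1 if row["expected_tpos"] else None
                    ),
                    expected_strand=row["expected_strand"] or None,
                )
            )
    return out
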