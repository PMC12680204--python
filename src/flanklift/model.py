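"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate convention: every coordinate stored on these objects is 0-based
half-open.  Conversion to/from 1-based conventions (VCF, GFF3, the marker
table's ``pos`` column) happens only inside the loaders/writers in this
module.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .dna import VALID_BASES, sanitize


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


class InternalConsistencyError(RuntimeError):
    """Raised when an emitted record contradicts the genome it was written
    against; this indicates a pipeline bug, not bad input."""


# ---------------------------------------------------------------------------
# GenomeAssembly
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """An in-memory genome assembly.

    Parameters
    ----------
    name:
        Assembly label (e.g. ``"v1"``).
    sequences:
        Mapping from sequence name to upper-case DNA string over {A,C,G,T,N}.
    is_scaffold:
        Per-sequence flag distinguishing unplaced scaffolds from chromosomes.
    """

    name: str
    sequences: Dict[str, str]
    is_scaffold: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sname in self.sequences:
            self.is_scaffold.setdefault(sname, _looks_like_scaffold(sname))

    @property
    def lengths(self) -> Dict[str, int]:
        return {s: len(seq) for s, seq in self.sequences.items()}

    def __contains__(self, sname: str) -> bool:
        return sname in self.sequences

    def base(self, chrom: str, pos0: int) -> str:
        """Single base at a 0-based coordinate."""
        seq = self._seq(chrom)
        if not 0 <= pos0 < len(seq):
            raise IndexError(f"position {pos0} outside {chrom} (len {len(seq)})")
        return seq[pos0]

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Sub-sequence over [start0, end0); bounds must be valid."""
        seq = self._seq(chrom)
        if not 0 <= start0 <= end0 <= len(seq):
            raise IndexError(
                f"range [{start0}, {end0}) outside {chrom} (len {len(seq)})"
            )
        return seq[start0:end0]

    def _seq(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise KeyError(f"sequence {chrom!r} absent from assembly {self.name!r}")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        name: Optional[str] = None,
        scaffold_names: Optional[Iterable[str]] = None,
    ) -> "GenomeAssembly":
        return load_genome(path, name=name, scaffold_names=scaffold_names)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for sname, seq in self.sequences.items():
                fh.write(f">{sname}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _looks_like_scaffold(name: str) -> bool:
    return name.lower().startswith("scaffold")


def load_genome(
    path: str | Path,
    name: Optional[str] = None,
    scaffold_names: Optional[Iterable[str]] = None,
) -> GenomeAssembly:
    """Load a FASTA file into a :class:`GenomeAssembly`.

    Sequences are upper-cased and non-ACGTN letters are collapsed to ``N``.
    Scaffold status defaults to a case-insensitive ``scaffold`` name-prefix
    match unless an explicit ``scaffold_names`` list is supplied.
    """
    path = Path(path)
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = sanitize(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no records")
    if scaffold_names is not None:
        scaffold_set = set(scaffold_names)
        flags = {s: s in scaffold_set for s in sequences}
    else:
        flags = {s: _looks_like_scaffold(s) for s in sequences}
    return GenomeAssembly(name=name or path.stem, sequences=sequences, is_scaffold=flags)


# ---------------------------------------------------------------------------
# Marker
# ---------------------------------------------------------------------------

REGION_LABELS = {"genic", "upstream", "downstream", "intergenic", "unknown"}


@dataclass(frozen=True)
class Marker:
    """An array SNP with its source-assembly coordinate and allele pair."""

    id: str
    chrom: str
    pos0: int
    ref_allele: str
    alt_allele: str
    source_region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise FormatError(
                f"marker {self.id}: alleles must be A/C/G/T, "
                f"got {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"marker {self.id}: ref and alt alleles are identical")
        if self.pos0 < 0:
            raise FormatError(f"marker {self.id}: negative coordinate")
        if self.source_region is not None and self.source_region not in REGION_LABELS:
            raise FormatError(
                f"marker {self.id}: unknown region label {self.source_region!r}"
            )


def load_markers(
    path: str | Path, genome: Optional[GenomeAssembly] = None
) -> List[Marker]:
    """Load markers from a TSV table or a VCF file.

    The TSV must have a header with columns ``id chrom pos ref alt`` and an
    optional ``region`` column; ``pos`` is 1-based in the file and converted
    to 0-based here.  VCF mode reads CHROM/POS/ID/REF/ALT.
    """
    path = Path(path)
    if path.suffix in {".vcf"} or str(path).endswith(".vcf.gz"):
        markers = _markers_from_vcf(path)
    else:
        markers = _markers_from_tsv(path)
    seen = set()
    for m in markers:
        if m.id in seen:
            raise FormatError(f"{path}: duplicate marker id {m.id!r}")
        seen.add(m.id)
        if genome is not None:
            if m.chrom not in genome:
                raise FormatError(f"{path}: marker {m.id} on unknown sequence {m.chrom}")
            if m.pos0 >= genome.lengths[m.chrom]:
                raise FormatError(
                    f"{path}: marker {m.id} position beyond end of {m.chrom}"
                )
    return markers


def _markers_from_tsv(path: Path) -> List[Marker]:
    markers = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "chrom", "pos", "ref", "alt"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: marker table must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            pos = int(row["pos"])
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: pos must be >= 1")
            markers.append(
                Marker(
                    id=row["id"],
                    chrom=row["chrom"],
                    pos0=pos - 1,
                    ref_allele=row["ref"].upper(),
                    alt_allele=row["alt"].upper(),
                    source_region=(row.get("region") or None),
                )
            )
    return markers


def _markers_from_vcf(path: Path) -> List[Marker]:
    import pysam

    markers = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.id is None:
                raise FormatError(f"{path}: VCF record at {rec.chrom}:{rec.pos} lacks an ID")
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"{path}: marker {rec.id} is not biallelic")
            markers.append(
                Marker(
                    id=rec.id,
                    chrom=rec.chrom,
                    pos0=rec.pos - 1,
                    ref_allele=rec.ref.upper(),
                    alt_allele=rec.alts[0].upper(),
                )
            )
    return markers


def write_markers_tsv(markers: Sequence[Marker], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "chrom", "pos", "ref", "alt", "region"])
        for m in markers:
            w.writerow(
                [m.id, m.chrom, m.pos0 + 1, m.ref_allele, m.alt_allele, m.source_region or ""]
            )


# ---------------------------------------------------------------------------
# Interval
# ---------------------------------------------------------------------------

INTERVAL_KINDS = {"gene", "te_class_I", "te_class_II", "low_identity", "other"}


@dataclass(frozen=True)
class Interval:
    """A genomic feature interval, 0-based half-open."""

    chrom: str
    start0: int
    end0: int
    name: str = "."
    strand: str = "."
    kind: str = "other"

    def __post_init__(self) -> None:
        if not 0 <= self.start0 < self.end0:
            raise FormatError(
                f"interval {self.name}: invalid range [{self.start0}, {self.end0})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"interval {self.name}: bad strand {self.strand!r}")
        if self.kind not in INTERVAL_KINDS:
            raise FormatError(f"interval {self.name}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end0 - self.start0

    def contains(self, pos0: int) -> bool:
        return self.start0 <= pos0 < self.end0


def _te_kind(name: str) -> str:
    # TE BED names encode the class as an "I"/"II" prefix (e.g. "II_hAT_3").
    head = name.split("_", 1)[0].split("/", 1)[0]
    if head == "II":
        return "te_class_II"
    if head == "I":
        return "te_class_I"
    return "other"


def load_intervals(
    path: str | Path, kind_filter: Optional[str] = None
) -> List[Interval]:
    """Load intervals from BED (0-based half-open) or GFF3 (1-based inclusive).

    ``kind_filter`` keeps only intervals whose derived kind (or, for GFF3,
    whose raw feature type) equals the given value — e.g. ``"gene"`` selects
    gene features and discards mRNA/exon lines.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        intervals = _intervals_from_gff3(path, kind_filter)
    else:
        intervals = _intervals_from_bed(path)
        if kind_filter is not None:
            intervals = [iv for iv in intervals if iv.kind == kind_filter]
    return intervals


def _intervals_from_bed(path: Path) -> List[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs at least 3 columns")
            name = f[3] if len(f) > 3 and f[3] else "."
            strand = f[5] if len(f) > 5 and f[5] in {"+", "-"} else "."
            start0, end0 = int(f[1]), int(f[2])
            if start0 >= end0:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            intervals.append(
                Interval(f[0], start0, end0, name=name, strand=strand, kind=_te_kind(name))
            )
    return intervals


def _intervals_from_gff3(path: Path, kind_filter: Optional[str]) -> List[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            ftype = f[2]
            if kind_filter is not None and ftype != kind_filter:
                continue
            start0, end0 = int(f[3]) - 1, int(f[4])  # 1-based inclusive -> half-open
            if start0 >= end0:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or "."
            strand = f[6] if f[6] in {"+", "-"} else "."
            kind = "gene" if ftype == "gene" else "other"
            intervals.append(
                Interval(f[0], start0, end0, name=name, strand=strand, kind=kind)
            )
    return intervals


def write_intervals_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start0}\t{iv.end0}\t{iv.name}\t.\t{iv.strand}\n"
            )


def write_intervals_gff3(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            ftype = "gene" if iv.kind == "gene" else "region"
            fh.write(
                f"{iv.chrom}\tflanklift\t{ftype}\t{iv.start0 + 1}\t{iv.end0}\t.\t"
                f"{iv.strand}\t.\tID={iv.name}\n"
            )


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for markers x accessions.

    ``calls`` holds codes 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing) in
    an int8 matrix of shape (n_markers, n_accessions).
    """

    marker_ids: List[str]
    accession_ids: List[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.accession_ids)):
            raise FormatError(
                f"genotype matrix shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.accession_ids)} accessions"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype codes must be one of {0, 1, 2, -1}")
        self._row_index = {m: i for i, m in enumerate(self.marker_ids)}

    def row(self, marker_id: str) -> np.ndarray:
        return self.calls[self._row_index[marker_id]]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._row_index

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a marker x accession matrix; first column = marker id,
        header row = accession ids, cells 0/1/2/NA."""
        marker_ids: List[str] = []
        rows: List[List[int]] = []
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if not header or len(header) < 2:
                raise FormatError(f"{path}: genotype TSV needs a header row")
            accession_ids = header[1:]
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(header):
                    raise FormatError(f"{path}:{lineno}: ragged row")
                marker_ids.append(row[0])
                rows.append(
                    [MISSING if v in {"NA", ".", ""} else int(v) for v in row[1:]]
                )
        return cls(marker_ids, accession_ids, np.array(rows, dtype=np.int8))

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        import pysam

        marker_ids: List[str] = []
        rows: List[List[int]] = []
        with pysam.VariantFile(str(path)) as vf:
            accession_ids = list(vf.header.samples)
            for rec in vf:
                marker_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
                row = []
                for sample in accession_ids:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or any(a is None for a in gt):
                        row.append(MISSING)
                    else:
                        row.append(int(sum(gt)))
                rows.append(row)
        return cls(marker_ids, accession_ids, np.array(rows, dtype=np.int8))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["marker_id"] + self.accession_ids)
            for i, mid in enumerate(self.marker_ids):
                w.writerow(
                    [mid] + ["NA" if v == MISSING else str(v) for v in self.calls[i]]
                )


# ---------------------------------------------------------------------------
# Lifted VCF writer
# ---------------------------------------------------------------------------

def write_lifted_vcf(
    results: Sequence,  # Sequence[LiftResult]; typed loosely to avoid a cycle
    markers: Sequence[Marker],
    target: GenomeAssembly,
    out_path: str | Path,
    rejects_path: Optional[str | Path] = None,
) -> int:
    """Write one VCF record per LIFTED marker, sorted by (chrom, pos).

    The emitted REF is the base the target genome actually carries at the
    lifted position (strand-normalized); the ALT is the other member of the
    marker's allele pair.  A REF outside the allele pair raises
    :class:`InternalConsistencyError` — validation must have run first.
    Failed markers go to ``rejects_path`` with their failure reason.
    """
    import pysam

    from .lift import LiftStatus  # local import to avoid circular dependency

    by_id = {m.id: m for m in markers}
    header = pysam.VariantHeader()
    header.add_line("##source=flanklift")
    for sname, length in target.lengths.items():
        header.contigs.add(sname, length=length)
    header.add_line(
        '##INFO=<ID=SRC,Number=1,Type=String,Description="Source coordinate (chrom:pos, 1-based)">'
    )
    header.add_line('##INFO=<ID=STRAND,Number=1,Type=String,Description="Lifted strand">')
    header.add_line('##INFO=<ID=PROV,Number=1,Type=String,Description="Lift provenance">')

    lifted = [r for r in results if r.status is LiftStatus.LIFTED]
    failed = [r for r in results if r.status is not LiftStatus.LIFTED]
    order = {s: i for i, s in enumerate(target.sequences)}
    lifted.sort(key=lambda r: (order.get(r.tname, len(order)), r.tpos0))

    n = 0
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for r in lifted:
            marker = by_id[r.marker_id]
            pair = (r.lifted_ref, r.lifted_alt)
            observed = target.base(r.tname, r.tpos0)
            if observed not in pair:
                raise InternalConsistencyError(
                    f"marker {marker.id}: target base {observed} at "
                    f"{r.tname}:{r.tpos0 + 1} is outside lifted allele pair {pair}"
                )
            alt = pair[1] if observed == pair[0] else pair[0]
            rec = out.new_record(
                contig=r.tname, start=r.tpos0, alleles=(observed, alt), id=marker.id
            )
            rec.info["SRC"] = f"{marker.chrom}:{marker.pos0 + 1}"
            rec.info["STRAND"] = r.strand
            if r.provenance:
                rec.info["PROV"] = r.provenance
            out.write(rec)
            n += 1

    if rejects_path is not None:
        with open(rejects_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["marker_id", "reason"])
            for r in failed:
                w.writerow([r.marker_id, r.status.name])
    return n


def read_lifted_vcf(path: str | Path) -> List[Marker]:
    """Re-load a lifted VCF as markers (used by round-trip checks)."""
    return _markers_from_vcf(Path(path))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
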