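"""Core data model and I/O for collapsed small-RNA alignment libraries.

The whole toolkit operates on one in-memory representation: a
:class:`Library` of :class:`AlignmentRecord` objects, each of which places a
collapsed read (:class:`SmallRNARead`) on a reference sequence.  Alignments
may come from SAM/BAM (e.g. Bowtie output) or from the 6-column BED-like
dialect used by the simulator, in which the *name* field carries the read
sequence and the *score* field its copy count.

Conventions
-----------
* Coordinates are 0-based, half-open everywhere in memory and in BED output;
  SAM input is converted on load.
* Sequences are stored in the DNA alphabet (U is converted to T on input);
  they may be rendered back with U for display.
* The 5' end of a plus-strand record is ``start``; of a minus-strand record
  ``end - 1``.
* ``n_hits`` (placement multiplicity) is always recomputed over the loaded
  record set and never trusted from file tags, because a read unique on the
  genome may be a multi-mapper on a transposon-consensus set and vice versa.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pyfaidx
import pysam

__all__ = [
    "SmallRNARead",
    "AlignmentRecord",
    "Library",
    "collapse_reads",
    "read_alignments",
    "write_bed",
    "filter_by_length",
    "MIN_READ_LEN",
    "MAX_READ_LEN",
]

MIN_READ_LEN = 15
MAX_READ_LEN = 45

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")


class FormatError(ValueError):
    """A malformed or out-of-bounds record in an input file."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a stored DNA-alphabet sequence with U instead of T."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRNARead:
    """A distinct small-RNA sequence with its collapsed copy count."""

    sequence: str
    copy_count: int = 1

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValueError(f"copy_count must be >= 1, got {self.copy_count}")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in read sequence")
        if not MIN_READ_LEN <= len(self.sequence) <= MAX_READ_LEN:
            raise ValueError(
                f"read length {len(self.sequence)} outside "
                f"[{MIN_READ_LEN}, {MAX_READ_LEN}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of a collapsed read on a reference sequence.

    ``n_hits`` counts the placements of this read over the reference set
    under analysis; ``mismatches`` is carried as metadata only.
    """

    read: SmallRNARead
    ref_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive; end - start == len(read)
    strand: str  # "+" or "-"
    n_hits: int = 1
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.read):
            raise ValueError(
                f"span {self.end - self.start} != read length {len(self.read)}"
            )
        if self.start < 0:
            raise ValueError("negative start coordinate")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1

    def sort_key(self) -> tuple:
        return (self.ref_id, self.start, self.end, self.strand, self.read.sequence)


@dataclass
class Library:
    """A collapsed small-RNA library aligned against one reference set.

    ``total_mapped`` is the copy-weighted number of mapped reads and is the
    RPM denominator downstream.  When a library is derived by filtering, the
    parent's ``total_mapped`` is retained so that RPM values stay on the
    denominator of the full genome alignment.
    """

    name: str
    records: list[AlignmentRecord] = field(default_factory=list)
    condition: str | None = None
    total_mapped: int | None = None
    ref_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=AlignmentRecord.sort_key)
        self._recompute_hits()
        if self.total_mapped is None:
            self.total_mapped = sum(r.copy_count for r in self.distinct_reads())

    def _recompute_hits(self) -> None:
        hits = collections.Counter(r.read.sequence for r in self.records)
        self.records = [
            replace(r, n_hits=hits[r.read.sequence]) for r in self.records
        ]

    def distinct_reads(self) -> list[SmallRNARead]:
        """Distinct collapsed reads with at least one placement."""
        seen: dict[str, SmallRNARead] = {}
        for r in self.records:
            seen.setdefault(r.read.sequence, r.read)
        return [seen[s] for s in sorted(seen)]

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Check coordinate bounds against ``ref_lengths`` and invariants."""
        for r in self.records:
            if self.ref_lengths is not None:
                if r.ref_id not in self.ref_lengths:
                    raise FormatError(f"unknown reference {r.ref_id!r}")
                if r.end > self.ref_lengths[r.ref_id]:
                    raise FormatError(
                        f"record {r.ref_id}:{r.start}-{r.end} exceeds reference "
                        f"length {self.ref_lengths[r.ref_id]}"
                    )
        counts: dict[str, int] = {}
        for r in self.records:
            prev = counts.setdefault(r.read.sequence, r.read.copy_count)
            if prev != r.read.copy_count:
                raise FormatError(
                    f"inconsistent copy_count for sequence {r.read.sequence}"
                )


def collapse_reads(raw_sequences: Iterable[str]) -> list[SmallRNARead]:
    """Collapse raw read sequences into distinct reads with copy counts.

    Output is sorted lexicographically by sequence; the sum of copy counts
    equals the number of input reads.  Raises ``ValueError`` naming the
    offending read index on a non-ACGTU character.
    """
    counts: collections.Counter[str] = collections.Counter()
    for i, seq in enumerate(raw_sequences):
        norm = normalize_sequence(seq)
        if set(norm) - _VALID:
            raise ValueError(f"read {i}: invalid characters in {seq!r}")
        counts[norm] += 1
    return [SmallRNARead(s, counts[s]) for s in sorted(counts)]


def _load_ref_lengths(fasta_path: str | Path) -> dict[str, int]:
    fa = pyfaidx.Fasta(str(fasta_path))
    return {name: len(fa[name]) for name in fa.keys()}


def _count_mismatches(seq: str, ref_seq: str, strand: str) -> int:
    aligned = seq if strand == "+" else revcomp(seq)
    return sum(1 for a, b in zip(aligned, ref_seq.upper()) if a != b)


def read_alignments(
    path: str | Path,
    fasta_path: str | Path,
    format: str | None = None,
    name: str | None = None,
    condition: str | None = None,
) -> Library:
    """Load alignments from SAM/BAM or the BED dialect into a :class:`Library`.

    Parameters
    ----------
    path
        Alignment file.  ``format`` is inferred from the suffix when omitted
        (``.sam``/``.bam``/``.bed``).
    fasta_path
        Reference FASTA; used for coordinate validation and, for BED input,
        to recompute per-record mismatch counts.

    Notes
    -----
    In SAM input the collapsed copy count is taken from a ``_xN`` suffix on
    the query name (the common collapser convention); absent that, 1.  The
    stored read sequence is the sequenced strand, i.e. the reverse
    complement of the SAM SEQ field for minus-strand records.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("sam", "bam", "bed"):
        raise ValueError(f"unsupported format {format!r}")
    ref_lengths = _load_ref_lengths(fasta_path)
    if format == "bed":
        records = _read_bed(path, fasta_path, ref_lengths)
    else:
        records = _read_sam(path, format, ref_lengths)
    lib = Library(
        name=name or path.stem,
        records=records,
        condition=condition,
        ref_lengths=ref_lengths,
    )
    lib.validate()
    return lib


def _read_sam(path: Path, fmt: str, ref_lengths: dict[str, int]) -> list[AlignmentRecord]:
    mode = "rb" if fmt == "bam" else "r"
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for i, aln in enumerate(fh):
            if aln.is_unmapped:
                continue
            try:
                seq = aln.query_sequence
                if seq is None:
                    raise FormatError("missing SEQ field")
                strand = "-" if aln.is_reverse else "+"
                if strand == "-":
                    seq = revcomp(seq)
                copy = _copy_from_name(aln.query_name)
                nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
                rec = AlignmentRecord(
                    read=SmallRNARead(normalize_sequence(seq), copy),
                    ref_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand=strand,
                    mismatches=int(nm),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}, record {i + 1}: {exc}") from exc
            if rec.end > ref_lengths.get(rec.ref_id, -1):
                raise FormatError(
                    f"{path}, record {i + 1}: coordinates out of bounds"
                )
            records.append(rec)
    return records


def _copy_from_name(qname: str) -> int:
    if "_x" in qname:
        tail = qname.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1


def _read_bed(
    path: Path, fasta_path: str | Path, ref_lengths: dict[str, int]
) -> list[AlignmentRecord]:
    fa = pyfaidx.Fasta(str(fasta_path))
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}, line {lineno}: expected 6 columns")
            ref_id, start_s, end_s, seq, copy_s, strand = fields[:6]
            try:
                start, end, copy = int(start_s), int(end_s), int(copy_s)
                read = SmallRNARead(normalize_sequence(seq), copy)
                if ref_id not in ref_lengths:
                    raise FormatError(f"unknown reference {ref_id!r}")
                if not (0 <= start < end <= ref_lengths[ref_id]):
                    raise FormatError("coordinates out of bounds")
                ref_seq = str(fa[ref_id][start:end])
                rec = AlignmentRecord(
                    read=read,
                    ref_id=ref_id,
                    start=start,
                    end=end,
                    strand=strand,
                    mismatches=_count_mismatches(read.sequence, ref_seq, strand),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_bed(lib: Library, path: str | Path) -> None:
    """Write a library in the 6-column BED dialect (sorted, deterministic)."""
    with open(path, "w") as fh:
        for r in sorted(lib.records, key=AlignmentRecord.sort_key):
            fh.write(
                f"{r.ref_id}\t{r.start}\t{r.end}\t{r.read.sequence}\t"
                f"{r.read.copy_count}\t{r.strand}\n"
            )


def filter_by_length(lib: Library, lo: int, hi: int) -> Library:
    """Keep records whose read length is within ``[lo, hi]`` inclusive.

    The parent library's ``total_mapped`` is retained, so RPM values computed
    on the filtered library keep the full-library denominator.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) > hi ({hi})")
    kept = [r for r in lib.records if lo <= len(r.read) <= hi]
    return Library(
        name=lib.name,
        records=kept,
        condition=lib.condition,
        total_mapped=lib.total_mapped,
        ref_lengths=lib.ref_lengths,
    )


def unique_records(lib: Library) -> list[AlignmentRecord]:
    """Records of uniquely-mapping reads (``n_hits == 1``) on this set."""
    return [r for r in lib.records if r.n_hits == 1]
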