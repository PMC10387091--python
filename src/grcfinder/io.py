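"""Readers and writers for the plain-text formats the pipeline touches.

All coordinates are 0-based half-open internally.  BED and PAF share that
convention so they pass through unchanged; any 1-based external dialect is
converted at the boundary.

Parsers are deliberately strict: a malformed record raises
:class:`FormatError` naming the offending line, and duplicate FASTA
identifiers are rejected, because downstream stages key everything on
scaffold identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

__all__ = [
    "FormatError",
    "GenomicInterval",
    "ReadRecord",
    "AlignmentRecord",
    "HitRecord",
    "CoverageTrack",
    "read_fasta",
    "write_fasta",
    "read_fastq_barcoded",
    "write_fastq_barcoded",
    "read_paf",
    "write_paf",
    "read_bed",
    "write_bed",
    "read_hit_table",
    "write_hit_table",
]

PathOrFile = Union[str, Path, TextIO]


class FormatError(ValueError):
    """A file violated the dialect this package reads/writes."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different scaffolds)."""
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class ReadRecord:
    """One sequencing read with optional linked-read (molecule) barcode."""

    read_id: str
    sequence: str
    qualities: Optional[str] = None
    barcode: Optional[str] = None
    tissue: Optional[str] = None
    sample: Optional[str] = None
    mate: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class AlignmentRecord:
    """Placement of a query (read or scaffold segment) on a target."""

    query_id: str
    query_start: int
    query_end: int
    target: GenomicInterval
    matches: int
    block_len: int
    mapq: int = 60
    unique: bool = True

    def __post_init__(self) -> None:
        if self.block_len < 1:
            raise ValueError(f"{self.query_id}: block_len must be >= 1")
        if self.matches > self.block_len:
            raise ValueError(f"{self.query_id}: matches > block_len")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len

    @property
    def mismatches(self) -> int:
        return self.block_len - self.matches


@dataclass
class HitRecord:
    """One translated-search hit of a query region against a gene CDS."""

    query_id: str
    gene_id: str
    pident: float
    length: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    evalue: float
    bitscore: float
    strand: str
    frame: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class CoverageTrack:
    """Per-base sequencing depth along one scaffold for one sample/tissue."""

    scaffold: str
    depth: "object"  # numpy integer array
    sample: str = ""
    tissue: str = ""

    def __len__(self) -> int:
        return len(self.depth)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _open(path: PathOrFile, mode: str = "r") -> tuple[TextIO, bool]:
    if isinstance(path, (str, Path)):
        return open(path, mode), True
    return path, False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathOrFile) -> dict[str, str]:
    """Read a FASTA file into ``{identifier: sequence}``.

    The identifier is the header token before the first whitespace; case is
    preserved.  Duplicate identifiers, headerless sequence and empty records
    raise :class:`FormatError` naming the line.
    """
    handle, close = _open(path)
    try:
        records: dict[str, str] = {}
        name: Optional[str] = None
        name_line = 0
        chunks: list[str] = []

        def _flush(line_no: int) -> None:
            if name is None:
                return
            seq = "".join(chunks)
            if not seq:
                raise FormatError(f"line {name_line}: record {name!r} has empty sequence")
            records[name] = seq

        for i, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush(i)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {i}: empty FASTA header")
                name = header.split()[0]
                if name in records:
                    raise FormatError(f"line {i}: duplicate identifier {name!r}")
                name_line = i
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"line {i}: sequence before any FASTA header")
                chunks.append(line.strip())
        _flush(0)
        if not records and name is None:
            return {}
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: dict[str, str], path: PathOrFile, width: int = 80) -> None:
    handle, close = _open(path, "w")
    try:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# FASTQ with SAM-style barcode tag
# ---------------------------------------------------------------------------

def read_fastq_barcoded(
    path: PathOrFile, barcode_tag: str = "BX"
) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ, picking up a ``TAG:Z:value`` header token.

    The barcode is taken from the header comment (``@id BX:Z:AAA-1``);
    reads without the tag get ``barcode=None``.  Record order is preserved.
    """
    handle, close = _open(path)
    prefix = f"{barcode_tag}:Z:"
    try:
        line_no = 0
        while True:
            header = handle.readline()
            if not header:
                break
            line_no += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"line {line_no}: expected '@' header, got {header[:20]!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"line {line_no}: truncated FASTQ record")
            line_no += 3
            if not plus.startswith("+"):
                raise FormatError(f"line {line_no - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise FormatError(
                    f"line {line_no}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            tokens = header[1:].split()
            read_id = tokens[0]
            barcode = None
            for tok in tokens[1:]:
                if tok.startswith(prefix):
                    barcode = tok[len(prefix):]
                    break
            yield ReadRecord(read_id=read_id, sequence=seq, qualities=qual, barcode=barcode)
    finally:
        if close:
            handle.close()


def write_fastq_barcoded(
    reads: Iterable[ReadRecord], path: PathOrFile, barcode_tag: str = "BX"
) -> None:
    handle, close = _open(path, "w")
    try:
        for r in reads:
            comment = f" {barcode_tag}:Z:{r.barcode}" if r.barcode else ""
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            handle.write(f"@{r.read_id}{comment}\n{r.sequence}\n+\n{qual}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# PAF (12-column dialect)
# ---------------------------------------------------------------------------

def read_paf(path: PathOrFile) -> Iterator[AlignmentRecord]:
    """Stream 12+-column PAF lines as :class:`AlignmentRecord`.

    Columns 10/11 (1-based) are residue matches and block length; a ``tp:A``
    or ``un:i`` tag is not required — uniqueness defaults to True and can be
    carried in column 13+ as ``un:i:0/1``.
    """
    handle, close = _open(path)
    try:
        for i, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"line {i}: PAF needs >= 12 columns, got {len(cols)}")
            try:
                qstart, qend = int(cols[2]), int(cols[3])
                tstart, tend = int(cols[7]), int(cols[8])
                matches, block = int(cols[9]), int(cols[10])
                mapq = int(cols[11])
            except ValueError as exc:
                raise FormatError(f"line {i}: non-integer coordinate field: {exc}") from None
            strand = cols[4]
            if strand not in ("+", "-"):
                raise FormatError(f"line {i}: invalid strand {strand!r}")
            unique = True
            for tag in cols[12:]:
                if tag.startswith("un:i:"):
                    unique = tag[5:] == "1"
            yield AlignmentRecord(
                query_id=cols[0],
                query_start=qstart,
                query_end=qend,
                target=GenomicInterval(cols[5], tstart, tend, strand),
                matches=matches,
                block_len=block,
                mapq=mapq,
                unique=unique,
            )
    finally:
        if close:
            handle.close()


def write_paf(
    alignments: Iterable[AlignmentRecord],
    path: PathOrFile,
    query_lengths: Optional[dict[str, int]] = None,
    target_lengths: Optional[dict[str, int]] = None,
) -> None:
    handle, close = _open(path, "w")
    try:
        for a in alignments:
            qlen = (query_lengths or {}).get(a.query_id, a.query_end)
            tlen = (target_lengths or {}).get(a.target.scaffold, a.target.end)
            strand = a.target.strand if a.target.strand in "+-" else "+"
            handle.write(
                "\t".join(
                    map(
                        str,
                        [
                            a.query_id, qlen, a.query_start, a.query_end, strand,
                            a.target.scaffold, tlen, a.target.start, a.target.end,
                            a.matches, a.block_len, a.mapq,
                            f"un:i:{1 if a.unique else 0}",
                        ],
                    )
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathOrFile) -> list[GenomicInterval]:
    handle, close = _open(path)
    try:
        out = []
        for i, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {i}: BED needs >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError(f"line {i}: non-integer BED coordinate") from None
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
        return out
    finally:
        if close:
            handle.close()


def write_bed(intervals: Iterable[GenomicInterval], path: PathOrFile) -> None:
    """Write 6-column BED (name and score filled with '.')."""
    handle, close = _open(path, "w")
    try:
        for iv in intervals:
            handle.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t.\t.\t{iv.strand}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Tabular hit table (BLAST outfmt-6 column order + frame)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore frame"
).split()


def read_hit_table(path: PathOrFile) -> Iterator[HitRecord]:
    """Read translated-search hits: outfmt-6 columns plus a frame column.

    Query/target 1-based inclusive coordinates are converted to 0-based
    half-open at this boundary.  A target interval given high-to-low denotes
    the minus strand.
    """
    handle, close = _open(path)
    try:
        for i, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 13:
                raise FormatError(f"line {i}: hit table needs 13 columns, got {len(cols)}")
            try:
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                frame = int(cols[12])
            except ValueError:
                raise FormatError(f"line {i}: non-integer field in hit table") from None
            if qstart > qend:
                strand = "-"
                qstart, qend = qend, qstart
            else:
                strand = "+"
            if sstart > send:
                sstart, send = send, sstart
            yield HitRecord(
                query_id=cols[0],
                gene_id=cols[1],
                pident=float(cols[2]),
                length=int(cols[3]),
                query_start=qstart - 1,
                query_end=qend,
                target_start=sstart - 1,
                target_end=send,
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
                strand=strand,
                frame=frame,
            )
    finally:
        if close:
            handle.close()


def write_hit_table(hits: Iterable[HitRecord], path: PathOrFile) -> None:
    handle, close = _open(path, "w")
    try:
        for h in hits:
            if h.strand == "-":
                qs, qe = h.query_end, h.query_start + 1
            else:
                qs, qe = h.query_start + 1, h.query_end
            handle.write(
                "\t".join(
                    map(
                        str,
                        [
                            h.query_id, h.gene_id, h.pident, h.length, 0, 0,
                            qs, qe, h.target_start + 1, h.target_end,
                            h.evalue, h.bitscore, h.frame,
                        ],
                    )
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()
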