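"""Readers and writers for the plain-text formats the toolkit touches.

All internal coordinates are 0-based half-open; 1-based inclusive inputs
(SAM, BLAST tabular) are shifted at this boundary and shifted back on
output. Sequence parsing is delegated to Bio.SeqIO; SAM reading to pysam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
import pysam


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred qualities.

    ``species_tag`` records which species/genome the sequence belongs to;
    the contamination test keys its self/non-self decision on it.
    """

    id: str
    residues: str
    qualities: Optional[list[int]] = None
    species_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadPair:
    """Two mates sequenced from the ends of one DNA fragment."""

    mate1: SeqRecord
    mate2: SeqRecord
    pair_id: str

    def __post_init__(self) -> None:
        if not self.mate1.residues or not self.mate2.residues:
            raise ValueError(f"pair {self.pair_id!r}: empty mate")


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SamRecord:
    """Subset of a SAM line needed for read placement."""

    qname: str
    seq_id: Optional[str]
    start: Optional[int]  # 0-based; None if unmapped
    is_read1: bool
    is_reverse: bool
    is_unmapped: bool
    length: int


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _check_unique_ids(records: list[SeqRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly line-wrapped) FASTA file; empty file -> empty list."""
    records = [
        SeqRecord(id=r.id, residues=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read 4-line FASTQ records (Phred+33) with qualities populated."""
    records = []
    for r in SeqIO.parse(str(path), "fastq"):
        records.append(
            SeqRecord(
                id=r.id,
                residues=str(r.seq).upper(),
                qualities=list(r.letter_annotations["phred_quality"]),
            )
        )
    _check_unique_ids(records)
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(33 + q) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")


def quality_mask(read: SeqRecord, min_q: int = 20) -> SeqRecord:
    """Replace bases below ``min_q`` with N (seqtk seq -q style masking).

    Length is conserved; qualities are carried over unchanged.
    """
    if read.qualities is None:
        raise ValueError(f"read {read.id!r} has no qualities to mask on")
    masked = "".join(
        "N" if q < min_q else b for b, q in zip(read.residues, read.qualities)
    )
    return replace(read, residues=masked)


def n_fraction(read: SeqRecord) -> float:
    if not read.residues:
        return 1.0
    return read.residues.count("N") / len(read.residues)


def is_low_quality(read: SeqRecord, max_n_frac: float = 0.5) -> bool:
    """Reads with more than ``max_n_frac`` masked/ambiguous bases are dropped
    from classification rather than trimmed."""
    return n_fraction(read) > max_n_frac


# ---------------------------------------------------------------------------
# BED


def read_intervals(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 (already 0-based half-open)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >=3 BED columns")
            strand = parts[5] if len(parts) >= 6 else "+"
            try:
                out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# BLAST-style 12-column tabular

_TABULAR_COLS = 12


def read_tabular_hits(path: str | Path) -> list:
    """Read 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore).

    1-based inclusive spans are normalized to 0-based half-open; subject
    spans with sstart > send become minus-strand hits with start < end.
    """
    from .alignkit import SearchHit  # deferred: alignkit imports this module

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _TABULAR_COLS:
                raise FormatError(
                    f"line {lineno}: expected {_TABULAR_COLS} columns, got {len(parts)}"
                )
            (qid, sid, pident, length, _mm, _go, qs, qe, ss, se, ev, bits) = parts
            qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            hits.append(
                SearchHit(
                    query_id=qid,
                    subject_id=sid,
                    subject_species=None,
                    raw_score=0,
                    bitscore=float(bits),
                    evalue=float(ev),
                    identity_pct=float(pident),
                    q_span=Interval(qid, qs - 1, qe),
                    s_span=Interval(sid, ss - 1, se),
                    strand=strand,
                    aligned_columns=int(length),
                )
            )
    return hits


def write_tabular_hits(hits: Iterable, path: str | Path) -> None:
    """Emit hits in the 12-column tabular dialect (1-based inclusive spans,
    minus-strand hits written with sstart > send)."""
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.s_span.start + 1, h.s_span.end
            if h.strand == "-":
                ss, se = se, ss
            n_cols = h.aligned_columns or len(h.q_span)
            n_ident = round(h.identity_pct / 100.0 * n_cols)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        n_cols,
                        n_cols - n_ident,
                        0,
                        h.q_span.start + 1,
                        h.q_span.end,
                        ss,
                        se,
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM (text subset)


def read_samlite(path: str | Path) -> list[SamRecord]:
    """Read placements from a text SAM via pysam (QNAME/FLAG/RNAME/POS)."""
    out: list[SamRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            out.append(
                SamRecord(
                    qname=rec.query_name,
                    seq_id=None if rec.is_unmapped else rec.reference_name,
                    start=None if rec.is_unmapped else rec.reference_start,
                    is_read1=not rec.is_read2,
                    is_reverse=rec.is_reverse,
                    is_unmapped=rec.is_unmapped,
                    length=rec.query_length or (len(rec.query_sequence or "")),
                )
            )
    return out


def write_samlite(
    records: Iterable[tuple[SeqRecord, Optional[str], Optional[int], bool, bool]],
    references: dict[str, int],
    path: str | Path,
) -> None:
    """Write minimal SAM. ``records`` yields (read, seq_id, start0, is_read1,
    is_reverse); seq_id None means unmapped. ``references`` maps name->length."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for read, seq_id, start, is_read1, is_reverse in records:
            flag = 0x1 | (0x40 if is_read1 else 0x80)
            if seq_id is None:
                flag |= 0x4
                rname, pos, cigar = "*", 0, "*"
            else:
                rname, pos, cigar = seq_id, start + 1, f"{len(read)}M"
                if is_reverse:
                    flag |= 0x10
            qual = (
                "".join(chr(33 + q) for q in read.qualities)
                if read.qualities
                else "*"
            )
            fh.write(
                f"{read.id}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
                f"{read.residues}\t{qual}\n"
            )
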