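"""Repeat-library annotation and masking.

Stands in for RepeatMasker at the scales this toolkit targets: each library
consensus is searched against the target sequence, hits become family
annotations (with a raw divergence over aligned columns, gap columns
included), same-family overlaps are merged, and length/divergence filters
are applied after merging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .alignkit import NUCLEOTIDE_SCHEME, ScoringScheme, SearchDatabase, search
from .io_formats import Interval, SeqRecord


@dataclass
class RepeatAnnotation:
    """A repeat-derived interval on a sequence.

    ``divergence_pct`` counts mismatches+indels over aligned columns (x100).
    ``consensus_span`` is the matched span on the library consensus, used by
    defragmentation to test collinearity of fragments.
    """

    interval: Interval
    family: str
    divergence_pct: float
    score: float
    consensus_span: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.interval)


def _merge_family(anns: list[RepeatAnnotation]) -> list[RepeatAnnotation]:
    """Union overlapping same-family annotations; merged divergence is the
    length-weighted mean of the parts, score the max."""
    anns = sorted(anns, key=lambda a: (a.interval.start, a.interval.end))
    merged: list[RepeatAnnotation] = []
    for a in anns:
        if merged and a.interval.start < merged[-1].interval.end:
            prev = merged[-1]
            new_end = max(prev.interval.end, a.interval.end)
            w_prev, w_a = len(prev), len(a)
            div = (prev.divergence_pct * w_prev + a.divergence_pct * w_a) / (
                w_prev + w_a
            )
            cs = prev.consensus_span
            if cs is not None and a.consensus_span is not None:
                cs = (
                    min(cs[0], a.consensus_span[0]),
                    max(cs[1], a.consensus_span[1]),
                )
            merged[-1] = RepeatAnnotation(
                interval=Interval(
                    prev.interval.seq_id, prev.interval.start, new_end,
                    prev.interval.strand,
                ),
                family=prev.family,
                divergence_pct=div,
                score=max(prev.score, a.score),
                consensus_span=cs,
            )
        else:
            merged.append(a)
    return merged


def annotate_repeats(
    seq: SeqRecord,
    library: Sequence[SeqRecord],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
    min_len: int = 50,
    max_divergence: float = 100.0,
    evalue_cutoff: float = 1e-5,
    k: int = 11,
) -> list[RepeatAnnotation]:
    """Annotate all library-derived intervals on ``seq``.

    Overlapping annotations of the same family (and strand) are merged
    before the ``min_len`` (keep >= threshold) and ``max_divergence``
    (keep strictly under threshold) filters are applied.
    """
    if not library:
        return []
    target_db = SearchDatabase([seq], label="target")
    raw: dict[tuple[str, str], list[RepeatAnnotation]] = {}
    for consensus in library:
        hits = search(consensus, target_db, scheme, evalue_cutoff, k=k)
        for h in hits:
            ann = RepeatAnnotation(
                interval=Interval(
                    seq.id, h.s_span.start, h.s_span.end, h.strand
                ),
                family=consensus.id,
                divergence_pct=100.0 - h.identity_pct,
                score=h.bitscore,
                consensus_span=(h.q_span.start, h.q_span.end),
            )
            raw.setdefault((consensus.id, h.strand), []).append(ann)
    out: list[RepeatAnnotation] = []
    for anns in raw.values():
        for m in _merge_family(anns):
            if len(m) >= min_len and m.divergence_pct < max_divergence:
                out.append(m)
    out.sort(key=lambda a: (a.interval.start, a.interval.end, a.family))
    return out


def reference_rte_bed(
    assembly: Sequence[SeqRecord],
    rte_consensus: SeqRecord,
    max_div: float = 20.0,
    min_len: int = 200,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> list[Interval]:
    """Locate one element family on a reference assembly, keeping copies
    under ``max_div``% divergence and at least ``min_len`` bp long."""
    intervals: list[Interval] = []
    for contig in assembly:
        anns = annotate_repeats(
            contig, [rte_consensus], scheme,
            min_len=min_len, max_divergence=max_div,
        )
        intervals.extend(a.interval for a in anns)
    return intervals


def mask(
    seq: SeqRecord,
    annotations: Iterable[RepeatAnnotation],
    mode: str = "hard",
) -> tuple[SeqRecord, int]:
    """Mask annotated intervals (hard: N, soft: lowercase); returns the
    masked record and the informative (unmasked) base count."""
    if mode not in ("hard", "soft"):
        raise ValueError(f"unknown mask mode {mode!r}")
    residues = list(seq.residues)
    n = len(residues)
    covered = [False] * n
    for ann in annotations:
        iv = ann.interval
        if iv.seq_id != seq.id:
            raise ValueError(f"annotation on {iv.seq_id!r}, sequence is {seq.id!r}")
        if iv.end > n:
            raise ValueError(f"annotation {iv.start}-{iv.end} out of bounds (len {n})")
        for i in range(iv.start, iv.end):
            covered[i] = True
    masked = [
        ("N" if mode == "hard" else b.lower()) if c else b
        for b, c in zip(residues, covered)
    ]
    informative = n - sum(covered)
    return replace(seq, residues="".join(masked)), informative


def write_annotations_tsv(
    annotations: Iterable[RepeatAnnotation], path: str | Path
) -> None:
    """RepeatMasker .out-equivalent TSV."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tfamily\tdivergence_pct\tscore\n")
        for a in annotations:
            iv = a.interval
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t{a.family}\t"
                f"{a.divergence_pct:.2f}\t{a.score:.1f}\n"
            )


def read_annotations_tsv(path: str | Path) -> list[RepeatAnnotation]:
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            seq_id, start, end, strand, family, div, score = line.rstrip("\n").split("\t")
            out.append(
                RepeatAnnotation(
                    interval=Interval(seq_id, int(start), int(end), strand),
                    family=family,
                    divergence_pct=float(div),
                    score=float(score),
                )
            )
    return out
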