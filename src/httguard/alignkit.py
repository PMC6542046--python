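"""Desk-scale sequence search engine.

Local/global affine-gap alignment (delegated to Bio.Align.PairwiseAligner),
six-frame translation, Karlin-Altschul bitscore/E-value statistics, and a
k-mer seed-and-extend database search over nucleotide or (translated)
protein space. The engine replaces an external BLAST/DIAMOND at the scales
this toolkit targets, and speaks the 12-column tabular dialect so a user's
own search results can be substituted anywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import Interval, SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScoringScheme:
    """Alignment scores plus the Karlin-Altschul constants that convert a
    raw score into a bitscore.

    Defaults are the classic blastn scheme (+2/-3, gap open 5, extend 2)
    with its widely published gapped constants lambda=0.625, K=0.41. Setting
    ``protein_matrix`` switches the aligners to matrix scoring (BLOSUM62 for
    the bundled protein scheme, lambda=0.267, K=0.041).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    k_const: float = 0.41
    protein_matrix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protein_matrix is None:
            if self.match <= 0 or self.mismatch >= 0:
                raise ValueError("match must be >0 and mismatch <0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes, must be >=0")
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        if not 0 < self.k_const < 1:
            raise ValueError("K must be in (0,1)")


NUCLEOTIDE_SCHEME = ScoringScheme()
PROTEIN_SCHEME = ScoringScheme(
    match=1,
    mismatch=-1,
    gap_open=11,
    gap_extend=1,
    lam=0.267,
    k_const=0.041,
    protein_matrix="BLOSUM62",
)


@lru_cache(maxsize=16)
def _aligner(
    mode: str,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    matrix: Optional[str],
    free_end_gaps: bool,
) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if matrix is not None:
        al.substitution_matrix = substitution_matrices.load(matrix)
    else:
        al.match_score = match
        al.mismatch_score = mismatch
    # gap of length L costs open + L*extend (BLAST convention)
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    if free_end_gaps:
        al.open_end_gap_score = 0
        al.extend_end_gap_score = 0
    return al


def aligner_for(scheme: ScoringScheme, mode: str, free_end_gaps: bool = False):
    return _aligner(
        mode,
        scheme.match,
        scheme.mismatch,
        scheme.gap_open,
        scheme.gap_extend,
        scheme.protein_matrix,
        free_end_gaps,
    )


@dataclass
class PairwiseAlignment:
    """One pairwise alignment with explicit gapped strings and 0-based
    half-open spans on each input."""

    score: float
    aligned_a: str
    aligned_b: str
    a_span: tuple[int, int]
    b_span: tuple[int, int]

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_matches(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    @property
    def identity_pct(self) -> float:
        if self.n_columns == 0:
            return 0.0
        return 100.0 * self.n_matches / self.n_columns


def _as_str(seq) -> str:
    return seq.residues if isinstance(seq, SeqRecord) else str(seq)


def _expand(alignment, a: str, b: str, full_extent: bool = False) -> PairwiseAlignment:
    """Turn a Bio.Align alignment (block coordinates) into gapped strings.

    ``full_extent`` pads terminal gaps so both sequences appear whole
    (global alignments)."""
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        if full_extent:
            return PairwiseAlignment(
                alignment.score,
                a + "-" * len(b),
                "-" * len(a) + b,
                (0, len(a)),
                (0, len(b)),
            )
        return PairwiseAlignment(alignment.score, "", "", (0, 0), (0, 0))
    out_a: list[str] = []
    out_b: list[str] = []
    prev_a_end, prev_b_end = blocks_a[0][0], blocks_b[0][0]
    if full_extent:
        prev_a_end, prev_b_end = 0, 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if a0 > prev_a_end:  # gap in b
            out_a.append(a[prev_a_end:a0])
            out_b.append("-" * (a0 - prev_a_end))
        if b0 > prev_b_end:  # gap in a
            out_a.append("-" * (b0 - prev_b_end))
            out_b.append(b[prev_b_end:b0])
        out_a.append(a[a0:a1])
        out_b.append(b[b0:b1])
        prev_a_end, prev_b_end = a1, b1
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    if full_extent:
        if prev_a_end < len(a):
            out_a.append(a[prev_a_end:])
            out_b.append("-" * (len(a) - prev_a_end))
        if prev_b_end < len(b):
            out_a.append("-" * (len(b) - prev_b_end))
            out_b.append(b[prev_b_end:])
        a_span, b_span = (0, len(a)), (0, len(b))
    return PairwiseAlignment(
        score=alignment.score,
        aligned_a="".join(out_a),
        aligned_b="".join(out_b),
        a_span=a_span,
        b_span=b_span,
    )


def smith_waterman(a, b, scheme: ScoringScheme = NUCLEOTIDE_SCHEME) -> PairwiseAlignment:
    """Best local alignment under affine gaps; deterministic traceback
    (first optimal alignment). All-negative inputs yield score 0 and an
    empty alignment."""
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    al = aligner_for(scheme, "local")
    score = al.score(sa, sb)
    if score <= 0:
        return PairwiseAlignment(0.0, "", "", (0, 0), (0, 0))
    return _expand(al.align(sa, sb)[0], sa, sb)


def needleman_wunsch(a, b, scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
                     free_end_gaps: bool = False) -> PairwiseAlignment:
    """Optimal global alignment under affine gaps; end gaps penalized unless
    ``free_end_gaps``."""
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    al = aligner_for(scheme, "global", free_end_gaps)
    return _expand(al.align(sa, sb)[0], sa, sb, full_extent=True)


# ---------------------------------------------------------------------------
# Translation

_FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(rec: SeqRecord | str) -> list[tuple[int, str]]:
    """Translate in all six frames (standard code, stops as '*', N -> X).

    Returns [(frame, peptide)] with frames +1..+3 on the forward strand and
    -1..-3 on the reverse complement.
    """
    seq = _as_str(rec).upper()
    out = []
    for frame in _FRAMES:
        s = seq if frame > 0 else revcomp(seq)
        off = abs(frame) - 1
        sub = s[off : off + 3 * ((len(s) - off) // 3)]
        pep = str(Seq(sub).translate()) if sub else ""
        out.append((frame, pep))
    return out


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def bitscore(raw_score: float, scheme: ScoringScheme) -> float:
    """bits = (lambda*S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    return (scheme.lam * raw_score - math.log(scheme.k_const)) / math.log(2)


def evalue(bits: float, m_eff: float, n_eff: float) -> float:
    """E = m_eff * n_eff * 2^(-bits)."""
    if m_eff <= 0 or n_eff <= 0:
        raise ValueError("effective lengths must be positive")
    return m_eff * n_eff * math.pow(2.0, -bits)


# ---------------------------------------------------------------------------
# Database search


@dataclass
class SearchHit:
    """A scored local hit of a query against one database record."""

    query_id: str
    subject_id: str
    subject_species: Optional[str]
    raw_score: float
    bitscore: float
    evalue: float
    identity_pct: float
    q_span: Interval
    s_span: Interval
    strand: str
    aligned_columns: int = 0
    frame: Optional[int] = None

    @property
    def sort_key(self):
        return (-self.bitscore, self.evalue, self.subject_id)


class SearchDatabase:
    """A set of subject sequences with a lazily built k-mer index.

    ``label`` is "self" or "non-self" in the contamination test, but any
    tag works for generic searches.
    """

    def __init__(self, records: Sequence[SeqRecord], label: str = "db",
                 effective_size_override: Optional[int] = None):
        if not records:
            raise ValueError("database must contain at least one record")
        self.records = list(records)
        self.label = label
        self.effective_size_override = effective_size_override
        self._index: dict[int, dict[str, list[tuple[int, int]]]] = {}

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def effective_size(self) -> int:
        return self.effective_size_override or self.total_length

    def kmer_index(self, k: int) -> dict[str, list[tuple[int, int]]]:
        if k not in self._index:
            index: dict[str, list[tuple[int, int]]] = {}
            for ri, rec in enumerate(self.records):
                s = rec.residues
                for pos in range(len(s) - k + 1):
                    kmer = s[pos : pos + k]
                    if "N" in kmer or "X" in kmer or "*" in kmer:
                        continue
                    index.setdefault(kmer, []).append((ri, pos))
            self._index[k] = index
        return self._index[k]


def _seed_clusters(
    qseq: str, index: dict[str, list[tuple[int, int]]], k: int, window: int
) -> dict[int, list[tuple[int, int]]]:
    """Collect seed matches grouped by record, clustered along the subject."""
    by_record: dict[int, list[tuple[int, int]]] = {}
    for qpos in range(len(qseq) - k + 1):
        kmer = qseq[qpos : qpos + k]
        hits = index.get(kmer)
        if not hits:
            continue
        for ri, spos in hits:
            by_record.setdefault(ri, []).append((spos, qpos))
    return by_record


_SEED_PAD = 120
_DIAG_TOL = 120
_POS_GAP = 500


def _cluster_seed_boxes(
    seeds: list[tuple[int, int]], qlen: int, slen: int, k: int
) -> list[tuple[int, int, int, int]]:
    """Chain seeds into candidate (qlo, qhi, slo, shi) boxes.

    Seeds join a chain when close along the subject and on a nearby
    diagonal (tolerating indel drift); the resulting boxes bound the
    extension work by the matched-region size rather than the query size.
    """
    seeds.sort()
    chains: list[dict] = []
    for spos, qpos in seeds:
        diag = spos - qpos
        placed = False
        for ch in reversed(chains):
            if spos - ch["shi"] > _POS_GAP:
                break
            if abs(diag - ch["diag"]) <= _DIAG_TOL and spos >= ch["slo"]:
                ch["qlo"] = min(ch["qlo"], qpos)
                ch["qhi"] = max(ch["qhi"], qpos + k)
                ch["slo"] = min(ch["slo"], spos)
                ch["shi"] = max(ch["shi"], spos + k)
                ch["diag"] = diag
                placed = True
                break
        if not placed:
            chains.append(
                {"qlo": qpos, "qhi": qpos + k, "slo": spos, "shi": spos + k,
                 "diag": diag}
            )
    boxes: list[tuple[int, int, int, int]] = []
    for ch in chains:
        boxes.append(
            (
                max(0, ch["qlo"] - _SEED_PAD),
                min(qlen, ch["qhi"] + _SEED_PAD),
                max(0, ch["slo"] - _SEED_PAD),
                min(slen, ch["shi"] + _SEED_PAD),
            )
        )
    # merge overlapping boxes so each region is extended once
    boxes.sort()
    merged: list[list[int]] = []
    for qlo, qhi, slo, shi in boxes:
        if merged and qlo <= merged[-1][1] and slo <= merged[-1][3] and shi >= merged[-1][2]:
            merged[-1][1] = max(merged[-1][1], qhi)
            merged[-1][2] = min(merged[-1][2], slo)
            merged[-1][3] = max(merged[-1][3], shi)
            merged[-1][0] = min(merged[-1][0], qlo)
        else:
            merged.append([qlo, qhi, slo, shi])
    return [tuple(m) for m in merged]


_EXACT_DP_CELLS = 1_000_000


def _scores_per_column(aligned_a: str, aligned_b: str, scheme: ScoringScheme) -> list[float]:
    scores: list[float] = []
    in_gap = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            scores.append(
                -(scheme.gap_open + scheme.gap_extend) if not in_gap else -scheme.gap_extend
            )
            in_gap = True
        else:
            scores.append(scheme.match if x == y else scheme.mismatch)
            in_gap = False
    return scores


def _kadane_trim(
    aligned_a: str, aligned_b: str, scheme: ScoringScheme
) -> tuple[float, int, int]:
    """Best-scoring contiguous segment of an alignment path (local trim)."""
    scores = _scores_per_column(aligned_a, aligned_b, scheme)
    best = cur = 0.0
    best_lo = best_hi = lo = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur, lo = s, i
        else:
            cur += s
        if cur > best:
            best, best_lo, best_hi = cur, lo, i + 1
    return best, best_lo, best_hi


_EDLIB_CIGAR = {"=": "match", "X": "mismatch", "I": "ins", "D": "del"}


def _edlib_local(qseq: str, sub: str, scheme: ScoringScheme) -> PairwiseAlignment:
    """Near-linear local alignment of a large candidate box: edlib edit-
    distance path, rescored under the scheme and trimmed to the best local
    segment."""
    import re

    import edlib

    res = edlib.align(qseq, sub, mode="HW", task="path")
    cigar = res.get("cigar")
    if not cigar:
        return PairwiseAlignment(0.0, "", "", (0, 0), (0, 0))
    s_start = res["locations"][0][0]
    out_a: list[str] = []
    out_b: list[str] = []
    qi, si = 0, s_start
    for n_str, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n_str)
        if op in "=XM":
            out_a.append(qseq[qi : qi + n])
            out_b.append(sub[si : si + n])
            qi += n
            si += n
        elif op == "I":  # consumes query
            out_a.append(qseq[qi : qi + n])
            out_b.append("-" * n)
            qi += n
        else:  # D consumes subject
            out_a.append("-" * n)
            out_b.append(sub[si : si + n])
            si += n
    aligned_a = "".join(out_a)
    aligned_b = "".join(out_b)
    score, lo, hi = _kadane_trim(aligned_a, aligned_b, scheme)
    if score <= 0:
        return PairwiseAlignment(0.0, "", "", (0, 0), (0, 0))
    seg_a = aligned_a[lo:hi]
    seg_b = aligned_b[lo:hi]
    a_off = lo - aligned_a[:lo].count("-")
    b_off = s_start + lo - aligned_b[:lo].count("-")
    return PairwiseAlignment(
        score=score,
        aligned_a=seg_a,
        aligned_b=seg_b,
        a_span=(a_off, a_off + len(seg_a.replace("-", ""))),
        b_span=(b_off, b_off + len(seg_b.replace("-", ""))),
    )


def _align_window(qseq: str, sub: str, scheme: ScoringScheme) -> PairwiseAlignment:
    """Exact affine SW for small boxes; edlib path + rescoring for large
    ones (protein schemes always use exact SW)."""
    if scheme.protein_matrix is None and len(qseq) * len(sub) > _EXACT_DP_CELLS:
        return _edlib_local(qseq, sub, scheme)
    return smith_waterman(qseq, sub, scheme)


def _search_one_strand(
    qseq: str,
    query: SeqRecord,
    db: SearchDatabase,
    scheme: ScoringScheme,
    k: int,
    strand: str,
    m_eff: int,
    n_eff: int,
    evalue_cutoff: float,
) -> list[SearchHit]:
    index = db.kmer_index(k)
    hits: list[SearchHit] = []
    qlen = len(qseq)
    for ri, seeds in _seed_clusters(qseq, index, k, qlen).items():
        rec = db.records[ri]
        for qlo, qhi, slo, shi in _cluster_seed_boxes(seeds, qlen, len(rec), k):
            sub = rec.residues[slo:shi]
            aln = _align_window(qseq[qlo:qhi], sub, scheme)
            if aln.score <= 0:
                continue
            bits = bitscore(aln.score, scheme)
            ev = evalue(bits, m_eff, n_eff)
            if ev > evalue_cutoff:
                continue
            qs, qe = qlo + aln.a_span[0], qlo + aln.a_span[1]
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            hits.append(
                SearchHit(
                    query_id=query.id,
                    subject_id=rec.id,
                    subject_species=rec.species_tag,
                    raw_score=aln.score,
                    bitscore=bits,
                    evalue=ev,
                    identity_pct=aln.identity_pct,
                    q_span=Interval(query.id, qs, qe),
                    s_span=Interval(rec.id, slo + aln.b_span[0], slo + aln.b_span[1]),
                    strand=strand,
                    aligned_columns=aln.n_columns,
                )
            )
    return hits


def _dedupe(hits: list[SearchHit]) -> list[SearchHit]:
    best: dict[tuple, SearchHit] = {}
    for h in hits:
        key = (h.subject_id, h.s_span.start, h.s_span.end, h.strand)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    return list(best.values())


def search(
    query: SeqRecord,
    db: SearchDatabase,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
    evalue_cutoff: float = 1e-10,
    db_size_for_stats: Optional[int] = None,
    k: int = 11,
) -> list[SearchHit]:
    """Seed-and-extend nucleotide search of ``query`` against ``db``.

    Both strands of the query are searched. E-values use
    ``db_size_for_stats`` as the effective database length when given, so
    searches of two databases can share one statistical footing (the
    contamination test adjusts both to the larger database). Hits are
    sorted by bitscore desc, then E-value asc, then subject id.
    """
    qseq = query.residues.upper()
    if len(qseq) < k:
        return []  # query-too-short
    m_eff = len(qseq)
    n_eff = db_size_for_stats or db.effective_size
    hits: list[SearchHit] = []
    for strand, s in (("+", qseq), ("-", revcomp(qseq))):
        hits.extend(
            _search_one_strand(s, query, db, scheme, k, strand, m_eff, n_eff,
                               evalue_cutoff)
        )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: h.sort_key)
    return hits


def translated_search(
    read: SeqRecord,
    protein_db: SearchDatabase | Sequence[SeqRecord],
    scheme: ScoringScheme = PROTEIN_SCHEME,
    evalue_cutoff: float = 1e-10,
    k: int = 5,
) -> list[SearchHit]:
    """Search a nucleotide read against protein subjects in all six frames
    (DIAMOND blastx style). Spans and identities are in amino-acid space of
    the reported frame; E-values use the translated query length."""
    if not isinstance(protein_db, SearchDatabase):
        protein_db = SearchDatabase(protein_db, label="protein")
    if len(read.residues) < 3:
        return []
    hits: list[SearchHit] = []
    n_eff = protein_db.effective_size
    for frame, pep in six_frame_translate(read):
        if len(pep) < k:
            continue
        frame_query = SeqRecord(id=read.id, residues=pep)
        frame_hits = _search_one_strand(
            pep, frame_query, protein_db, scheme, k,
            "+" if frame > 0 else "-", len(pep), n_eff, evalue_cutoff,
        )
        for h in frame_hits:
            h.frame = frame
        hits.extend(frame_hits)
    best: dict[tuple, SearchHit] = {}
    for h in hits:
        key = (h.subject_id, h.s_span.start, h.s_span.end, h.frame)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    hits = list(best.values())
    hits.sort(key=lambda h: h.sort_key)
    return hits


def best_hit(hits: list[SearchHit]) -> Optional[SearchHit]:
    return hits[0] if hits else None
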