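"""The contamination test: decide whether reads carrying a candidate
horizontally transferred element belong to the sequenced species or to a
contaminant.

Three selection modes pick the reads that carry the element:

* ``long``  — long reads whose translation hits the element's ORF;
* ``ref``   — read pairs where exactly one mate maps inside an annotated
  element region of the reference assembly (the other mate is informative);
* ``noref`` — quality-masked read pairs where exactly one mate has a
  reciprocal nucleotide hit to the element consensus.

The informative read/mate is then hard-masked against the full repeat
library and searched against two databases — "self" (genomes of the focal
taxon) and "non-self" (genomes of the candidate donor/contaminant taxon) —
with a shared effective database size so E-values are comparable. Hits to
the focal species' own genome are discarded; the label of the best
surviving hit decides the verdict. A dataset-level majority of self
verdicts is consistent with an endogenous element (hence possible HTT);
a majority of non-self verdicts indicates contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .alignkit import (
    NUCLEOTIDE_SCHEME,
    PROTEIN_SCHEME,
    ScoringScheme,
    SearchDatabase,
    SearchHit,
    search,
    translated_search,
)
from .io_formats import (
    Interval,
    ReadPair,
    SeqRecord,
    is_low_quality,
    quality_mask,
)
from .repeatmask import annotate_repeats, mask

VERDICTS = ("self", "non-self", "ambiguous", "unassigned", "low-quality")


@dataclass
class Classification:
    read_id: str
    verdict: str
    best_hit: Optional[SearchHit] = None
    discarded_own_genome_hits: int = 0


@dataclass
class ContestSummary:
    n_selected: int
    n_self: int
    n_nonself: int
    n_ambiguous: int
    n_unassigned: int
    n_low_quality: int
    frac_self: float
    frac_nonself: float
    call: str  # endogenous/HTT-consistent | contamination | inconclusive
    warning: Optional[str] = None

    @property
    def n_assigned(self) -> int:
        return self.n_self + self.n_nonself


# ---------------------------------------------------------------------------
# Read selection


def _best_library_hit(
    read: SeqRecord,
    library_db: SearchDatabase,
    scheme: ScoringScheme,
    evalue_cutoff: float,
) -> Optional[SearchHit]:
    hits = search(read, library_db, scheme, evalue_cutoff)
    return hits[0] if hits else None


def select_long_reads(
    reads: Sequence[SeqRecord],
    rte_orf_protein: SeqRecord,
    evalue: float = 1e-10,
    scheme: ScoringScheme = PROTEIN_SCHEME,
) -> list[SeqRecord]:
    """Long reads whose six-frame translation hits the element ORF."""
    protein_db = SearchDatabase([rte_orf_protein], label="rte_orf")
    selected = []
    for read in reads:
        if translated_search(read, protein_db, scheme, evalue):
            selected.append(read)
    return selected


def select_pairs_reference(
    pairs: Sequence[ReadPair],
    mappings: dict[str, tuple],
    rte_bed: Sequence[Interval],
    rte_consensus: SeqRecord | Sequence[SeqRecord],
    repeat_library: Optional[Sequence[SeqRecord]] = None,
    evalue: float = 1e-10,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> tuple[list[tuple[SeqRecord, SeqRecord]], dict[str, int]]:
    """Reference-based selection: keep pairs where exactly one mate overlaps
    an annotated element interval (>=1 bp) and that mate reciprocally hits
    the element consensus (its best repeat-library hit IS the element).

    ``mappings`` maps pair_id -> (placement1, placement2); placements need
    ``seq_id``/``start``/``end`` attributes, None meaning unmapped.
    Returns [(informative_mate, rte_mate)] and selection counters.
    """
    rte_records = (
        [rte_consensus] if isinstance(rte_consensus, SeqRecord) else list(rte_consensus)
    )
    rte_names = {r.id for r in rte_records}
    library = list(repeat_library) if repeat_library else rte_records
    library_db = SearchDatabase(library, label="repeat_library")
    counters = {"unmapped": 0, "both_in_rte": 0, "neither_in_rte": 0,
                "reciprocal_fail": 0, "kept": 0}
    out: list[tuple[SeqRecord, SeqRecord]] = []

    def overlaps(placement) -> bool:
        if placement is None:
            return False
        for iv in rte_bed:
            if (
                placement.seq_id == iv.seq_id
                and placement.start < iv.end
                and iv.start < placement.end
            ):
                return True
        return False

    for pair in pairs:
        p1, p2 = mappings.get(pair.pair_id, (None, None))
        if p1 is None and p2 is None:
            counters["unmapped"] += 1
            continue
        in1, in2 = overlaps(p1), overlaps(p2)
        if in1 and in2:
            counters["both_in_rte"] += 1
            continue
        if not in1 and not in2:
            counters["neither_in_rte"] += 1
            continue
        rte_mate, informative = (
            (pair.mate1, pair.mate2) if in1 else (pair.mate2, pair.mate1)
        )
        best = _best_library_hit(rte_mate, library_db, scheme, evalue)
        if best is None or best.subject_id not in rte_names:
            counters["reciprocal_fail"] += 1
            continue
        counters["kept"] += 1
        out.append((informative, rte_mate))
    return out, counters


def select_pairs_noref(
    pairs: Sequence[ReadPair],
    rte_consensus: SeqRecord | Sequence[SeqRecord],
    repeat_library: Optional[Sequence[SeqRecord]] = None,
    evalue: float = 1e-10,
    min_q: int = 20,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Assembly-free selection: quality-mask both mates, keep pairs where
    one mate's best repeat-library hit is the element (E < cutoff) and the
    other mate has no element hit at all; the latter is informative."""
    rte_records = (
        [rte_consensus] if isinstance(rte_consensus, SeqRecord) else list(rte_consensus)
    )
    rte_names = {r.id for r in rte_records}
    library = list(repeat_library) if repeat_library else rte_records
    library_db = SearchDatabase(library, label="repeat_library")
    counters = {"both_rte": 0, "neither_rte": 0, "reciprocal_fail": 0,
                "low_quality": 0, "kept": 0}
    out: list[SeqRecord] = []
    for pair in pairs:
        m1 = quality_mask(pair.mate1, min_q) if pair.mate1.qualities else pair.mate1
        m2 = quality_mask(pair.mate2, min_q) if pair.mate2.qualities else pair.mate2
        if is_low_quality(m1) or is_low_quality(m2):
            counters["low_quality"] += 1
            continue
        best1 = _best_library_hit(m1, library_db, scheme, evalue)
        best2 = _best_library_hit(m2, library_db, scheme, evalue)
        is_rte1 = best1 is not None and best1.subject_id in rte_names
        is_rte2 = best2 is not None and best2.subject_id in rte_names
        if is_rte1 and is_rte2:
            counters["both_rte"] += 1
            continue
        if not is_rte1 and not is_rte2:
            counters["neither_rte"] += 1
            continue
        rte_best, informative = (best1, m2) if is_rte1 else (best2, m1)
        # reciprocality: the element must be the mate's best library hit
        if rte_best.subject_id not in rte_names:
            counters["reciprocal_fail"] += 1
            continue
        counters["kept"] += 1
        out.append(informative)
    return out, counters


# ---------------------------------------------------------------------------
# Classification


def classify(
    informative: SeqRecord,
    self_db: SearchDatabase,
    nonself_db: SearchDatabase,
    own_species: str,
    repeat_library: Sequence[SeqRecord],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
    evalue: float = 1e-10,
    min_informative: int = 30,
) -> Classification:
    """Classify one informative read as self / non-self.

    Steps: hard-mask the read against the full repeat library; require at
    least ``min_informative`` unmasked bases; search both databases with the
    shared effective size max(|self|,|non-self|); discard hits whose subject
    species is the focal species; rank the surviving pool by bitscore (ties:
    E-value, subject id). Equal top bitscores in both databases give
    ``ambiguous``; an empty pool gives ``unassigned``.
    """
    if not self_db.records or not nonself_db.records:
        raise ValueError("both databases must be non-empty")
    anns = annotate_repeats(
        informative, repeat_library, scheme, min_len=20, evalue_cutoff=1e-3
    )
    masked, informative_len = mask(informative, anns, mode="hard")
    if informative_len < min_informative:
        return Classification(informative.id, "low-quality")
    n_eff = max(self_db.effective_size, nonself_db.effective_size)
    labelled: list[tuple[SearchHit, str]] = []
    discarded = 0
    for db, label in ((self_db, "self"), (nonself_db, "non-self")):
        for h in search(masked, db, scheme, evalue, db_size_for_stats=n_eff):
            if h.subject_species == own_species:
                discarded += 1
                continue
            labelled.append((h, label))
    if not labelled:
        return Classification(informative.id, "unassigned",
                              discarded_own_genome_hits=discarded)
    labelled.sort(key=lambda hl: hl[0].sort_key)
    top_hit, top_label = labelled[0]
    other = [h for h, lab in labelled if lab != top_label]
    if other and other[0].bitscore == top_hit.bitscore:
        return Classification(informative.id, "ambiguous", best_hit=top_hit,
                              discarded_own_genome_hits=discarded)
    return Classification(informative.id, top_label, best_hit=top_hit,
                          discarded_own_genome_hits=discarded)


def summarize(
    classifications: Iterable[Classification | str] | dict[str, int],
    call_threshold: float = 0.80,
) -> ContestSummary:
    """Dataset-level verdict from per-read classifications (or a dict of
    verdict counts). Fractions are over assigned (self + non-self) reads;
    the call needs a ``call_threshold`` majority."""
    counts = {v: 0 for v in VERDICTS}
    if isinstance(classifications, dict):
        for v, n in classifications.items():
            key = {"nonself": "non-self", "low_quality": "low-quality"}.get(v, v)
            if key not in counts:
                raise ValueError(f"unknown verdict {v!r}")
            counts[key] += n
    else:
        for c in classifications:
            v = c if isinstance(c, str) else c.verdict
            counts[v] += 1
    n_selected = sum(counts.values())
    assigned = counts["self"] + counts["non-self"]
    warning = None
    if assigned == 0:
        frac_self = frac_nonself = 0.0
        call = "inconclusive"
        warning = "no assigned reads"
    else:
        frac_self = counts["self"] / assigned
        frac_nonself = counts["non-self"] / assigned
        if frac_nonself >= call_threshold:
            call = "contamination"
        elif frac_self >= call_threshold:
            call = "endogenous/HTT-consistent"
        else:
            call = "inconclusive"
    return ContestSummary(
        n_selected=n_selected,
        n_self=counts["self"],
        n_nonself=counts["non-self"],
        n_ambiguous=counts["ambiguous"],
        n_unassigned=counts["unassigned"],
        n_low_quality=counts["low-quality"],
        frac_self=frac_self,
        frac_nonself=frac_nonself,
        call=call,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Orchestration


def run_contest(
    mode: str,
    self_records: Sequence[SeqRecord],
    nonself_records: Sequence[SeqRecord],
    own_species: str,
    repeat_library: Sequence[SeqRecord],
    pairs: Optional[Sequence[ReadPair]] = None,
    long_reads: Optional[Sequence[SeqRecord]] = None,
    rte_consensus: Optional[SeqRecord] = None,
    rte_orf_protein: Optional[SeqRecord] = None,
    mappings: Optional[dict] = None,
    rte_bed: Optional[Sequence[Interval]] = None,
    evalue: float = 1e-10,
    call_threshold: float = 0.80,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> tuple[ContestSummary, list[Classification], dict[str, int]]:
    """Run one full contamination test (selection + classification +
    summary) in the given mode ('long' | 'ref' | 'noref')."""
    self_db = SearchDatabase(self_records, label="self")
    nonself_db = SearchDatabase(nonself_records, label="non-self")
    if mode == "long":
        if long_reads is None or rte_orf_protein is None:
            raise ValueError("long mode needs long_reads and rte_orf_protein")
        informative = select_long_reads(long_reads, rte_orf_protein, evalue)
        counters = {"kept": len(informative),
                    "not_selected": len(long_reads) - len(informative)}
    elif mode == "ref":
        if pairs is None or mappings is None or rte_bed is None or rte_consensus is None:
            raise ValueError("ref mode needs pairs, mappings, rte_bed, rte_consensus")
        kept, counters = select_pairs_reference(
            pairs, mappings, rte_bed, rte_consensus, repeat_library, evalue, scheme
        )
        informative = [info for info, _ in kept]
    elif mode == "noref":
        if pairs is None or rte_consensus is None:
            raise ValueError("noref mode needs pairs and rte_consensus")
        informative, counters = select_pairs_noref(
            pairs, rte_consensus, repeat_library, evalue, scheme=scheme
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    classifications = [
        classify(read, self_db, nonself_db, own_species, repeat_library,
                 scheme, evalue)
        for read in informative
    ]
    return summarize(classifications, call_threshold), classifications, counters


def write_per_read_tsv(classifications: Iterable[Classification],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tverdict\tbest_subject\tbest_species\tbitscore\tevalue\n")
        for c in classifications:
            if c.best_hit is None:
                fh.write(f"{c.read_id}\t{c.verdict}\tNA\tNA\tNA\tNA\n")
            else:
                h = c.best_hit
                fh.write(
                    f"{c.read_id}\t{c.verdict}\t{h.subject_id}\t"
                    f"{h.subject_species or 'NA'}\t{h.bitscore:.1f}\t"
                    f"{h.evalue:.2e}\n"
                )


def write_summary_tsv(summary: ContestSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "n_selected\tn_self\tn_nonself\tn_ambiguous\tn_unassigned\t"
            "n_low_quality\tfrac_self\tfrac_nonself\tcall\n"
        )
        fh.write(
            f"{summary.n_selected}\t{summary.n_self}\t{summary.n_nonself}\t"
            f"{summary.n_ambiguous}\t{summary.n_unassigned}\t"
            f"{summary.n_low_quality}\t{summary.frac_self:.4f}\t"
            f"{summary.frac_nonself:.4f}\t{summary.call}\n"
        )
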