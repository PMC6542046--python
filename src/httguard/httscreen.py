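"""Reciprocal best-hit screening for candidate horizontal transposon
transfers.

Each element of a TE library is searched against each genome; hits of at
least 100 bp alignment length (E < 1e-10) are extracted, de-duplicated by
exact coordinates, and searched back against the full library. A genomic
locus counts only if its best reciprocal hit is the originating element,
guarding against cross-family misassignment. A (element, species) pair is
nominated when at least ``min_hits`` loci survive — a small floor that
suppresses spurious single-hit candidates.

A second, read-level screen searches translated reads against an element
ORF (used in the original study to ask whether close relatives of the
recipient carry the element at all).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .alignkit import (
    NUCLEOTIDE_SCHEME,
    PROTEIN_SCHEME,
    ScoringScheme,
    SearchDatabase,
    SearchHit,
    revcomp,
    search,
    translated_search,
)
from .io_formats import SeqRecord


@dataclass
class CandidateReport:
    rte_name: str
    species: str
    n_reciprocal_hits: int
    hits: list[SearchHit]
    passes: bool


def screen(
    rte_library: Sequence[SeqRecord],
    genomes: Sequence[SeqRecord],
    evalue: float = 1e-10,
    min_len: int = 100,
    min_hits: int = 10,
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> list[CandidateReport]:
    """Reciprocal screen of every library element against every genome.

    Genome records must carry ``species_tag``. Reports are emitted per
    (element, species) with >=1 surviving locus, sorted by element then
    species; ``passes`` marks reports with >= ``min_hits`` loci.
    """
    if not rte_library or not genomes:
        return []
    for g in genomes:
        if not g.species_tag:
            raise ValueError(f"genome {g.id!r} lacks a species_tag")
    genome_db = SearchDatabase(genomes, label="genomes")
    library_db = SearchDatabase(rte_library, label="rte_library")
    species_of = {g.id: g.species_tag for g in genomes}
    seq_of = {g.id: g.residues for g in genomes}

    reports: dict[tuple[str, str], list[SearchHit]] = {}
    for rte in rte_library:
        hits = search(rte, genome_db, scheme, evalue)
        seen_loci: set[tuple[str, int, int, str]] = set()
        for h in hits:
            if h.aligned_columns < min_len:
                continue
            locus = (h.subject_id, h.s_span.start, h.s_span.end, h.strand)
            if locus in seen_loci:  # duplicate extracted coordinates
                continue
            seen_loci.add(locus)
            extracted = seq_of[h.subject_id][h.s_span.start : h.s_span.end]
            if h.strand == "-":
                extracted = revcomp(extracted)
            back = search(
                SeqRecord(id="locus", residues=extracted),
                library_db, scheme, evalue,
            )
            if not back or back[0].subject_id != rte.id:
                continue  # reciprocal best hit is a different element
            reports.setdefault((rte.id, species_of[h.subject_id]), []).append(h)

    out = [
        CandidateReport(
            rte_name=rte_name,
            species=species,
            n_reciprocal_hits=len(hits),
            hits=hits,
            passes=len(hits) >= min_hits,
        )
        for (rte_name, species), hits in reports.items()
    ]
    out.sort(key=lambda r: (r.rte_name, r.species))
    return out


def screen_reads_translated(
    reads: Sequence[SeqRecord],
    rte_orf_protein: SeqRecord,
    evalue: float = 1e-10,
    min_identity: float = 75.0,
    scheme: ScoringScheme = PROTEIN_SCHEME,
) -> list[SearchHit]:
    """Translated read-level screen: hits to the element ORF passing both
    the E-value cutoff and a strict identity floor (identity > threshold)."""
    protein_db = SearchDatabase([rte_orf_protein], label="rte_orf")
    out: list[SearchHit] = []
    for read in reads:
        for h in translated_search(read, protein_db, scheme, evalue):
            if h.identity_pct > min_identity:
                out.append(h)
    return out


def write_report_tsv(reports: Sequence[CandidateReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rte\tspecies\tn_hits\tpass\n")
        for r in reports:
            fh.write(
                f"{r.rte_name}\t{r.species}\t{r.n_reciprocal_hits}\t"
                f"{int(r.passes)}\n"
            )
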