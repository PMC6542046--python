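"""Synthetic genomes, TE families and read sets with per-read truth labels.

The generator emulates the data regime of a host-parasite HTT study: a
recipient ("host-like") genome and a donor ("parasite-like") genome, a
single retroelement family carrying a long ORF, Illumina-style read pairs
and long reads, and three scenarios:

* ``HTT`` — the family is present in both genomes; the recipient's copies
  descend from a donor-lineage copy (a recent transfer); reads come only
  from the recipient.
* ``contamination`` — the family is present only in the donor; a fraction
  of the recipient's read set is replaced by donor-derived reads.
* ``negative`` — no TE anywhere; selection should pick essentially nothing.

Sequence evolution is a K2P substitution process: ``divergence`` is the
K2P evolutionary distance, and per-site change probabilities are the K2P
transition-matrix closed forms at that distance, so divergence estimates
made downstream are directly comparable to the generating parameter.
All randomness flows through one numpy Generator; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from Bio.Seq import Seq

from .alignkit import revcomp
from .io_formats import (
    Interval,
    ReadPair,
    SeqRecord,
    write_fasta,
    write_fastq,
    write_samlite,
)

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}
# transitions: A<->G, C<->T
_TS = np.array([2, 3, 0, 1])
# the two transversion targets per base
_TV = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic data set."""

    seed: int = 1
    scenario: str = "HTT"  # HTT | contamination | negative
    te_length: int = 3000
    n_copies_donor: int = 30
    n_copies_recipient: int = 30
    copy_divergence: float = 0.10
    kappa: float = 2.0
    indel_rate: float = 0.0005
    genome_length: int = 100_000
    background_divergence: float = 0.20
    read_length: int = 150
    insert_mean: int = 500
    insert_sd: int = 50
    paired_coverage: float = 20.0
    long_read_mean: int = 8000
    long_read_coverage: float = 5.0
    error_rate: float = 0.005
    contamination_fraction: float = 0.05
    transfer_divergence: float = 0.03  # donor-lineage copy -> recipient founder

    def __post_init__(self) -> None:
        if self.scenario not in ("HTT", "contamination", "negative"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("copy_divergence", "indel_rate", "background_divergence",
                     "error_rate", "contamination_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("te_length", "genome_length", "read_length",
                     "insert_mean", "long_read_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedCopy:
    copy_id: str
    interval: Interval
    true_divergence: float  # realized substitution fraction vs family ancestor


@dataclass
class TruthLabels:
    """Per-read provenance: origin genome and TE overlap."""

    origin: dict[str, str] = field(default_factory=dict)
    te_overlap: dict[str, bool] = field(default_factory=dict)
    planted: list[PlantedCopy] = field(default_factory=list)


@dataclass
class Placement:
    seq_id: str
    start: int
    end: int
    is_reverse: bool


@dataclass
class ScenarioData:
    config: ScenarioConfig
    te_ancestor: SeqRecord
    rte_orf_protein: SeqRecord
    recipient_genome: SeqRecord
    donor_genome: SeqRecord
    assembly: list[SeqRecord]
    self_records: list[SeqRecord]
    nonself_records: list[SeqRecord]
    pairs: list[ReadPair]
    long_reads: list[SeqRecord]
    mappings: dict[str, tuple[Optional[Placement], Optional[Placement]]]
    truth: TruthLabels


# ---------------------------------------------------------------------------
# Mutation machinery


def k2p_change_probs(divergence: float, kappa: float) -> tuple[float, float]:
    """Expected transition (p) and transversion (q) proportions after a K2P
    process of total distance ``divergence`` with ts/tv rate ratio kappa."""
    bt = divergence / (kappa + 2.0)
    at = kappa * bt
    e4b = math.exp(-4.0 * bt)
    e2ab = math.exp(-2.0 * (at + bt))
    q = 0.5 * (1.0 - e4b)
    p = 0.25 + 0.25 * e4b - 0.5 * e2ab
    return p, q


def mutate_sequence(
    seq: str,
    divergence: float,
    kappa: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Evolve ``seq`` by a K2P substitution process plus simple indels.

    Returns (mutated sequence, realized substitution fraction). Indels
    (insert or delete 1-5 bp) happen at ``indel_rate`` per site after
    substitution.
    """
    idx = np.array([_IDX.get(b, 0) for b in seq], dtype=np.int64)
    n = len(idx)
    if n == 0:
        return "", 0.0
    p, q = k2p_change_probs(divergence, kappa)
    u = rng.random(n)
    tv_choice = rng.integers(0, 2, n)
    new = np.where(
        u < p, _TS[idx], np.where(u < p + q, _TV[idx, tv_choice], idx)
    )
    realized = float((new != idx).sum()) / n
    out = "".join(_BASES[i] for i in new)
    if indel_rate > 0:
        hit = np.nonzero(rng.random(n) < indel_rate)[0]
        if len(hit) > 0:
            pieces: list[str] = []
            prev = 0
            for pos in hit:
                is_ins = rng.random() < 0.5
                length = int(rng.integers(1, 6))
                pieces.append(out[prev:pos])
                if is_ins:
                    ins = "".join(_BASES[i] for i in rng.integers(0, 4, length))
                    pieces.append(out[pos] + ins)
                    prev = pos + 1
                else:
                    prev = min(n, pos + length)
            pieces.append(out[prev:])
            out = "".join(pieces)
    return out, realized


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def make_te_ancestor(length: int, rng: np.random.Generator,
                     name: str = "RTE_syn") -> SeqRecord:
    """A TE family ancestor that is one long ORF (ATG ... stop), so both
    nucleotide and translated selection modes can find it."""
    n_codons = max(3, length // 3)
    body = [_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons - 2)]
    seq = "ATG" + "".join(body) + "TAA"
    return SeqRecord(id=name, residues=seq)


def orf_protein(te: SeqRecord) -> SeqRecord:
    pep = str(Seq(te.residues[: 3 * (len(te.residues) // 3)]).translate()).rstrip("*")
    return SeqRecord(id=f"{te.id}_orf", residues=pep)


def evolve_te_family(
    ancestor: SeqRecord,
    n: int,
    divergence: float,
    kappa: float,
    indel_rate: float,
    rng: np.random.Generator,
    prefix: str = "copy",
) -> tuple[list[SeqRecord], list[float]]:
    """Generate ``n`` independent copies at K2P distance ``divergence`` from
    the ancestor; realized per-copy substitution fractions are returned."""
    copies: list[SeqRecord] = []
    realized: list[float] = []
    for i in range(n):
        seq, r = mutate_sequence(
            ancestor.residues, divergence, kappa, indel_rate, rng
        )
        copies.append(SeqRecord(id=f"{prefix}_{i:03d}", residues=seq))
        realized.append(r)
    return copies, realized


def insert_copies(
    background: str,
    copies: list[SeqRecord],
    realized: list[float],
    rng: np.random.Generator,
    seq_id: str,
) -> tuple[SeqRecord, list[PlantedCopy]]:
    """Plant copies at uniform positions (random strand); returns the genome
    and the registry of planted locations in final coordinates."""
    positions = sorted(int(x) for x in rng.integers(0, len(background) + 1, len(copies)))
    strands = ["+" if rng.random() < 0.5 else "-" for _ in copies]
    pieces: list[str] = []
    registry: list[PlantedCopy] = []
    prev = 0
    offset = 0
    for pos, copy, strand, true_div in zip(positions, copies, strands, realized):
        pieces.append(background[prev:pos])
        start = pos + offset
        seq = copy.residues if strand == "+" else revcomp(copy.residues)
        pieces.append(seq)
        registry.append(
            PlantedCopy(
                copy_id=copy.id,
                interval=Interval(seq_id, start, start + len(seq), strand),
                true_divergence=true_div,
            )
        )
        offset += len(seq)
        prev = pos
    pieces.append(background[prev:])
    return SeqRecord(id=seq_id, residues="".join(pieces)), registry


# ---------------------------------------------------------------------------
# Read simulation


def _apply_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Substitution errors at ``error_rate``; qualities Q40 everywhere except
    Q11 at error positions (so quality masking can find them)."""
    chars = list(seq)
    quals = [40] * len(chars)
    if error_rate > 0:
        hit = np.nonzero(rng.random(len(chars)) < error_rate)[0]
        for pos in hit:
            old = chars[pos]
            choices = [b for b in _BASES if b != old]
            chars[pos] = choices[int(rng.integers(0, 3))]
            quals[pos] = 11
    return "".join(chars), quals


def simulate_paired_reads(
    genome: SeqRecord,
    coverage: float,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    id_prefix: str = "pair",
) -> tuple[list[ReadPair], dict[str, tuple[Placement, Placement]]]:
    """FR read pairs with Normal insert sizes (truncated at 2x read length)
    sampled uniformly along the genome."""
    rl = cfg.read_length
    glen = len(genome.residues)
    min_insert = 2 * rl
    if glen < min_insert:
        raise ValueError(f"genome {genome.id!r} shorter than one insert")
    n_pairs = int(round(coverage * glen / (2 * rl)))
    pairs: list[ReadPair] = []
    placements: dict[str, tuple[Placement, Placement]] = {}
    for i in range(n_pairs):
        insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = max(min_insert, min(insert, glen))
        start = int(rng.integers(0, glen - insert + 1))
        frag = genome.residues[start : start + insert]
        s1, q1 = _apply_errors(frag[:rl], cfg.error_rate, rng)
        s2, q2 = _apply_errors(revcomp(frag[-rl:]), cfg.error_rate, rng)
        pid = f"{id_prefix}_{i:06d}"
        pairs.append(
            ReadPair(
                mate1=SeqRecord(id=f"{pid}/1", residues=s1, qualities=q1),
                mate2=SeqRecord(id=f"{pid}/2", residues=s2, qualities=q2),
                pair_id=pid,
            )
        )
        placements[pid] = (
            Placement(genome.id, start, start + rl, False),
            Placement(genome.id, start + insert - rl, start + insert, True),
        )
    return pairs, placements


def simulate_long_reads(
    genome: SeqRecord,
    coverage: float,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    id_prefix: str = "long",
) -> tuple[list[SeqRecord], dict[str, Placement]]:
    """Long reads with Exponential lengths (mean ``long_read_mean``),
    uniform starts, random strand."""
    glen = len(genome.residues)
    if glen < 200:
        raise ValueError("genome too short for long reads")
    n_reads = int(round(coverage * glen / cfg.long_read_mean))
    reads: list[SeqRecord] = []
    placements: dict[str, Placement] = {}
    for i in range(n_reads):
        length = int(round(rng.exponential(cfg.long_read_mean)))
        length = max(200, min(length, glen))
        start = int(rng.integers(0, glen - length + 1))
        seq = genome.residues[start : start + length]
        is_rev = bool(rng.random() < 0.5)
        if is_rev:
            seq = revcomp(seq)
        seq, quals = _apply_errors(seq, cfg.error_rate, rng)
        rid = f"{id_prefix}_{i:06d}"
        reads.append(SeqRecord(id=rid, residues=seq, qualities=quals))
        placements[rid] = Placement(genome.id, start, start + length, is_rev)
    return reads, placements


# ---------------------------------------------------------------------------
# Scenario assembly


def _overlaps_te(placement: Placement, registry: list[PlantedCopy]) -> bool:
    for pc in registry:
        iv = pc.interval
        if (
            placement.seq_id == iv.seq_id
            and placement.start < iv.end
            and iv.start < placement.end
        ):
            return True
    return False


def build_scenario(cfg: ScenarioConfig) -> ScenarioData:
    """Generate the full data set for one scenario (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = make_te_ancestor(cfg.te_length, rng)
    protein = orf_protein(ancestor)

    # lineage founders: donor copies descend from the donor founder; in the
    # HTT scenario the recipient founder is a recent offshoot of the donor's
    donor_founder_seq, _ = mutate_sequence(
        ancestor.residues, 0.05, cfg.kappa, cfg.indel_rate, rng
    )
    donor_founder = SeqRecord(id=f"{ancestor.id}_donor", residues=donor_founder_seq)
    recipient_founder_seq, _ = mutate_sequence(
        donor_founder_seq, cfg.transfer_divergence, cfg.kappa, cfg.indel_rate, rng
    )
    recipient_founder = SeqRecord(
        id=f"{ancestor.id}_recipient", residues=recipient_founder_seq
    )

    recipient_bg = random_genome(cfg.genome_length, rng)
    donor_bg = random_genome(cfg.genome_length, rng)

    truth = TruthLabels()

    # donor genome
    if cfg.scenario in ("HTT", "contamination"):
        donor_copies, donor_real = evolve_te_family(
            donor_founder, cfg.n_copies_donor, cfg.copy_divergence,
            cfg.kappa, cfg.indel_rate, rng, prefix="donor_copy",
        )
        donor_genome, donor_registry = insert_copies(
            donor_bg, donor_copies, donor_real, rng, "donor_chr1"
        )
    else:
        donor_genome, donor_registry = SeqRecord(id="donor_chr1", residues=donor_bg), []

    # recipient genome
    if cfg.scenario == "HTT":
        rec_copies, rec_real = evolve_te_family(
            recipient_founder, cfg.n_copies_recipient, cfg.copy_divergence,
            cfg.kappa, cfg.indel_rate, rng, prefix="recipient_copy",
        )
        recipient_genome, rec_registry = insert_copies(
            recipient_bg, rec_copies, rec_real, rng, "recipient_chr1"
        )
    else:
        recipient_genome, rec_registry = (
            SeqRecord(id="recipient_chr1", residues=recipient_bg),
            [],
        )
    truth.planted = rec_registry + donor_registry

    # databases: sister taxa derived from each background, plus the actual
    # genomes (real databases contain them; classify discards own-species hits)
    def sister(bg: str, name: str, tag: str) -> SeqRecord:
        seq, _ = mutate_sequence(bg, cfg.background_divergence, cfg.kappa,
                                 cfg.indel_rate, rng)
        return SeqRecord(id=name, residues=seq, species_tag=tag)

    self_records = [
        SeqRecord(id=recipient_genome.id, residues=recipient_genome.residues,
                  species_tag="recipient"),
        sister(recipient_bg, "recipient_sister1_chr1", "recipient_sister1"),
        sister(recipient_bg, "recipient_sister2_chr1", "recipient_sister2"),
    ]
    nonself_records = [
        SeqRecord(id=donor_genome.id, residues=donor_genome.residues,
                  species_tag="donor"),
        sister(donor_bg, "donor_sister1_chr1", "donor_sister1"),
    ]

    # reads
    pairs: list[ReadPair] = []
    mappings: dict[str, tuple[Optional[Placement], Optional[Placement]]] = {}
    rec_pairs, rec_place = simulate_paired_reads(
        recipient_genome, cfg.paired_coverage, cfg, rng, id_prefix="rec"
    )
    pairs.extend(rec_pairs)
    for pid, (p1, p2) in rec_place.items():
        mappings[pid] = (p1, p2)
        truth.origin[pid] = "recipient_genome"
        truth.te_overlap[pid] = _overlaps_te(p1, rec_registry) or _overlaps_te(
            p2, rec_registry
        )

    long_reads: list[SeqRecord] = []
    rec_long, rec_long_place = simulate_long_reads(
        recipient_genome, cfg.long_read_coverage, cfg, rng, id_prefix="rec_long"
    )
    long_reads.extend(rec_long)
    for rid, pl in rec_long_place.items():
        truth.origin[rid] = "recipient_genome"
        truth.te_overlap[rid] = _overlaps_te(pl, rec_registry)

    assembly = [recipient_genome]
    if cfg.scenario == "contamination":
        # contaminant reads, and the contaminant contig that co-assembles
        frac = cfg.contamination_fraction
        cont_cov_pairs = cfg.paired_coverage * frac / (1 - frac)
        cont_pairs, cont_place = simulate_paired_reads(
            donor_genome, cont_cov_pairs, cfg, rng, id_prefix="cont"
        )
        pairs.extend(cont_pairs)
        for pid, (p1, p2) in cont_place.items():
            mappings[pid] = (p1, p2)
            truth.origin[pid] = "donor_genome"
            truth.te_overlap[pid] = _overlaps_te(p1, donor_registry) or _overlaps_te(
                p2, donor_registry
            )
        cont_cov_long = cfg.long_read_coverage * frac / (1 - frac)
        cont_long, cont_long_place = simulate_long_reads(
            donor_genome, cont_cov_long, cfg, rng, id_prefix="cont_long"
        )
        long_reads.extend(cont_long)
        for rid, pl in cont_long_place.items():
            truth.origin[rid] = "donor_genome"
            truth.te_overlap[rid] = _overlaps_te(pl, donor_registry)
        assembly = [recipient_genome,
                    SeqRecord(id=donor_genome.id, residues=donor_genome.residues)]

    return ScenarioData(
        config=cfg,
        te_ancestor=ancestor,
        rte_orf_protein=protein,
        recipient_genome=recipient_genome,
        donor_genome=donor_genome,
        assembly=assembly,
        self_records=self_records,
        nonself_records=nonself_records,
        pairs=pairs,
        long_reads=long_reads,
        mappings=mappings,
        truth=truth,
    )


def simulate_lineage_radiation(
    seed: int,
    n_copies: int = 10,
    te_length: int = 1000,
    split_divergence: float = 0.08,
    transfer_divergence: float = 0.03,
    copy_divergence: float = 0.05,
    kappa: float = 2.0,
    indel_rate: float = 0.0005,
) -> tuple[dict[str, list[SeqRecord]], SeqRecord, str]:
    """Four donor-taxon lineages ((L1,L2),(L3,L4)) plus a recipient whose
    family was seeded from L1 (the transfer donor). Returns per-lineage copy
    sets, the family ancestor (usable as consensus seed), and the donor
    lineage name."""
    rng = np.random.default_rng(seed)
    root = make_te_ancestor(te_length, rng)

    def offshoot(parent: str, d: float) -> str:
        seq, _ = mutate_sequence(parent, d, kappa, indel_rate, rng)
        return seq

    clade_ab = offshoot(root.residues, split_divergence)
    clade_cd = offshoot(root.residues, split_divergence)
    founders = {
        "L1": offshoot(clade_ab, split_divergence),
        "L2": offshoot(clade_ab, split_divergence),
        "L3": offshoot(clade_cd, split_divergence),
        "L4": offshoot(clade_cd, split_divergence),
    }
    founders["recipient"] = offshoot(founders["L1"], transfer_divergence)
    families: dict[str, list[SeqRecord]] = {}
    for name, founder in founders.items():
        copies, _ = evolve_te_family(
            SeqRecord(id=name, residues=founder), n_copies, copy_divergence,
            kappa, indel_rate, rng, prefix=f"{name}_copy",
        )
        families[name] = copies
    return families, root, "L1"


# ---------------------------------------------------------------------------
# Serialization


def write_scenario(data: ScenarioData, outdir: str | Path) -> None:
    """Write FASTA/FASTQ/SAM + truth TSV + config JSON for one scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([data.te_ancestor], outdir / "rte_consensus.fa")
    write_fasta([data.rte_orf_protein], outdir / "rte_orf.faa")
    write_fasta(data.assembly, outdir / "assembly.fa")

    def tagged(records: list[SeqRecord]) -> list[SeqRecord]:
        # species|contig headers, the convention the CLI parses tags from
        return [
            SeqRecord(id=f"{r.species_tag}|{r.id}", residues=r.residues)
            for r in records
        ]

    write_fasta(tagged(data.self_records), outdir / "self_db.fa")
    write_fasta(tagged(data.nonself_records), outdir / "nonself_db.fa")
    write_fastq([p.mate1 for p in data.pairs], outdir / "reads_1.fq")
    write_fastq([p.mate2 for p in data.pairs], outdir / "reads_2.fq")
    write_fastq(data.long_reads, outdir / "long_reads.fq")

    refs = {rec.id: len(rec.residues) for rec in data.assembly}
    ref_ids = set(refs)
    sam_rows = []
    for pair in data.pairs:
        p1, p2 = data.mappings.get(pair.pair_id, (None, None))
        for mate, pl, is_r1 in ((pair.mate1, p1, True), (pair.mate2, p2, False)):
            if pl is not None and pl.seq_id in ref_ids:
                sam_rows.append((mate, pl.seq_id, pl.start, is_r1, pl.is_reverse))
            else:
                sam_rows.append((mate, None, None, is_r1, False))
    write_samlite(sam_rows, refs, outdir / "pairs.sam")

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("read_id\torigin\tte_overlap\n")
        for rid in sorted(data.truth.origin):
            fh.write(
                f"{rid}\t{data.truth.origin[rid]}\t"
                f"{int(data.truth.te_overlap[rid])}\n"
            )
    with open(outdir / "planted_copies.tsv", "w") as fh:
        fh.write("copy_id\tseq_id\tstart\tend\tstrand\ttrue_divergence\n")
        for pc in data.truth.planted:
            iv = pc.interval
            fh.write(
                f"{pc.copy_id}\t{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{pc.true_divergence:.6f}\n"
            )
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(data.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
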