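"""Per-species TE consensus construction and evolutionary analytics.

Covers: reference-anchored star-alignment consensus (majority rule),
pairwise consensus identity matrices, defragmentation of RepeatMasker-style
fragment annotations into copies, top-copy selection, ORF finding, and a
neighbor-joining tree with midpoint rooting for the transfer-topology test.
Tree inference delegates to scikit-bio's NJ; the distances feeding it are
CpG-excluded K2P so distance semantics match the landscape module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from . import kimura
from .alignkit import (
    NUCLEOTIDE_SCHEME,
    ScoringScheme,
    needleman_wunsch,
    revcomp,
    six_frame_translate,
    smith_waterman,
)
from .io_formats import Interval, SeqRecord
from .repeatmask import RepeatAnnotation


@dataclass
class ConsensusModel:
    species: str
    consensus: SeqRecord
    coverage: list[int]
    n_input_fragments: int


@dataclass
class CopyRecord:
    """A defragmented TE copy: collinear same-family fragments merged."""

    species: str
    fragments: list[RepeatAnnotation]
    genomic_span: Interval
    strand: str
    merged_length: int
    mean_divergence_pct: float


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # percent identity, symmetric, diagonal 100

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")


# ---------------------------------------------------------------------------
# Consensus


def build_consensus(
    fragments: Sequence[SeqRecord],
    seed: SeqRecord,
    min_coverage: int = 3,
    species: str = "",
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> ConsensusModel:
    """Majority-rule consensus over a star alignment anchored on ``seed``.

    Each fragment is locally aligned to the seed; per seed column the
    consensus base is the plurality among aligned fragment bases where
    coverage >= ``min_coverage``, otherwise the seed base is retained.
    Insertions relative to the seed are discarded. Fragments are placed on
    the strand that aligns better.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    L = len(seed.residues)
    counts: list[Counter] = [Counter() for _ in range(L)]
    for frag in fragments:
        fwd = smith_waterman(frag.residues, seed.residues, scheme)
        rev = smith_waterman(revcomp(frag.residues), seed.residues, scheme)
        aln = fwd if fwd.score >= rev.score else rev
        if aln.n_columns == 0:
            continue
        spos = aln.b_span[0]
        for fb, sb in zip(aln.aligned_a, aln.aligned_b):
            if sb == "-":
                continue  # insertion in fragment: no seed column
            if fb != "-" and fb in "ACGT":
                counts[spos][fb] += 1
            spos += 1
    consensus_chars: list[str] = []
    coverage: list[int] = []
    for i, ctr in enumerate(counts):
        cov = sum(ctr.values())
        coverage.append(cov)
        if cov >= min_coverage:
            # plurality; deterministic tie-break on base order
            best = max(sorted(ctr), key=lambda b: ctr[b])
            consensus_chars.append(best)
        else:
            consensus_chars.append(seed.residues[i])
    cons_id = f"{species or seed.id}_consensus"
    return ConsensusModel(
        species=species or seed.id,
        consensus=SeqRecord(id=cons_id, residues="".join(consensus_chars),
                            species_tag=species or None),
        coverage=coverage,
        n_input_fragments=len(fragments),
    )


# ---------------------------------------------------------------------------
# Identity and distance matrices


def pairwise_identity(
    consensuses: Sequence[SeqRecord],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
) -> IdentityMatrix:
    """Percent identity from global alignment with free terminal gaps:
    matches over columns where at least one sequence has a base."""
    n = len(consensuses)
    labels = [c.id for c in consensuses]
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = needleman_wunsch(
                consensuses[i].residues, consensuses[j].residues, scheme,
                free_end_gaps=True,
            )
            ident = 100.0 * aln.n_matches / aln.n_columns if aln.n_columns else 0.0
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values)


def k2p_distance_matrix(
    consensuses: Sequence[SeqRecord],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
    exclude_cpg: bool = True,
) -> DistanceMatrix:
    """CpG-excluded K2P distances between consensus sequences.

    CpG columns of either sequence are excluded so the matrix is symmetric.
    Saturated pairs get a large finite placeholder (twice the largest
    defined distance) so NJ still runs.
    """
    n = len(consensuses)
    labels = [c.id for c in consensuses]
    values = np.zeros((n, n))
    saturated: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = needleman_wunsch(
                consensuses[i].residues, consensuses[j].residues, scheme,
                free_end_gaps=True,
            )
            p, q, _, _ = kimura.count_changes(
                aln.aligned_a, aln.aligned_b, exclude_cpg, cpg_in_either=True
            )
            try:
                d = kimura.k2p(p, q)
            except kimura.SaturationError:
                saturated.append((i, j))
                continue
            values[i, j] = values[j, i] = d
    if saturated:
        cap = 2.0 * values.max() if values.max() > 0 else 1.0
        for i, j in saturated:
            values[i, j] = values[j, i] = cap
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Defragmentation and copy selection


def defragment(
    annotations: Sequence[RepeatAnnotation],
    max_gap: int = 5000,
    collinearity_slack: int = 20,
    species: str = "",
) -> list[CopyRecord]:
    """Merge collinear same-family, same-strand fragments into copies.

    Fragments on one sequence merge when the genomic gap is <= ``max_gap``
    and their consensus coordinates progress collinearly (next fragment's
    consensus start >= previous consensus end - slack on the plus strand;
    mirrored on minus). Strict mode: a different-family annotation between
    two fragments breaks the chain.
    """
    anns = sorted(
        annotations, key=lambda a: (a.interval.seq_id, a.interval.start, a.interval.end)
    )
    copies: list[list[RepeatAnnotation]] = []
    open_chains: dict[tuple[str, str, str], int] = {}  # (seq,family,strand) -> copies idx
    for a in anns:
        key = (a.interval.seq_id, a.family, a.interval.strand)
        # strict mode: any annotation of another family closes chains it passes
        for other_key in list(open_chains):
            if other_key[0] == a.interval.seq_id and other_key[1] != a.family:
                idx = open_chains[other_key]
                last = copies[idx][-1]
                if last.interval.end <= a.interval.start:
                    del open_chains[other_key]
        idx = open_chains.get(key)
        mergeable = False
        if idx is not None:
            last = copies[idx][-1]
            gap = a.interval.start - last.interval.end
            if gap <= max_gap:
                if a.consensus_span is None or last.consensus_span is None:
                    mergeable = True
                elif a.interval.strand == "+":
                    mergeable = a.consensus_span[0] >= last.consensus_span[1] - collinearity_slack
                else:
                    mergeable = a.consensus_span[1] <= last.consensus_span[0] + collinearity_slack
        if mergeable:
            copies[idx].append(a)
        else:
            copies.append([a])
            open_chains[key] = len(copies) - 1
    out: list[CopyRecord] = []
    for frags in copies:
        total = sum(len(f) for f in frags)
        div = sum(f.divergence_pct * len(f) for f in frags) / total
        out.append(
            CopyRecord(
                species=species,
                fragments=frags,
                genomic_span=Interval(
                    frags[0].interval.seq_id,
                    frags[0].interval.start,
                    frags[-1].interval.end,
                    frags[0].interval.strand,
                ),
                strand=frags[0].interval.strand,
                merged_length=total,
                mean_divergence_pct=div,
            )
        )
    return out


def select_top_copies(copies: Sequence[CopyRecord], n: int = 100) -> list[CopyRecord]:
    """Stable sort by merged length (desc) then mean divergence (asc);
    return the first ``n`` (all if fewer)."""
    ranked = sorted(
        copies, key=lambda c: (-c.merged_length, c.mean_divergence_pct)
    )
    return ranked[:n]


# ---------------------------------------------------------------------------
# ORFs


@dataclass
class Orf:
    frame: int
    start: int  # forward-strand 0-based half-open nucleotide coords
    end: int
    peptide: str


def find_orfs(seq: SeqRecord | str, min_codons: int = 30) -> list[Orf]:
    """All stop-to-stop ORFs of >= ``min_codons`` codons in six frames
    (standard code); coordinates are on the forward strand."""
    s = seq.residues if isinstance(seq, SeqRecord) else str(seq)
    L = len(s)
    orfs: list[Orf] = []
    for frame, pep in six_frame_translate(s):
        off = abs(frame) - 1
        start_aa = 0
        for segment in pep.split("*"):
            if len(segment) >= min_codons:
                nt_start = off + 3 * start_aa
                nt_end = nt_start + 3 * len(segment)
                if frame > 0:
                    orfs.append(Orf(frame, nt_start, nt_end, segment))
                else:
                    orfs.append(Orf(frame, L - nt_end, L - nt_start, segment))
            start_aa += len(segment) + 1
    return orfs


def longest_orf(seq: SeqRecord | str, min_codons: int = 30) -> Optional[Orf]:
    """Longest ORF by peptide length; ties broken by frame order
    (+1,+2,+3,-1,-2,-3) then position."""
    frame_rank = {f: i for i, f in enumerate((1, 2, 3, -1, -2, -3))}
    orfs = find_orfs(seq, min_codons)
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-len(o.peptide), frame_rank[o.frame], o.start))


# ---------------------------------------------------------------------------
# Trees


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; negative branch lengths are clamped to zero."""
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 taxa")
    tree = nj(_SkbioDM(dm.values, ids=dm.labels))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    return tree.root_at_midpoint()


def topological_path_edges(tree: TreeNode, x: str, y: str) -> int:
    """Number of edges on the path between two leaves."""
    a, b = tree.find(x), tree.find(y)
    anc_a = [a] + list(a.ancestors())
    anc_b = [b] + list(b.ancestors())
    pos_a = {id(n): i for i, n in enumerate(anc_a)}
    for j, n in enumerate(anc_b):
        if id(n) in pos_a:
            return pos_a[id(n)] + j
    raise ValueError(f"{x!r} and {y!r} share no ancestor")


def is_cherry(tree: TreeNode, x: str, y: str) -> bool:
    """True when two leaves are joined by a single internal node (i.e. they
    are sisters on the unrooted tree)."""
    return topological_path_edges(tree, x, y) == 2


def star_score(tree: TreeNode) -> float:
    """Internal branch length over total branch length; 0 for a perfect
    star (all length on terminal branches)."""
    tips = list(tree.tips())
    if len(tips) < 4:
        raise ValueError("need at least 4 leaves")
    internal = 0.0
    total = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        total += length
        if not node.is_tip():
            internal += length
    if total == 0:
        return 0.0
    return internal / total
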