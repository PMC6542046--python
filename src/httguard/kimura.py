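"""Kimura 2-parameter divergence of TE copies from their consensus, with
CpG exclusion, and the length-weighted repeat landscape.

Methylated CpG dinucleotides hypermutate (C->T deamination), so counting
them inflates the apparent age of a copy; both positions of every CpG in
the ungapped consensus are therefore excluded from the counts by default.
K2P separates transition (p) and transversion (q) proportions and corrects
for multiple hits: K = -1/2 ln((1-2p-q) sqrt(1-2q)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

_NT = frozenset("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Observed p/q are beyond the domain of the K2P correction."""


@dataclass
class KimuraEstimate:
    copy_id: str
    p: float
    q: float
    k2p: Optional[float]  # None when saturated
    n_sites: int
    n_excluded_cpg: int
    copy_length: int

    @property
    def saturated(self) -> bool:
        return self.k2p is None

    @property
    def k2p_pct(self) -> Optional[float]:
        return None if self.k2p is None else 100.0 * self.k2p


def cpg_positions(ungapped_ref: str) -> set[int]:
    """Both positions of every CpG dinucleotide in the ungapped reference."""
    pos: set[int] = set()
    for i in range(len(ungapped_ref) - 1):
        if ungapped_ref[i] == "C" and ungapped_ref[i + 1] == "G":
            pos.add(i)
            pos.add(i + 1)
    return pos


def count_changes(
    ref_aligned: str,
    copy_aligned: str,
    exclude_cpg: bool = True,
    cpg_in_either: bool = False,
) -> tuple[float, float, int, int]:
    """Classify alignment columns into transitions/transversions.

    The reference (consensus) is the first sequence. Columns count only
    where both sequences carry A/C/G/T. With ``exclude_cpg``, CpG
    dinucleotide positions of the ungapped reference (and, if
    ``cpg_in_either``, of the other sequence too — used for symmetric
    consensus-vs-consensus distances) are excluded entirely.

    Returns (p, q, n_sites, n_excluded).
    """
    if len(ref_aligned) != len(copy_aligned):
        raise ValueError("aligned strings differ in length")
    excluded_cols: set[int] = set()
    if exclude_cpg:
        seqs = (ref_aligned, copy_aligned) if cpg_in_either else (ref_aligned,)
        for aligned in seqs:
            ungapped = aligned.replace("-", "")
            bad = cpg_positions(ungapped.upper())
            upos = -1
            for col, ch in enumerate(aligned):
                if ch != "-":
                    upos += 1
                    if upos in bad:
                        excluded_cols.add(col)
    n_sites = 0
    n_excluded = 0
    ts = tv = 0
    for col, (r, c) in enumerate(zip(ref_aligned.upper(), copy_aligned.upper())):
        if r not in _NT or c not in _NT:
            continue
        if col in excluded_cols:
            n_excluded += 1
            continue
        n_sites += 1
        if r == c:
            continue
        if (r, c) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n_sites == 0:
        raise ValueError("no informative sites")
    return ts / n_sites, tv / n_sites, n_sites, n_excluded


def k2p(p: float, q: float) -> float:
    """K = -1/2 ln((1-2p-q) sqrt(1-2q)); raises SaturationError outside the
    defined domain."""
    if p < 0 or q < 0 or p + q > 1:
        raise ValueError("p and q must be non-negative with p+q <= 1")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: p={p}, q={q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def estimate(
    copy_id: str,
    ref_aligned: str,
    copy_aligned: str,
    exclude_cpg: bool = True,
) -> KimuraEstimate:
    """K2P estimate for one copy-vs-consensus alignment; saturation is
    flagged rather than raised."""
    p, q, n_sites, n_excl = count_changes(ref_aligned, copy_aligned, exclude_cpg)
    try:
        k = k2p(p, q)
    except SaturationError:
        k = None
    return KimuraEstimate(
        copy_id=copy_id,
        p=p,
        q=q,
        k2p=k,
        n_sites=n_sites,
        n_excluded_cpg=n_excl,
        copy_length=len(copy_aligned.replace("-", "")),
    )


@dataclass
class Landscape:
    """Length-weighted age distribution of copies.

    ``bins`` maps a bin index (floor(k2p% / bin_width)) to the summed copy
    length in that bin; stats are on the percent scale. Proportion-scale
    stats are exposed alongside.
    """

    bin_width: float
    bins: dict[int, int]
    min_pct: float
    weighted_mean_pct: float
    max_pct: float

    @property
    def min(self) -> float:
        return self.min_pct / 100.0

    @property
    def weighted_mean(self) -> float:
        return self.weighted_mean_pct / 100.0

    @property
    def max(self) -> float:
        return self.max_pct / 100.0

    @property
    def total_length(self) -> int:
        return sum(self.bins.values())


def landscape(estimates: Iterable[KimuraEstimate], bin_width: float = 1.0) -> Landscape:
    """Bin each copy's length by its K2P distance (percent scale)."""
    usable = [e for e in estimates if not e.saturated]
    if not usable:
        raise ValueError("no unsaturated estimates to bin")
    bins: dict[int, int] = {}
    total_len = 0
    weighted = 0.0
    for e in usable:
        pct = e.k2p_pct
        bins[int(pct // bin_width)] = bins.get(int(pct // bin_width), 0) + e.copy_length
        total_len += e.copy_length
        weighted += pct * e.copy_length
    values = [e.k2p_pct for e in usable]
    return Landscape(
        bin_width=bin_width,
        bins=dict(sorted(bins.items())),
        min_pct=min(values),
        weighted_mean_pct=weighted / total_len,
        max_pct=max(values),
    )


def write_estimates_tsv(estimates: Iterable[KimuraEstimate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tp\tq\tk2p\tk2p_pct\tn_sites\tn_excluded_cpg\tcopy_length\n")
        for e in estimates:
            k = "NA" if e.saturated else f"{e.k2p:.6f}"
            kp = "NA" if e.saturated else f"{e.k2p_pct:.4f}"
            fh.write(
                f"{e.copy_id}\t{e.p:.6f}\t{e.q:.6f}\t{k}\t{kp}\t{e.n_sites}\t"
                f"{e.n_excluded_cpg}\t{e.copy_length}\n"
            )


def write_landscape_tsv(ls: Landscape, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width_pct={ls.bin_width}\n")
        fh.write(
            f"# min_pct={ls.min_pct:.4f} weighted_mean_pct="
            f"{ls.weighted_mean_pct:.4f} max_pct={ls.max_pct:.4f}\n"
        )
        fh.write("bin_lo_pct\tbin_hi_pct\tsummed_copy_length\n")
        for b, length in ls.bins.items():
            fh.write(f"{b * ls.bin_width:g}\t{(b + 1) * ls.bin_width:g}\t{length}\n")
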