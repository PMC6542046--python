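"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain-Python Gotoh
dynamic programming for affine-gap alignment scores, a dict-based codon
translator, and small enumeration helpers.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_global(a: str, b: str, match: int, mismatch: int,
                 gap_open: int, gap_extend: int) -> float:
    """Optimal global affine-gap score; a gap of length L costs
    open + L*extend; end gaps penalized."""
    n, m = len(a), len(b)
    go, ge = gap_open, gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go - ge, X[i - 1][j] - ge,
                          Y[i - 1][j] - go - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, Y[i][j - 1] - ge,
                          X[i][j - 1] - go - ge)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local(a: str, b: str, match: int, mismatch: int,
                gap_open: int, gap_extend: int) -> float:
    """Optimal local (Smith-Waterman) affine-gap score, floored at 0."""
    n, m = len(a), len(b)
    go, ge = gap_open, gap_extend
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                (X[i - 1][j - 1] + s) if X[i - 1][j - 1] > NEG else NEG,
                (Y[i - 1][j - 1] + s) if Y[i - 1][j - 1] > NEG else NEG,
            )
            X[i][j] = max(M[i - 1][j] - go - ge, X[i - 1][j] - ge,
                          Y[i - 1][j] - go - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, Y[i][j - 1] - ge,
                          X[i][j - 1] - go - ge)
            best = max(best, M[i][j])
    return best


_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    # standard genetic code, written out independently of Bio.Seq
    code = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
    return code


def translate_oracle(seq: str) -> str:
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    pep = []
    for i in range(0, len(seq) - 2, 3):
        pep.append(_CODON_TABLE.get(seq[i : i + 3].upper(), "X"))
    return "".join(pep)


def revcomp_oracle(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(c, "N") for c in reversed(seq.upper()))


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length covered by a set of (start, end) half-open intervals."""
    covered: set[int] = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return len(covered)


def orf_scan_oracle(seq: str, min_codons: int = 30) -> list[tuple[int, str]]:
    """All stop-to-stop peptides >= min_codons across 6 frames, as
    (frame, peptide), by direct scanning."""
    out = []
    for strand, s in ((1, seq), (-1, revcomp_oracle(seq))):
        for off in (0, 1, 2):
            pep = translate_oracle(s[off:])
            for seg in pep.split("*"):
                if len(seg) >= min_codons:
                    out.append((strand * (off + 1), seg))
    return out
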