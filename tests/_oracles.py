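"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as a *different code path* from the
package: plain-python dynamic programming and exhaustive window scans, so
that agreement with the package is evidence, not tautology.
"""

from __future__ import annotations

import itertools

NEG_INF = float("-inf")


def affine_global_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Gotoh affine-gap global alignment score (end gaps penalized).

    A gap of length k costs gap_open + k*gap_extend. ``score(x, y)`` gives
    the substitution score. Quadratic time, three explicit state matrices.
    """
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first residue of a gap
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue unmatched)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend, Iy[i - 1][j] - first)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend, Ix[i][j - 1] - first)
        Ix[i][0] = -(gap_open + i * gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def sliding_hamming_find(haystack: str, needle: str, max_mm: int, start: int = 0) -> int:
    """Leftmost approximate occurrence by exhaustive window comparison."""
    for i in range(start, len(haystack) - len(needle) + 1):
        if sum(x != y for x, y in zip(haystack[i : i + len(needle)], needle)) <= max_mm:
            return i
    return -1


REVCOMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


def iupac_match(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(b in IUPAC[s] for b, s in zip(window, pattern))


def scan_windows(seq: str, pattern: str, both_strands: bool) -> list[tuple[int, str]]:
    """Exhaustive per-window IUPAC scan, forward coordinates."""
    k = len(pattern)
    hits = [(i, "+") for i in range(len(seq) - k + 1) if iupac_match(seq[i : i + k], pattern)]
    if both_strands:
        r = rc(seq)
        hits += [(len(seq) - i - k, "-") for i in range(len(r) - k + 1) if iupac_match(r[i : i + k], pattern)]
    return sorted(hits)


def offtarget_scan(genome: dict[str, str], spacer: str, pam: str, max_mm: int):
    """Exhaustive per-window off-target enumeration.

    Yields (seqid, start, end, strand, protospacer, pam_seq, mismatches)
    with forward-strand half-open protospacer coordinates.
    """
    S, P = len(spacer), len(pam)
    out = []
    for seqid, seq in genome.items():
        for strand_seq, strand in ((seq, "+"), (rc(seq), "-")):
            L = len(strand_seq)
            for i in range(L - S - P + 1):
                proto = strand_seq[i : i + S]
                pam_seq = strand_seq[i + S : i + S + P]
                if not iupac_match(pam_seq, pam):
                    continue
                mm = sum(x != y for x, y in zip(proto, spacer))
                if mm <= max_mm:
                    if strand == "+":
                        out.append((seqid, i, i + S, "+", proto, pam_seq, mm))
                    else:
                        out.append((seqid, L - i - S, L - i, "-", proto, pam_seq, mm))
    return sorted(out, key=lambda h: (h[6], h[0], h[1], h[3]))


def enumerate_pattern_density(pattern: str, both_strands: bool) -> float:
    """PAM density by exhaustive enumeration of all 4^k k-mers."""
    k = len(pattern)
    n_match = sum(iupac_match("".join(w), pattern) for w in itertools.product("ACGT", repeat=k))
    d = n_match / 4**k
    return 2 * d if both_strands else d


def minimal_iupac_consensus(freqs: dict[str, float], strong: float, pair: float) -> str:
    """Exhaustive minimal-subset consensus call for one position."""
    inv = {frozenset(v): k for k, v in IUPAC.items()}
    best = max(freqs, key=freqs.get)
    if freqs[best] >= strong:
        return best
    for size in (2, 3):
        subsets = [(sum(freqs[b] for b in c), frozenset(c)) for c in itertools.combinations("ACGT", size)]
        total, bases = max(subsets, key=lambda t: t[0])
        if total >= pair:
            return inv[bases]
    return "N"
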