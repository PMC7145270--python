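"""Small shared sequence helpers: alphabets, IUPAC codes, reverse complement,
Hamming distance and approximate substring search.

These are deliberately tiny and dependency-free; every module in the package
uses them, so they live in one private place.
"""

from __future__ import annotations

DNA = "ACGT"
DNA_SET = frozenset(DNA)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of concrete bases each accepts.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse lookup: frozenset of bases -> minimal IUPAC symbol.
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming() requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def find_approx(haystack: str, needle: str, max_mismatches: int, start: int = 0) -> int:
    """Leftmost index >= *start* where *needle* matches *haystack* with at most
    *max_mismatches* substitutions, or -1 if absent.

    Plain sliding-window scan; reads here are short (~100 bp) so this is never
    a bottleneck.
    """
    n, m = len(haystack), len(needle)
    if m == 0:
        return start
    for i in range(start, n - m + 1):
        mm = 0
        for x, y in zip(haystack[i : i + m], needle):
            if x != y:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return i
    return -1


def is_dna(seq: str) -> bool:
    return set(seq) <= DNA_SET


def validate_iupac(pattern: str) -> None:
    bad = set(pattern) - set(IUPAC_TO_BASES)
    if bad or not pattern:
        raise ValueError(f"invalid IUPAC pattern {pattern!r} (bad symbols: {sorted(bad)})")
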