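"""Ortholog protein arithmetic for Cas9 engineering.

Covers the desk computations behind ortholog engineering campaigns:
translating an ORF, globally aligning two orthologs with affine gap costs,
reading percent identity off the alignment, mapping residue numbers across
orthologs (how SaCas9's KKH positions E782/N968/R1015 transfer to another
ortholog), applying point mutations written in standard one-letter
nomenclature (e.g. the RuvC-inactivating D15A that turns a nuclease into a
nickase), and splicing a PAM-interacting domain (PID) from one ortholog
into another to build a chimera.

Residue numbering is 1-based everywhere, matching mutation nomenclature.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._seq import AMINO_ACIDS

_PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: One (arbitrary but fixed) codon per amino acid, for reverse translation.
_CODON_FOR: dict[str, str] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODON_FOR.setdefault(_aa, _codon)


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence, optionally with its source ORF."""

    name: str
    sequence: str
    orf: Optional[str] = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _PROTEIN_ALPHABET
        if not self.sequence or bad:
            raise ValueError(f"{self.name}: invalid protein sequence (bad residues: {sorted(bad)})")
        if self.orf is not None:
            if len(self.orf) != 3 * len(self.sequence) + 3:
                raise ValueError(f"{self.name}: ORF length must be 3*residues + 3 (stop included)")
            if str(Seq(self.orf[:-3]).translate()) != self.sequence:
                raise ValueError(f"{self.name}: ORF does not translate to the stated sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at 1-based *position*."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(f"{self.name}: position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


def translate_orf(dna: str, name: str = "protein") -> ProteinRecord:
    """Translate an ORF (standard code, single terminal stop required).

    Internal stop codons and lengths not divisible by 3 are errors.
    """
    dna = dna.upper().replace("U", "T")
    if len(dna) % 3 != 0:
        raise ValueError(f"{name}: ORF length {len(dna)} is not divisible by 3")
    protein = str(Seq(dna).translate())
    if not protein.endswith("*"):
        raise ValueError(f"{name}: ORF lacks a terminal stop codon")
    protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"{name}: internal stop codon at residue {protein.index('*') + 1}")
    return ProteinRecord(name=name, sequence=protein, orf=dna)


def reverse_translate(protein: ProteinRecord | str, stop: str = "TAA") -> str:
    """A DNA ORF (one fixed codon per residue + stop) translating back to
    *protein*; translate_orf(reverse_translate(p)) round-trips."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    return "".join(_CODON_FOR[aa] for aa in seq) + stop


# ---------------------------------------------------------------------------
# global alignment


@dataclass
class GlobalAlignment:
    """Affine-gap global alignment of two proteins with a residue map.

    ``aligned_a``/``aligned_b`` are the gapped rows; ``pairs`` lists 1-based
    (i, j) for every residue-residue column, strictly increasing on both
    sides.
    """

    a: ProteinRecord
    b: ProteinRecord
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    pairs: list[tuple[int, int]]
    _a_to_b: dict[int, int] = field(init=False, repr=False)
    _b_to_a: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        assert self.aligned_a.replace("-", "") == self.a.sequence
        assert self.aligned_b.replace("-", "") == self.b.sequence
        self._a_to_b = dict(self.pairs)
        self._b_to_a = {j: i for i, j in self.pairs}

    def format(self, width: int = 60) -> str:
        """Readable two-row alignment with a match line."""
        lines = []
        for off in range(0, len(self.aligned_a), width):
            sa = self.aligned_a[off : off + width]
            sb = self.aligned_b[off : off + width]
            mid = "".join("|" if x == y and x != "-" else " " for x, y in zip(sa, sb))
            lines += [f"{self.a.name[:12]:>12} {sa}", f"{'':>12} {mid}", f"{self.b.name[:12]:>12} {sb}", ""]
        return "\n".join(lines)


@functools.lru_cache(maxsize=4)
def _protein_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # EMBOSS-style costs: a gap of length k costs gap_open + k*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    identity_denominator: Literal["alignment", "shorter"] = "alignment",
) -> GlobalAlignment:
    """Optimal affine-gap global alignment (Needleman-Wunsch, end gaps
    penalized) with BLOSUM62 scores by default.

    A gap of length k costs ``gap_open + k*gap_extend``. Identity is
    identical columns over alignment length (gap columns included), or over
    the shorter sequence with ``identity_denominator="shorter"``. Note that
    percent identity is convention-dependent at the level of a point or two;
    both conventions are exposed.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("both sequences must be nonempty")
    aln = _protein_aligner(matrix, gap_open, gap_extend).align(a.sequence, b.sequence)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    identical = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    if identity_denominator == "alignment":
        denom = len(aligned_a)
    elif identity_denominator == "shorter":
        denom = min(len(a.sequence), len(b.sequence))
    else:
        raise ValueError(f"unknown identity_denominator {identity_denominator!r}")
    pairs = []
    i = j = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            pairs.append((i + 1, j + 1))
        i += x != "-"
        j += y != "-"
    return GlobalAlignment(
        a=a, b=b, aligned_a=aligned_a, aligned_b=aligned_b, score=float(aln.score),
        identity_pct=100.0 * identical / denom, pairs=pairs,
    )


@dataclass(frozen=True)
class ResidueMapping:
    """Cross-ortholog residue correspondence for one query position.

    ``mapped`` is the partner's 1-based position, or None when the query
    residue sits in a gap column; ``flank_left``/``flank_right`` then give
    the nearest mapped partner positions on either side.
    """

    source_position: int
    mapped: Optional[int]
    flank_left: Optional[int] = None
    flank_right: Optional[int] = None


def map_residue(alignment: GlobalAlignment, source: Literal["a", "b"], position: int) -> ResidueMapping:
    """Partner position of a 1-based residue through the alignment."""
    protein = alignment.a if source == "a" else alignment.b
    if not 1 <= position <= len(protein):
        raise ValueError(f"position {position} outside 1..{len(protein)}")
    table = alignment._a_to_b if source == "a" else alignment._b_to_a
    if position in table:
        return ResidueMapping(source_position=position, mapped=table[position])
    left = max((p for p in table if p < position), default=None)
    right = min((p for p in table if p > position), default=None)
    return ResidueMapping(
        source_position=position,
        mapped=None,
        flank_left=table[left] if left is not None else None,
        flank_right=table[right] if right is not None else None,
    )


# ---------------------------------------------------------------------------
# mutagenesis and chimeras


@dataclass(frozen=True)
class Mutation:
    """One substitution in standard nomenclature, e.g. D15A."""

    reference: str
    position: int
    replacement: str

    def __str__(self) -> str:
        return f"{self.reference}{self.position}{self.replacement}"


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutations(spec: str) -> list[Mutation]:
    """Parse "D15A,Q788K/Y973K" (comma or slash separated) into Mutations."""
    muts = []
    for token in re.split(r"[,/]", spec):
        token = token.strip()
        if not token:
            continue
        m = _MUTATION_RE.match(token)
        if not m:
            raise ValueError(f"cannot parse mutation {token!r} (expected e.g. D15A)")
        muts.append(Mutation(m.group(1), int(m.group(2)), m.group(3)))
    return muts


def apply_mutations(protein: ProteinRecord, spec: Sequence[Mutation] | str, name: Optional[str] = None) -> ProteinRecord:
    """Apply point mutations, validating each stated reference residue.

    A mismatch between the stated and actual residue is an error naming the
    position and the residue found — silent renumbering bugs are the main
    hazard of cross-ortholog mutagenesis.
    """
    mutations = parse_mutations(spec) if isinstance(spec, str) else list(spec)
    seq = list(protein.sequence)
    for mut in mutations:
        if not 1 <= mut.position <= len(seq):
            raise ValueError(f"{protein.name}: position {mut.position} outside 1..{len(seq)}")
        found = seq[mut.position - 1]
        if found != mut.reference:
            raise ValueError(
                f"{protein.name}: expected {mut.reference} at position {mut.position}, found {found}"
            )
        seq[mut.position - 1] = mut.replacement
    new_name = name or (protein.name + "(" + ",".join(map(str, mutations)) + ")" if mutations else protein.name)
    return ProteinRecord(name=new_name, sequence="".join(seq))


@dataclass(frozen=True)
class DomainSpan:
    """A named 1-based inclusive residue interval on a protein (e.g. a PID)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span {self.start}-{self.end}")

    def validate(self, protein: ProteinRecord) -> None:
        if self.end > len(protein):
            raise ValueError(f"{self.name} span {self.start}-{self.end} exceeds {protein.name} length {len(protein)}")

    def extract(self, protein: ProteinRecord) -> str:
        self.validate(protein)
        return protein.sequence[self.start - 1 : self.end]


def build_chimera(
    backbone: ProteinRecord,
    backbone_span: DomainSpan,
    donor: ProteinRecord,
    donor_span: DomainSpan,
    name: Optional[str] = None,
) -> ProteinRecord:
    """Replace a backbone domain by the donor's — the PID-swap construction
    that transfers PAM specificity between orthologs.

    Result length = len(backbone) - len(backbone span) + len(donor span).
    """
    backbone_span.validate(backbone)
    donor_span.validate(donor)
    seq = (
        backbone.sequence[: backbone_span.start - 1]
        + donor_span.extract(donor)
        + backbone.sequence[backbone_span.end :]
    )
    return ProteinRecord(name=name or f"{backbone.name}-{donor.name}-{donor_span.name}", sequence=seq)
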