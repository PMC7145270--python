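"""Editing-outcome quantification at endogenous-style amplicons.

Given deep-sequencing reads of a PCR amplicon spanning a nuclease target
site, this module measures (a) the fraction of reads carrying an insertion
or deletion near the predicted cut site — the standard readout of nuclease
activity — and (b) per-position base-conversion percentages among
indel-free reads, the standard readout of cytosine (C->T) and adenine
(A->G) base editors.

Conventions, stated explicitly because they vary across tools:

* The nuclease cut site is placed 3 bp 5' of the PAM-proximal protospacer
  end (the blunt cut typical of type II-A Cas9).
* Protospacer positions are numbered 1..L from the 5'-most, PAM-distal base
  of the protospacer on its own strand — the convention under which
  BE4max-class editors act in an edit window of roughly positions 1-10 and
  a label like "E1-C4" means "C at position 4 of target E1".
* A read counts as an indel read iff an insertion or deletion run of its
  global alignment overlaps the window cut +/- quant_window. Reads with
  substitutions only are never indel reads.
* Conversion percentages are computed over reads whose alignment contains
  no insertion or deletion run anywhere.
"""

from __future__ import annotations

import functools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from Bio import Align

from ._seq import COMPLEMENT, IUPAC_TO_BASES, revcomp, validate_iupac

Strand = Literal["+", "-"]


@dataclass(frozen=True)
class AmpliconTarget:
    """A reference amplicon with protospacer/PAM coordinates.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of the
    protospacer; the PAM lies immediately 3' of the protospacer *on the
    target strand* (forward-right for '+', forward-left for '-').
    """

    name: str
    sequence: str
    protospacer: str
    pam: str
    strand: Strand
    start: int
    end: int
    pam_start: int
    pam_end: int
    cut_offset: int = 3
    quant_window: int = 10
    edit_window: tuple[int, int] = (1, 10)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end <= len(self.sequence)):
            raise ValueError("protospacer interval outside amplicon")
        if not (0 <= self.pam_start < self.pam_end <= len(self.sequence)):
            raise ValueError("PAM interval outside amplicon")
        if self.strand == "+" and self.pam_start != self.end:
            raise ValueError("PAM must be immediately 3' of the protospacer")
        if self.strand == "-" and self.pam_end != self.start:
            raise ValueError("PAM must be immediately 3' of the protospacer (reverse strand)")

    @classmethod
    def locate(
        cls,
        name: str,
        amplicon: str,
        protospacer: str,
        pam_pattern: str,
        strand: Optional[Strand] = None,
        **kwargs,
    ) -> "AmpliconTarget":
        """Locate a protospacer (given 5'->3' on its own strand) in the
        amplicon and validate that the adjacent sequence matches the declared
        IUPAC PAM pattern. With ``strand=None`` both orientations are tried.
        """
        validate_iupac(pam_pattern)
        plen = len(pam_pattern)
        candidates: list[Strand] = [strand] if strand else ["+", "-"]
        for st in candidates:
            probe = protospacer if st == "+" else revcomp(protospacer)
            idx = amplicon.find(probe)
            if idx < 0:
                continue
            start, end = idx, idx + len(protospacer)
            if st == "+":
                pam_start, pam_end = end, end + plen
                pam_seq = amplicon[pam_start:pam_end]
            else:
                pam_start, pam_end = start - plen, start
                pam_seq = revcomp(amplicon[pam_start:pam_end])
            if pam_start < 0 or pam_end > len(amplicon):
                raise ValueError(f"{name}: PAM extends beyond the amplicon")
            if len(pam_seq) == plen and all(b in IUPAC_TO_BASES[s] for b, s in zip(pam_seq, pam_pattern)):
                return cls(
                    name=name, sequence=amplicon, protospacer=protospacer, pam=pam_seq,
                    strand=st, start=start, end=end, pam_start=pam_start, pam_end=pam_end,
                    **kwargs,
                )
        raise ValueError(f"{name}: protospacer with PAM {pam_pattern} not found in amplicon")

    @property
    def cut_site(self) -> int:
        """Forward-strand coordinate of the cut point: the cut falls between
        positions cut_site-1 and cut_site."""
        if self.strand == "+":
            return self.end - self.cut_offset
        return self.start + self.cut_offset

    def position_to_coord(self, position: int) -> int:
        """Forward-strand coordinate of 1-based protospacer *position*
        (position 1 = PAM-distal, 5'-most base on the target strand)."""
        if not 1 <= position <= len(self.protospacer):
            raise ValueError(f"protospacer position {position} outside 1..{len(self.protospacer)}")
        if self.strand == "+":
            return self.start + position - 1
        return self.end - position

    def strand_base(self, forward_base: str) -> str:
        """A forward-strand base expressed on the target strand."""
        return forward_base if self.strand == "+" else forward_base.translate(COMPLEMENT)


@dataclass(frozen=True)
class AlignedRun:
    """One run of a read-to-amplicon alignment in reference coordinates.

    op is M (match), X (mismatch), I (insertion: read bases absent from the
    reference, anchored at ref_start) or D (deletion of reference bases).
    """

    op: Literal["M", "X", "I", "D"]
    ref_start: int
    length: int
    read_start: int


@dataclass
class AmpliconAlignment:
    runs: list[AlignedRun]
    score: float
    identity: float
    read: str

    @property
    def has_indel(self) -> bool:
        return any(r.op in "ID" for r in self.runs)

    def base_at(self, coord: int) -> Optional[str]:
        """Read base aligned to reference coordinate *coord* (None if deleted)."""
        for r in self.runs:
            if r.op in "MX" and r.ref_start <= coord < r.ref_start + r.length:
                return self.read[r.read_start + (coord - r.ref_start)]
        return None


@dataclass
class EditingReport:
    """Indel quantification at one amplicon target."""

    target: str
    n_reads: int
    n_dropped: int
    n_indel: int
    indel_length_histogram: dict[int, int]

    @property
    def indel_pct(self) -> float:
        return 100.0 * self.n_indel / self.n_reads


@dataclass
class BaseEditTable:
    """Per-position conversion percentages among indel-free reads.

    ``table`` columns: position, label, ref_base, converted_base, n_reads,
    n_converted, conversion_pct. Labels follow the "<target>-<refbase><pos>"
    convention (e.g. "E1-C4" = C at position 4 of target E1).
    """

    target: str
    n_indel_free: int
    table: pd.DataFrame


@functools.lru_cache(maxsize=4)
def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -13.0  # first gap base: open 12 + extend 1
    aligner.extend_gap_score = -1.0
    return aligner


def align_to_amplicon(read: str, target: AmpliconTarget, min_identity: float = 0.6) -> Optional[AmpliconAlignment]:
    """Global affine-gap alignment of a read to the reference amplicon.

    Scoring: match +2, mismatch -4, gap of length k costs 12 + k. Returns the
    alignment as match/mismatch/insertion/deletion runs with reference
    coordinates, or None when identity (matches over alignment columns)
    falls below ``min_identity``.
    """
    ref = target.sequence
    if len(read) > 2 * len(ref):
        raise ValueError("read length exceeds twice the amplicon length")
    if len(read) == len(ref):
        # Gapless fast path: with these scores a gap pair costs >= 28 while
        # re-pairing a mismatch gains at most 6, so the column-by-column
        # alignment is provably optimal whenever mismatches <= 4.
        mismatch_cols = [i for i, (x, y) in enumerate(zip(ref, read)) if x != y]
        if len(mismatch_cols) <= 4:
            runs: list[AlignedRun] = []
            prev = 0
            for i in mismatch_cols:
                if i > prev:
                    runs.append(AlignedRun("M", prev, i - prev, prev))
                runs.append(AlignedRun("X", i, 1, i))
                prev = i + 1
            if len(ref) > prev:
                runs.append(AlignedRun("M", prev, len(ref) - prev, prev))
            identity = 1.0 - len(mismatch_cols) / len(ref)
            if identity < min_identity:
                return None
            score = 2.0 * (len(ref) - len(mismatch_cols)) - 4.0 * len(mismatch_cols)
            return AmpliconAlignment(runs=runs, score=score, identity=identity, read=read)
    aln = _dna_aligner().align(ref, read)[0]
    ref_blocks, read_blocks = aln.aligned
    runs: list[AlignedRun] = []
    prev_ref_end, prev_read_end = 0, 0
    columns = 0
    matches = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > prev_ref_end:
            runs.append(AlignedRun("D", prev_ref_end, rs - prev_ref_end, prev_read_end))
            columns += rs - prev_ref_end
        if qs > prev_read_end:
            runs.append(AlignedRun("I", rs, qs - prev_read_end, prev_read_end))
            columns += qs - prev_read_end
        # split the aligned block into match / mismatch runs
        run_op: Optional[str] = None
        run_start = 0
        for off in range(re_ - rs):
            op = "M" if ref[rs + off] == read[qs + off] else "X"
            if op == "M":
                matches += 1
            if op != run_op:
                if run_op is not None:
                    runs.append(AlignedRun(run_op, rs + run_start, off - run_start, qs + run_start))
                run_op, run_start = op, off
        if run_op is not None:
            runs.append(AlignedRun(run_op, rs + run_start, re_ - rs - run_start, qs + run_start))
        columns += re_ - rs
        prev_ref_end, prev_read_end = re_, qe
    if len(ref) > prev_ref_end:
        runs.append(AlignedRun("D", prev_ref_end, len(ref) - prev_ref_end, prev_read_end))
        columns += len(ref) - prev_ref_end
    if len(read) > prev_read_end:
        runs.append(AlignedRun("I", len(ref), len(read) - prev_read_end, prev_read_end))
        columns += len(read) - prev_read_end
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    return AmpliconAlignment(runs=runs, score=aln.score, identity=identity, read=read)


def _indel_runs_in_window(alignment: AmpliconAlignment, lo: int, hi: int) -> list[AlignedRun]:
    """Insertion/deletion runs overlapping the closed window [lo, hi]."""
    out = []
    for r in alignment.runs:
        if r.op == "D" and r.ref_start <= hi and r.ref_start + r.length - 1 >= lo:
            out.append(r)
        elif r.op == "I" and lo <= r.ref_start <= hi:
            out.append(r)
    return out


def quantify_indels(
    reads: Iterable[str],
    target: AmpliconTarget,
    min_identity: float = 0.6,
) -> EditingReport:
    """Fraction of aligned reads with an indel near the cut site.

    A read is an indel read iff any insertion/deletion run of its alignment
    overlaps cut_site +/- quant_window. The per-read net indel length (sum of
    insertions minus deletions within the window) feeds the histogram.
    """
    lo = target.cut_site - target.quant_window
    hi = target.cut_site + target.quant_window
    n_reads = n_dropped = n_indel = 0
    hist: Counter = Counter()
    for read in reads:
        aln = align_to_amplicon(read, target, min_identity)
        if aln is None:
            n_dropped += 1
            continue
        n_reads += 1
        window_runs = _indel_runs_in_window(aln, lo, hi)
        if window_runs:
            n_indel += 1
            net = sum(r.length if r.op == "I" else -r.length for r in window_runs)
            hist[net] += 1
    if n_reads == 0:
        raise ValueError(f"{target.name}: no reads aligned to the amplicon")
    return EditingReport(
        target=target.name, n_reads=n_reads, n_dropped=n_dropped, n_indel=n_indel,
        indel_length_histogram=dict(sorted(hist.items())),
    )


def quantify_conversions(
    reads: Iterable[str],
    target: AmpliconTarget,
    from_base: str = "C",
    to_base: str = "T",
    min_identity: float = 0.6,
) -> BaseEditTable:
    """Per-position conversion percentages among indel-free reads.

    For each protospacer position in the edit window whose reference base
    (on the target strand) equals ``from_base``, reports the percentage of
    indel-free aligned reads carrying ``to_base`` there. Reads with any
    insertion or deletion run are excluded entirely, so indel and conversion
    calls never mix.
    """
    for b, label in ((from_base, "from_base"), (to_base, "to_base")):
        if b not in "ACGT":
            raise ValueError(f"{label} must be one of A,C,G,T, got {b!r}")
    positions = [
        p
        for p in range(target.edit_window[0], target.edit_window[1] + 1)
        if p <= len(target.protospacer)
        and target.strand_base(target.sequence[target.position_to_coord(p)]) == from_base
    ]
    converted: Counter = Counter()
    n_indel_free = 0
    for read in reads:
        aln = align_to_amplicon(read, target, min_identity)
        if aln is None or aln.has_indel:
            continue
        n_indel_free += 1
        for p in positions:
            base = aln.base_at(target.position_to_coord(p))
            if base is not None and target.strand_base(base) == to_base:
                converted[p] += 1
    rows = []
    for p in positions:
        pct = 100.0 * converted[p] / n_indel_free if n_indel_free else 0.0
        rows.append(
            {
                "position": p,
                "label": f"{target.name}-{from_base}{p}",
                "ref_base": from_base,
                "converted_base": to_base,
                "n_reads": n_indel_free,
                "n_converted": converted[p],
                "conversion_pct": pct,
            }
        )
    table = pd.DataFrame(rows, columns=[
        "position", "label", "ref_base", "converted_base", "n_reads", "n_converted", "conversion_pct",
    ])
    return BaseEditTable(target=target.name, n_indel_free=n_indel_free, table=table)
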