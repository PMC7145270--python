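"""PAM-pattern scanning, targeting-scope density, and mismatch-bounded
off-target enumeration.

A nuclease's targeting scope is set by how often its PAM occurs: a pattern
like NNGG matched on both strands of uniform random sequence is expected
once per 8 positions (2 fixed bases -> 4^-2 per strand, doubled). Off-target
candidates for a guide are sites whose PAM matches the IUPAC pattern exactly
and whose protospacer is within a Hamming-distance budget of the spacer —
the standard in-silico candidate enumeration used to annotate
GUIDE-seq-style hits (mismatch highlighting only; no read-count ranking).

Conventions: coordinates are 0-based half-open on the forward strand (BED
convention); reverse-strand hits are reported in forward coordinates with a
strand flag. An ambiguous genome base N matches nothing, even at pattern-N
positions — conservative site calling that avoids inflating candidate lists
in gap-rich sequences. Scanning is brute force over windows (desk-scale
genomes are the contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA, DNA_SET, IUPAC_TO_BASES, revcomp, validate_iupac


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate nucleotide pattern with per-position allowed-base sets."""

    pattern: str
    expansion: tuple[frozenset, ...] = field(init=False)

    def __post_init__(self) -> None:
        validate_iupac(self.pattern)
        object.__setattr__(self, "expansion", tuple(IUPAC_TO_BASES[s] for s in self.pattern))

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        """Exact IUPAC match (genome N fails every position)."""
        return len(window) == len(self.pattern) and all(
            b in allowed for b, allowed in zip(window, self.expansion)
        )


@dataclass(frozen=True)
class SpacerQuery:
    """A guide spacer with its PAM requirement and mismatch budget (PAM 3')."""

    spacer: str
    pam: IupacPattern
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        if not self.spacer or not set(self.spacer) <= DNA_SET:
            raise ValueError("spacer must be a nonempty ACGT string")
        if not 0 <= self.max_mismatches <= len(self.spacer):
            raise ValueError("max_mismatches must lie in [0, spacer length]")


@dataclass(frozen=True)
class SiteHit:
    """A PAM-compatible match: 0-based half-open forward-strand protospacer
    coordinates, with the PAM immediately 3' on the hit strand. Mismatch
    positions are 0-based from the spacer 5' end."""

    seqid: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    mismatches: int
    mismatch_positions: tuple[int, ...]


def _base_masks(seq_arr: np.ndarray) -> dict[str, np.ndarray]:
    return {b: seq_arr == ord(b) for b in DNA}


def _pattern_hits(seq: str, pattern: IupacPattern) -> np.ndarray:
    """Start indices where *pattern* matches *seq* (single strand, vectorised)."""
    k = len(pattern)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _base_masks(arr)
    ok = np.ones(n, dtype=bool)
    for j, allowed in enumerate(pattern.expansion):
        col = np.zeros(n, dtype=bool)
        for b in allowed:
            col |= masks[b][j : j + n]
        ok &= col
    return np.nonzero(ok)[0]


def scan_pam_sites(sequence: str, pam: IupacPattern | str, both_strands: bool = True) -> list[tuple[int, str]]:
    """All (start, strand) PAM matches; reverse-strand hits in forward
    coordinates (start of the matched window on the forward strand)."""
    if isinstance(pam, str):
        pam = IupacPattern(pam)
    sequence = sequence.upper()
    hits = [(int(i), "+") for i in _pattern_hits(sequence, pam)]
    if both_strands:
        L, k = len(sequence), len(pam)
        rc = revcomp(sequence)
        hits += [(L - int(i) - k, "-") for i in _pattern_hits(rc, pam)]
    return sorted(hits)


def expected_pam_density(
    pam: IupacPattern | str,
    base_composition: Optional[Mapping[str, float]] = None,
    both_strands: bool = True,
) -> float:
    """Expected PAM matches per genomic position under an i.i.d. base model.

    density = prod_j sum_{b in allowed_j} p(b), doubled for both strands
    (per-strand site counting: palindromic double-hits count twice, the
    convention under which NNGG gives exactly one site per 8 positions).
    """
    if isinstance(pam, str):
        pam = IupacPattern(pam)
    comp = dict(base_composition) if base_composition else {b: 0.25 for b in DNA}
    if set(comp) != DNA_SET or any(p < 0 for p in comp.values()) or not np.isclose(sum(comp.values()), 1.0):
        raise ValueError("base_composition must assign nonnegative A/C/G/T probabilities summing to 1")
    density = 1.0
    for allowed in pam.expansion:
        density *= sum(comp[b] for b in allowed)
    return 2.0 * density if both_strands else density


def _strand_hits(seqid: str, strand_seq: str, query: SpacerQuery) -> Iterable[tuple[int, int, str, str, tuple[int, ...]]]:
    """Hits on one strand sequence: (strand_start, mismatches, protospacer,
    pam, mismatch_positions), with coordinates on that strand."""
    S, P = len(query.spacer), len(query.pam)
    n = len(strand_seq) - S - P + 1
    if n <= 0:
        return
    arr = np.frombuffer(strand_seq.encode("ascii"), dtype=np.uint8)
    spacer_bytes = np.frombuffer(query.spacer.encode("ascii"), dtype=np.uint8)
    mm = np.zeros(n, dtype=np.int32)
    for j in range(S):
        mm += arr[j : j + n] != spacer_bytes[j]
    # PAM immediately 3' of the protospacer
    pam_ok = np.ones(n, dtype=bool)
    masks = _base_masks(arr)
    for j, allowed in enumerate(query.pam.expansion):
        col = np.zeros(n, dtype=bool)
        for b in allowed:
            col |= masks[b][S + j : S + j + n]
        pam_ok &= col
    for i in np.nonzero(pam_ok & (mm <= query.max_mismatches))[0]:
        proto = strand_seq[i : i + S]
        positions = tuple(j for j in range(S) if proto[j] != query.spacer[j])
        yield int(i), int(mm[i]), proto, strand_seq[i + S : i + S + P], positions


def find_offtargets(genome: Mapping[str, str], query: SpacerQuery) -> list[SiteHit]:
    """Every site with an exact IUPAC PAM match and spacer Hamming distance
    <= max_mismatches, on both strands, sorted by (mismatches, seqid, start).

    ``genome`` maps sequence ids to ACGTN strings (e.g. from
    :func:`pamprofiler.io.read_fasta`).
    """
    hits: list[SiteHit] = []
    S, P = len(query.spacer), len(query.pam)
    for seqid in genome:
        seq = genome[seqid].upper()
        bad = set(seq) - (DNA_SET | {"N"})
        if bad:
            raise ValueError(f"{seqid}: genome contains non-ACGTN symbols {sorted(bad)}")
        for i, mm, proto, pam_seq, positions in _strand_hits(seqid, seq, query):
            hits.append(SiteHit(seqid, i, i + S, "+", proto, pam_seq, mm, positions))
        rc = revcomp(seq)
        L = len(seq)
        for i, mm, proto, pam_seq, positions in _strand_hits(seqid, rc, query):
            hits.append(SiteHit(seqid, L - i - S, L - i, "-", proto, pam_seq, mm, positions))
    hits.sort(key=lambda h: (h.mismatches, h.seqid, h.start, h.strand))
    return hits


def annotate_shared_pams(
    context_3prime: str,
    pam_list: Sequence[IupacPattern | str],
) -> dict[str, Optional[bool]]:
    """Which nucleases' PAM patterns accept a hit's 3' context.

    ``context_3prime`` is the sequence immediately 3' of the protospacer on
    the hit strand. A pattern longer than the available context maps to None
    (unknown). Useful for flagging off-target sites that carry a PAM for
    more than one Cas9 ortholog.
    """
    out: dict[str, Optional[bool]] = {}
    for pam in pam_list:
        pattern = IupacPattern(pam) if isinstance(pam, str) else pam
        if len(context_3prime) < len(pattern):
            out[pattern.pattern] = None
        else:
            out[pattern.pattern] = pattern.matches(context_3prime[: len(pattern)])
    return out


def hit_context(genome: Mapping[str, str], hit: SiteHit, length: int) -> str:
    """Up to *length* bases immediately 3' of a hit's protospacer, on the hit
    strand (PAM side)."""
    seq = genome[hit.seqid]
    if hit.strand == "+":
        return seq[hit.end : hit.end + length]
    return revcomp(seq[max(0, hit.start - length) : hit.start])


def hits_to_frame(hits: Sequence[SiteHit]) -> pd.DataFrame:
    """BED-like table of hits (0-based half-open; mismatch positions reported
    1-based from the spacer 5' end, '.' when none)."""
    rows = [
        {
            "seqid": h.seqid,
            "start": h.start,
            "end": h.end,
            "name": f"{h.protospacer}|{h.pam}",
            "mismatches": h.mismatches,
            "strand": h.strand,
            "protospacer": h.protospacer,
            "pam": h.pam,
            "mismatch_positions": ",".join(str(p + 1) for p in h.mismatch_positions) or ".",
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["seqid", "start", "end", "name", "mismatches", "strand", "protospacer", "pam", "mismatch_positions"],
    )
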