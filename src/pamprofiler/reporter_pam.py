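"""PAM discovery from a GFP-reporter randomized-library screen.

The screen encodes a disrupted GFP open reading frame: a fixed upstream
anchor, a 25-nt target whose last three bases (the "fixer", GCG) pin the
start of a 7-bp randomized PAM region, and a fixed downstream anchor.
Cleavage followed by error-prone repair restores GFP only when the net
length change is a non-zero multiple of 3 (an in-frame indel), so reads
sequenced from GFP-positive cells that carry in-frame mutations report
which randomized PAMs supported cleavage.

This module turns such reads into PAM statistics: anchor location, indel
classification, randomized-region extraction, k-mer tallies, per-position
frequency / information-content profiles, a hierarchical "PAM wheel", and
an IUPAC consensus call.

Coordinate conventions: 0-based half-open internally; report files are
1-based inclusive. PAM position 1 is the first base 3' of the protospacer.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES_TO_IUPAC, DNA, DNA_SET, find_approx, hamming

FrameClass = Literal["wildtype", "in_frame_edit", "frameshift", "unanchored"]


@dataclass(frozen=True)
class ReporterDesign:
    """Fixed-anchor layout of the reporter construct.

    Defaults are the construct used for PAM profiling: 20-bp flanks around a
    25-nt target ending in GCG, followed by 7 randomized bases.
    """

    upstream_anchor: str = "AAGCCTTGTTTGCCACCATG"
    downstream_anchor: str = "GTGAGCAAGGGCGAGGAGCT"
    target: str = "GAACGGCTCGGAGATCATCATTGCG"
    fixer: str = "GCG"
    random_length: int = 7

    def __post_init__(self) -> None:
        for name in ("upstream_anchor", "downstream_anchor", "target", "fixer"):
            seq = getattr(self, name)
            if not seq or not set(seq) <= DNA_SET:
                raise ValueError(f"{name} must be a nonempty ACGT string, got {seq!r}")
        if not self.target.endswith(self.fixer):
            raise ValueError("target must end with the fixer trinucleotide")
        if self.random_length < 4:
            raise ValueError("random_length must be >= 4")
        for anchor in (self.upstream_anchor, self.downstream_anchor):
            if anchor in self.target:
                raise ValueError("anchors must not occur inside the target")

    @property
    def inner_reference_length(self) -> int:
        """Unedited length of the region between the anchors."""
        return len(self.target) + self.random_length

    def construct(self, pam_region: str) -> str:
        """Full unedited construct sequence around a given randomized region."""
        if len(pam_region) != self.random_length or not set(pam_region) <= DNA_SET:
            raise ValueError(f"randomized region must be {self.random_length} nt of ACGT")
        return self.upstream_anchor + self.target + pam_region + self.downstream_anchor

    @property
    def cut_position(self) -> int:
        """Cut point inside the *inner* region (between anchors), 3 bp 5' of
        the PAM-proximal target end — i.e. just before the fixer."""
        return len(self.target) - 3


@dataclass(frozen=True)
class ReadClassification:
    """Outcome of locating and classifying one read."""

    anchored: bool
    net_indel: Optional[int]
    frame_class: FrameClass
    pam7: Optional[str]

    def __post_init__(self) -> None:
        if self.frame_class == "in_frame_edit":
            assert self.net_indel is not None and self.net_indel != 0 and self.net_indel % 3 == 0


@dataclass
class PamCounts:
    """Tally of PAM k-mers over in-frame-edited reads."""

    k: int
    counts: Counter
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts.values())


@dataclass
class PamProfile:
    """Per-position base frequencies over a PAM of length k.

    ``frequencies`` is a (k x 4) DataFrame indexed by 1-based PAM position
    with columns A, C, G, T; each row sums to 1.
    """

    frequencies: pd.DataFrame
    pseudocount: float
    n: int

    @property
    def k(self) -> int:
        return len(self.frequencies)


@dataclass
class PamWheelNode:
    """Node of the hierarchical PAM-wheel (sunburst) tree.

    Ring *depth* partitions the tally by the base at PAM position *depth*;
    ``conditional_fraction`` is this node's count over its parent's.
    """

    base: str
    depth: int
    count: int
    conditional_fraction: float
    children: dict[str, "PamWheelNode"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "base": self.base,
            "depth": self.depth,
            "count": self.count,
            "conditional_fraction": self.conditional_fraction,
        }
        if self.children:
            d["children"] = {b: c.to_dict() for b, c in sorted(self.children.items())}
        return d

    def leaves(self, prefix: str = "") -> dict[str, int]:
        """Leaf k-mer -> count mapping (round-trips with the source tally)."""
        label = prefix + self.base
        if not self.children:
            return {label: self.count}
        out: dict[str, int] = {}
        for child in self.children.values():
            out.update(child.leaves(label))
        return out


# ---------------------------------------------------------------------------
# read-level operations


def locate_anchors(read: str, design: ReporterDesign, max_anchor_mismatches: int = 1) -> Optional[str]:
    """Sequence strictly between the first upstream-anchor match and the first
    downstream-anchor match after it, or None when unanchored.

    Anchor matches tolerate up to ``max_anchor_mismatches`` substitutions.
    """
    if not read:
        raise ValueError("read must be nonempty")
    up = find_approx(read, design.upstream_anchor, max_anchor_mismatches)
    if up < 0:
        return None
    inner_start = up + len(design.upstream_anchor)
    down = find_approx(read, design.downstream_anchor, max_anchor_mismatches, start=inner_start)
    if down < 0:
        return None
    return read[inner_start:down]


def extract_pam7(inner: str, design: ReporterDesign) -> Optional[str]:
    """Randomized PAM region of an anchored inner sequence, or None.

    The region is the last ``random_length`` bases of the inner sequence and
    must be immediately preceded by an exact fixer match (deletions that chew
    into the fixer or the randomized region make it unextractable). The fixer
    is matched exactly: a 3-mer carries no information under mismatches.
    """
    n, f = design.random_length, len(design.fixer)
    if len(inner) < n + f:
        return None
    if inner[-(n + f) : -n] != design.fixer:
        return None
    region = inner[-n:]
    if not set(region) <= DNA_SET:
        return None
    return region


def classify_read(
    inner: str,
    design: ReporterDesign,
    substitution_tolerance: int = 2,
) -> ReadClassification:
    """Classify an anchored inner sequence by net length change.

    net_indel = len(inner) - (len(target) + random_length). Wildtype requires
    net 0 *and* a target region within ``substitution_tolerance`` mismatches
    of the reference (sequencing errors should not look like edits); a
    non-zero net that is a multiple of 3 is an in-frame edit; everything else
    is a frameshift. Indel calling is by length difference only — the fixer
    anchors the randomized region independently of where the indel sits.
    """
    net = len(inner) - design.inner_reference_length
    pam7 = extract_pam7(inner, design)
    if net == 0:
        target_region = inner[: len(design.target)]
        if hamming(target_region, design.target) <= substitution_tolerance:
            frame: FrameClass = "wildtype"
        else:
            frame = "frameshift"
    elif net % 3 == 0:
        frame = "in_frame_edit"
    else:
        frame = "frameshift"
    return ReadClassification(anchored=True, net_indel=net, frame_class=frame, pam7=pam7)


def classify_reads(
    reads: Iterable[str],
    design: ReporterDesign,
    max_anchor_mismatches: int = 1,
    substitution_tolerance: int = 2,
) -> list[ReadClassification]:
    """locate_anchors + classify_read over a collection of raw reads."""
    out = []
    for read in reads:
        inner = locate_anchors(read, design, max_anchor_mismatches)
        if inner is None:
            out.append(ReadClassification(anchored=False, net_indel=None, frame_class="unanchored", pam7=None))
        else:
            out.append(classify_read(inner, design, substitution_tolerance))
    return out


# ---------------------------------------------------------------------------
# tally and profile


def tally_pams(classifications: Iterable[ReadClassification], k: int = 4, random_length: int = 7) -> PamCounts:
    """Count the first k PAM bases over in-frame-edited reads only.

    Reads whose randomized region could not be extracted are skipped. Only
    ``frame_class == "in_frame_edit"`` reads enter the tally: those are the
    reads whose repair outcome restores GFP and hence reports cleavage.
    """
    if k > random_length:
        raise ValueError(f"k={k} exceeds randomized region length {random_length}")
    counts: Counter = Counter()
    for c in classifications:
        if c.frame_class == "in_frame_edit" and c.pam7 is not None:
            counts[c.pam7[:k]] += 1
    return PamCounts(k=k, counts=counts)


def position_frequencies(counts: PamCounts, pseudocount: float = 0.5) -> PamProfile:
    """Per-position base frequencies with additive smoothing.

    f[j][b] = (count of base b at position j + pseudocount) / (total + 4*pseudocount).
    """
    if counts.total == 0:
        raise ValueError("empty PAM selection: no in-frame-edited reads to profile")
    mat = np.zeros((counts.k, 4))
    base_idx = {b: i for i, b in enumerate(DNA)}
    for kmer, n in counts.counts.items():
        for j, b in enumerate(kmer):
            mat[j, base_idx[b]] += n
    mat = (mat + pseudocount) / (counts.total + 4.0 * pseudocount)
    df = pd.DataFrame(mat, index=pd.RangeIndex(1, counts.k + 1, name="position"), columns=list(DNA))
    return PamProfile(frequencies=df, pseudocount=pseudocount, n=counts.total)


def information_content(profile: PamProfile) -> np.ndarray:
    """Sequence-logo information content per PAM position, in bits.

    IC[j] = 2 + sum_b f[j][b] * log2 f[j][b], with 0*log0 := 0. Ranges from 0
    (uniform) to 2 (invariant). No small-sample correction.
    """
    f = profile.frequencies.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return 2.0 + plogp.sum(axis=1)


def build_pam_wheel(counts: PamCounts) -> PamWheelNode:
    """Hierarchical prefix tree over the PAM tally (sunburst layout).

    The depth-j node for prefix p counts the k-mers beginning with p; its
    conditional_fraction is count / parent count.
    """
    if counts.total == 0:
        raise ValueError("empty PAM selection: cannot build a wheel from zero reads")
    root = PamWheelNode(base="", depth=0, count=counts.total, conditional_fraction=1.0)
    for kmer, n in sorted(counts.counts.items()):
        node = root
        for depth, base in enumerate(kmer, start=1):
            if base not in node.children:
                node.children[base] = PamWheelNode(base=base, depth=depth, count=0, conditional_fraction=0.0)
            node = node.children[base]
            node.count += n
    # fill conditional fractions once counts are final
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children.values():
            child.conditional_fraction = child.count / node.count
            stack.append(child)
    return root


def call_consensus(profile: PamProfile, strong_threshold: float = 0.8, pair_threshold: float = 0.9) -> str:
    """IUPAC consensus over the profile.

    Per position: a single base with frequency >= strong_threshold wins;
    otherwise the smallest base set (2 then 3 bases) whose cumulative
    frequency reaches pair_threshold wins (highest cumulative frequency
    breaks ties); if no set smaller than 4 qualifies, the position is N.

    The degenerate-set threshold defaults higher than the single-base one
    because an unconstrained position already puts ~0.5 on its best pair
    and ~0.75 on its best triple; 0.9 keeps sampling noise at realistic
    read depths from promoting uniform positions to B/D/H/V calls.
    """
    for name, t in (("strong_threshold", strong_threshold), ("pair_threshold", pair_threshold)):
        if not 0.25 < t <= 1.0:
            raise ValueError(f"{name} must lie in (0.25, 1], got {t}")
    symbols = []
    for _, row in profile.frequencies.iterrows():
        freqs = row.to_dict()
        best = max(freqs, key=freqs.get)
        if freqs[best] >= strong_threshold:
            symbols.append(best)
            continue
        chosen = None
        for size in (2, 3):
            subsets = [
                (sum(freqs[b] for b in combo), frozenset(combo))
                for combo in itertools.combinations(DNA, size)
            ]
            total, bases = max(subsets, key=lambda t: t[0])
            if total >= pair_threshold:
                chosen = BASES_TO_IUPAC[bases]
                break
        symbols.append(chosen if chosen is not None else "N")
    return "".join(symbols)


def pam_table(counts: PamCounts, presort: Optional[Mapping[str, int]] = None) -> pd.DataFrame:
    """Tabular tally: kmer, count, frequency and enrichment.

    Enrichment is frequency over the uniform expectation 1/4^k, or over the
    presort frequency when a presort count table is supplied.
    """
    if counts.total == 0:
        return pd.DataFrame(columns=["kmer", "count", "frequency", "enrichment"])
    rows = []
    if presort is not None:
        presort_total = sum(presort.values())
    for kmer in sorted(counts.counts):
        n = counts.counts[kmer]
        freq = n / counts.total
        if presort is None:
            expected = 4.0 ** (-counts.k)
        else:
            expected = presort.get(kmer, 0) / presort_total if presort_total else math.nan
        rows.append((kmer, n, freq, freq / expected if expected else math.inf))
    return pd.DataFrame(rows, columns=["kmer", "count", "frequency", "enrichment"])


# ---------------------------------------------------------------------------
# one-call discovery pipeline


@dataclass
class DiscoveryResult:
    """End-to-end output of the PAM-discovery stage for one read set."""

    design: ReporterDesign
    n_reads: int
    n_anchored: int
    n_in_frame: int
    counts: PamCounts
    profile: PamProfile
    ic: np.ndarray
    consensus: str
    wheel: PamWheelNode

    @property
    def class_counts(self) -> Counter:
        return self._class_counts

    _class_counts: Counter = field(default_factory=Counter, repr=False)


def discover(
    reads: Sequence[str],
    design: Optional[ReporterDesign] = None,
    k: int = 4,
    max_anchor_mismatches: int = 1,
    substitution_tolerance: int = 2,
    pseudocount: float = 0.5,
    strong_threshold: float = 0.8,
    pair_threshold: float = 0.9,
) -> DiscoveryResult:
    """Run the whole discovery stage: classify, tally, profile, consensus, wheel."""
    design = design or ReporterDesign()
    cls = classify_reads(reads, design, max_anchor_mismatches, substitution_tolerance)
    counts = tally_pams(cls, k=k, random_length=design.random_length)
    profile = position_frequencies(counts, pseudocount=pseudocount)
    ic = information_content(profile)
    consensus = call_consensus(profile, strong_threshold, pair_threshold)
    wheel = build_pam_wheel(counts)
    result = DiscoveryResult(
        design=design,
        n_reads=len(cls),
        n_anchored=sum(c.anchored for c in cls),
        n_in_frame=sum(c.frame_class == "in_frame_edit" for c in cls),
        counts=counts,
        profile=profile,
        ic=ic,
        consensus=consensus,
        wheel=wheel,
    )
    result._class_counts = Counter(c.frame_class for c in cls)
    return result
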