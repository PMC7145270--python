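"""Seeded simulators for everything the pipeline consumes.

Two experiments are emulated, with ground truth recorded for recovery tests:

* The reporter-library PAM screen: constructs carry a 25-nt target followed
  by a 7-bp randomized region between fixed 20-bp anchors. A PAM-activity
  model decides per construct whether cleavage occurs (a Bernoulli draw on
  the weight of the randomized region's first four bases), repair draws a
  net indel length (in-frame with probability ``editable_fraction``), and
  only constructs repaired in frame — the ones that would turn GFP on and
  be sorted — emit reads.
* Amplicon deep sequencing: reads of a reference amplicon carrying either
  an indel at the cut site (with a given probability) or independent
  per-position base conversions, as produced by nucleases and base editors.

Error model: independent per-base substitutions at a configurable rate;
no simulated read indels, so the injected indel signal stays unambiguous.
Quality strings are constant 'I' (Q40); one read orientation only.

Indel placement: insertions go at the cut point (3 bp 5' of the
PAM-proximal target end); deletions remove ceil(d/2) bases 5' and
floor(d/2) bases 3' of the cut, so deletions can destroy the GCG fixer and
leave the randomized region unextractable — such constructs are emitted on
purpose and must be dropped downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA, DNA_SET
from .amplicon_quant import AmpliconTarget
from .reporter_pam import ReporterDesign


def default_indel_length_distribution(max_len: int = 9, decay: float = 0.8, deletion_bias: float = 2.0) -> dict[int, float]:
    """Geometric-tailed net-indel-length distribution over -max_len..+max_len
    excluding 0, with deletions ``deletion_bias``-fold more likely than
    insertions — the qualitative shape of NHEJ outcome spectra.
    """
    weights = {}
    for length in range(1, max_len + 1):
        weights[-length] = deletion_bias * decay ** (length - 1)
        weights[length] = decay ** (length - 1)
    total = sum(weights.values())
    return {k: v / total for k, v in sorted(weights.items())}


@dataclass
class PamActivityModel:
    """Ground-truth cleavage model over 4-mer PAMs.

    ``pattern_weights`` maps a 4-mer (positions 1-4 of the randomized
    region) to its cleavage probability; unlisted 4-mers get
    ``default_weight``. ``editable_fraction`` is the probability that an
    edited construct acquires an in-frame repair outcome (and is therefore
    sorted as GFP-positive).
    """

    pattern_weights: Mapping[str, float]
    default_weight: float = 0.0
    editable_fraction: float = 1.0 / 3.0
    indel_length_distribution: Mapping[int, float] = field(default_factory=default_indel_length_distribution)

    def __post_init__(self) -> None:
        for kmer, w in self.pattern_weights.items():
            if len(kmer) != 4 or not set(kmer) <= DNA_SET:
                raise ValueError(f"pattern_weights key {kmer!r} is not a DNA 4-mer")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"cleavage probability for {kmer} outside [0,1]: {w}")
        if not 0.0 <= self.default_weight <= 1.0:
            raise ValueError("default_weight outside [0,1]")
        if not 0.0 <= self.editable_fraction <= 1.0:
            raise ValueError("editable_fraction outside [0,1]")
        dist = dict(self.indel_length_distribution)
        if 0 in dist:
            raise ValueError("indel_length_distribution support must exclude 0")
        if any(p < 0 for p in dist.values()) or not np.isclose(sum(dist.values()), 1.0):
            raise ValueError("indel_length_distribution must be a probability mass summing to 1")

    def cleavage_probability(self, pam7: str) -> float:
        return self.pattern_weights.get(pam7[:4], self.default_weight)

    @classmethod
    def from_consensus(cls, consensus_positions: Mapping[int, str], weight: float = 1.0, **kwargs) -> "PamActivityModel":
        """Weight every 4-mer matching fixed bases at given 1-based positions.

        ``{3: "G", 4: "G"}`` yields the canonical GG-at-3-4 activity model.
        """
        weights = {}
        for kmer in map("".join, itertools.product(DNA, repeat=4)):
            if all(kmer[pos - 1] == base for pos, base in consensus_positions.items()):
                weights[kmer] = weight
        return cls(pattern_weights=weights, **kwargs)


@dataclass
class ScreenSimConfig:
    """Knobs of the reporter-screen simulation."""

    design: ReporterDesign = field(default_factory=ReporterDesign)
    n_constructs: int = 16384
    reads_per_construct: int = 10
    sequencing_error_rate: float = 0.001
    seed: int = 0
    enumerate_pams: bool = False
    pinned_pam7s: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.n_constructs <= 0 or self.reads_per_construct <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.sequencing_error_rate <= 0.1:
            raise ValueError("sequencing_error_rate outside [0, 0.1]")


@dataclass
class Library:
    """Simulated construct library with its randomized regions."""

    ids: list[str]
    pam7s: list[str]
    sequences: list[str]
    design: ReporterDesign


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def __str__(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{self.quality}\n"


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    bases = np.array(list(DNA))
    return ["".join(row) for row in bases[rng.integers(0, 4, size=(n, k))]]


def _substitute_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.array(list(DNA))
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _apply_indel(seq: str, cut: int, net: int, rng: np.random.Generator) -> str:
    """Apply a net indel at the cut point (see module docstring for placement)."""
    if net > 0:
        insert = "".join(np.array(list(DNA))[rng.integers(0, 4, size=net)])
        return seq[:cut] + insert + seq[cut:]
    d = -net
    left = (d + 1) // 2
    right = d - left
    lo = max(0, cut - left)
    return seq[:lo] + seq[cut + right :]


def simulate_library(config: ScreenSimConfig) -> Library:
    """Draw the construct library: anchors + target + randomized 7-mer + anchor.

    Randomized regions are uniform over 4^7 unless ``enumerate_pams`` cycles
    through all of them in lexicographic order or ``pinned_pam7s`` supplies
    them explicitly.
    """
    design = config.design
    n = config.n_constructs
    if config.pinned_pam7s is not None:
        if len(config.pinned_pam7s) != n:
            raise ValueError("pinned_pam7s length must equal n_constructs")
        pam7s = [p.upper() for p in config.pinned_pam7s]
    elif config.enumerate_pams:
        all_kmers = map("".join, itertools.product(DNA, repeat=design.random_length))
        pam7s = list(itertools.islice(itertools.cycle(all_kmers), n))
    else:
        pam7s = _random_kmers(_rng(config.seed, 0), n, design.random_length)
    ids = [f"construct{i:06d}" for i in range(n)]
    sequences = [design.construct(p) for p in pam7s]
    return Library(ids=ids, pam7s=pam7s, sequences=sequences, design=design)


def _conditional_indel_length(dist: Mapping[int, float], in_frame: bool, rng: np.random.Generator) -> int:
    support = [l for l in dist if (l % 3 == 0) == in_frame]
    if not support:
        raise ValueError("indel_length_distribution has no support for the requested frame class")
    probs = np.array([dist[l] for l in support])
    probs = probs / probs.sum()
    return int(rng.choice(support, p=probs))


def simulate_sorted_reads(
    library: Library,
    model: PamActivityModel,
    config: ScreenSimConfig,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate editing, GFP sorting and sequencing of the library.

    Per construct: cleavage is Bernoulli on the activity of the randomized
    region's first 4 bases; cleaved constructs draw an in-frame repair with
    probability ``editable_fraction`` and a net indel length from the model's
    distribution conditioned on the frame class. Only sorted (cleaved and
    in-frame) constructs emit ``reads_per_construct`` reads, each with
    independent substitution errors.

    Returns the FASTQ records and a truth table with columns construct_id,
    pam7, cleaved, net_indel, sorted, pam_extractable (whether the edited
    construct still carries an intact fixer + randomized region).
    """
    design = library.design
    rng = _rng(config.seed, 1)
    cut = len(design.upstream_anchor) + design.cut_position
    records: list[FastqRecord] = []
    truth_rows = []
    for cid, pam7, seq in zip(library.ids, library.pam7s, library.sequences):
        cleaved = bool(rng.random() < model.cleavage_probability(pam7))
        net = 0
        sorted_flag = False
        extractable = False
        if cleaved:
            in_frame = bool(rng.random() < model.editable_fraction)
            net = _conditional_indel_length(model.indel_length_distribution, in_frame, rng)
            sorted_flag = in_frame
        if sorted_flag:
            edited = _apply_indel(seq, cut, net, rng)
            down = len(design.downstream_anchor)
            tail = edited[: len(edited) - down]
            extractable = (
                len(tail) >= design.random_length + len(design.fixer)
                and tail.endswith(design.fixer + pam7)
            )
            for r in range(config.reads_per_construct):
                read_seq = _substitute_errors(edited, config.sequencing_error_rate, rng)
                records.append(FastqRecord(f"{cid}/read{r:03d}", read_seq, "I" * len(read_seq)))
        truth_rows.append((cid, pam7, cleaved, net, sorted_flag, extractable))
    truth = pd.DataFrame(
        truth_rows,
        columns=["construct_id", "pam7", "cleaved", "net_indel", "sorted", "pam_extractable"],
    )
    if not records:
        warnings.warn("no construct was editable: simulated screen produced zero reads", stacklevel=2)
    return records, truth


def simulate_amplicon_reads(
    target: AmpliconTarget,
    indel_fraction: float,
    conversion_profile: Mapping[int, float],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
    indel_length_distribution: Optional[Mapping[int, float]] = None,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate amplicon deep-sequencing reads with injected outcomes.

    Each read is the reference amplicon carrying, with probability
    ``indel_fraction``, a net indel at the cut site; otherwise each
    protospacer position in ``conversion_profile`` (1-based, PAM-distal
    numbering) is independently converted with its probability. Conversion
    replaces the reference base by its transition partner (C->T, A->G,
    G->A, T->C) on the target strand. Substitution errors are applied last.

    Returns FASTQ records and a truth table (read_id, has_indel, net_indel,
    converted_positions as comma-joined 1-based positions).
    """
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel_fraction outside [0,1]")
    for pos, p in conversion_profile.items():
        if not 1 <= pos <= len(target.protospacer):
            raise ValueError(f"conversion position {pos} outside the protospacer")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"conversion probability for position {pos} outside [0,1]")
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    dist = dict(indel_length_distribution or default_indel_length_distribution())
    rng = _rng(seed, 2)
    ref = target.sequence
    records: list[FastqRecord] = []
    truth_rows = []
    for i in range(n_reads):
        rid = f"read{i:06d}"
        net = 0
        converted: list[int] = []
        if rng.random() < indel_fraction:
            support = sorted(dist)
            probs = np.array([dist[l] for l in support])
            net = int(rng.choice(support, p=probs / probs.sum()))
            seq = _apply_indel(ref, target.cut_site, net, rng)
            has_indel = True
        else:
            arr = list(ref)
            for pos, p in sorted(conversion_profile.items()):
                if rng.random() < p:
                    coord = target.position_to_coord(pos)
                    strand_base = target.strand_base(arr[coord])
                    new_strand_base = transition[strand_base]
                    arr[coord] = target.strand_base(new_strand_base)  # involution maps back to forward
                    converted.append(pos)
            seq = "".join(arr)
            has_indel = False
        seq = _substitute_errors(seq, error_rate, rng)
        records.append(FastqRecord(rid, seq, "I" * len(seq)))
        truth_rows.append((rid, has_indel, net, ",".join(map(str, converted)) or "."))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "has_indel", "net_indel", "converted_positions"])
    return records, truth
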