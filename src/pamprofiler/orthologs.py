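"""Cas9 ortholog reference data: the SaCas9 protein and a SYNTHETIC
S. auricularis-style ortholog stand-in.

``SACAS9_PROTEIN`` is the Staphylococcus aureus Cas9 protein (UniProt
J7RUA5, 1053 aa); its KKH positions are E782/N968/R1015 and its RuvC
catalytic aspartate is D10.

:func:`synthetic_sauricas9` generates a **synthetic** ortholog — it is not
the published S. auricularis Cas9 sequence, which is not distributed with
this package. It is constructed from SaCas9 by a seeded, deterministic edit
process so that its ground truth is known exactly and mirrors the
documented arithmetic of the real ortholog pair:

* 1,061 residues (an N-terminal 5-residue insertion, one internal
  insertion, one internal deletion and a 3-residue C-terminal extension
  relative to SaCas9);
* the RuvC catalytic aspartate lands at position 15 (so D15A builds the
  nickase);
* SaCas9 E782/N968/R1015 align to positions 788/973/1020 carrying Q/Y/R
  (so the KKH transfer is Q788K/Y973K/R1020H) — note the alignment offset
  is +6 at position 782 but +5 at 968/1015, because an indel falls between
  them;
* ~62.4% identity to SaCas9 under the construction alignment
  (389 substituted columns out of 1062).

Tests and the acceptance script exercise translation, alignment, identity,
residue mapping, mutagenesis and chimera construction against this stand-in
because every one of those properties is known by construction.
"""

from __future__ import annotations

import numpy as np

from ._seq import AMINO_ACIDS
from .protein_tools import DomainSpan, ProteinRecord, reverse_translate

#: Staphylococcus aureus Cas9 (UniProt J7RUA5), 1053 aa.
SACAS9_PROTEIN = (
    "MKRNYILGLDIGITSVGYGIIDYETRDVIDAGVRLFKEANVENNEGRRSKRGARRLKRRRRHRIQRVKKLLFDYNLLTDHSELSGINPYEARVKGL"
    "SQKLSEEEFSAALLHLAKRRGVHNVNEVEEDTGNELSTKEQISRNSKALEEKYVAELQLERLKKDGEVRGSINRFKTSDYVKEAKQLLKVQKAYHQ"
    "LDQSFIDTYIDLLETRRTYYEGPGEGSPFGWKDIKEWYEMLMGHCTYFPEELRSVKYAYNADLYNALNDLNNLVITRDENEKLEYYEKFQIIENVF"
    "KQKKKPTLKQIAKEILVNEEDIKGYRVTSTGKPEFTNLKVYHDIKDITARKEIIENAELLDQIAKILTIYQSSEDIQEELTNLNSELTQEEIEQIS"
    "NLKGYTGTHNLSLKAINLILDELWHTNDNQIAIFNRLKLVPKKVDLSQQKEIPTTLVDDFILSPVVKRSFIQSIKVINAIIKKYGLPNDIIIELAR"
    "EKNSKDAQKMINEMQKRNRQTNERIEEIIRTTGKENAKYLIEKIKLHDMQEGKCLYSLEAIPLEDLLNNPFNYEVDHIIPRSVSFDNSFNNKVLVK"
    "QEENSKKGNRTPFQYLSSSDSKISYETFKKHILNLAKGKGRISKTKKEYLLEERDINRFSVQKDFINRNLVDTRYATRGLMNLLRSYFRVNNLDVK"
    "VKSINGGFTSFLRRKWKFKKERNKGYKHHAEDALIIANADFIFKEWKKLDKAKKVMENQMFEEKQAESMPEIETEQEYKEIFITPHQIKHIKDFKD"
    "YKYSHRVDKKPNRELINDTLYSTRKDDKGNTLIVNNLNGLYDKDNDKLKKLINKSPEKLLMYHHDPQTYQKLKLIMEQYGDEKNPLYKYYEETGNY"
    "LTKYSKKDNGPVIKKIKYYGNKLNAHLDITDDYPNSRNKVVKLSLKPYRFDVYLDNGVYKFVTVKNLDVIKKENYYEVNSKCYEEAKKLKKISNQA"
    "EFIASFYNNDLIKINGELYRVIGVNNDLLNRIEVNMIDITYREYLENMNDKRPPRIIKTIASKTQSIKKYSTDILGNLYEVKSKKHPQIIKKG"
)

#: KKH positions and the RuvC catalytic aspartate on SaCas9 (1-based).
SACAS9_KKH_POSITIONS = (782, 968, 1015)
SACAS9_CATALYTIC_D = 10

#: Nominal C-terminal PAM-interacting-domain span on SaCas9 (user-adjustable;
#: domain boundaries are an input, not something this package detects).
SACAS9_PID_SPAN = DomainSpan("PID", 910, 1053)

# --- construction constants of the synthetic ortholog (0-based SaCas9 indices)
_INS_NTERM = 5          # inserted after SaCas9 residue 1
_INS_MID_AFTER = 400    # 1 residue inserted after this index
_DEL_AT = 849           # this SaCas9 residue is deleted
_INS_CTERM = 3          # appended at the C terminus
_N_SUBSTITUTED_COLUMNS = 389  # total mismatch columns (incl. the 2 forced)
_DEFAULT_SEED = 2020


def sacas9() -> ProteinRecord:
    return ProteinRecord(name="SaCas9", sequence=SACAS9_PROTEIN)


def _sa_index_to_synthetic_position(sa_index: int) -> int:
    """1-based synthetic position of 0-based SaCas9 index (construction map)."""
    if sa_index == _DEL_AT:
        raise ValueError("residue deleted in the synthetic ortholog")
    offset = 0 if sa_index == 0 else _INS_NTERM
    if sa_index > _INS_MID_AFTER:
        offset += 1
    if sa_index > _DEL_AT:
        offset -= 1
    return sa_index + offset + 1


def synthetic_ortholog_truth() -> dict:
    """Ground truth of the synthetic ortholog pair, by construction."""
    residue_pairs = len(SACAS9_PROTEIN) - 1          # one SaCas9 residue is deleted
    gap_columns = _INS_NTERM + 1 + _INS_CTERM + 1    # insertions + the deletion column
    columns = residue_pairs + gap_columns
    return {
        "length": len(SACAS9_PROTEIN) + _INS_NTERM + 1 - 1 + _INS_CTERM,
        "catalytic_d_position": _sa_index_to_synthetic_position(SACAS9_CATALYTIC_D - 1),
        "kkh_positions": {p: _sa_index_to_synthetic_position(p - 1) for p in SACAS9_KKH_POSITIONS},
        "designed_identity_pct": 100.0 * (residue_pairs - _N_SUBSTITUTED_COLUMNS) / columns,
        "alignment_columns": columns,
    }


def synthetic_sauricas9(seed: int = _DEFAULT_SEED, with_orf: bool = True) -> ProteinRecord:
    """Deterministic SYNTHETIC S. auricularis-style Cas9 stand-in.

    See the module docstring: this is a seeded mutagenesis/indel edit of
    SaCas9 with known ground truth, not the published sequence. The default
    seed is part of the stand-in's definition; change it only if you want a
    different random realisation of the same design.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    sa = SACAS9_PROTEIN

    def random_residues(n: int) -> str:
        return "".join(aa[rng.integers(0, 20, size=n)])

    # indel scaffold (offsets chosen so the documented landmarks line up)
    pieces = [
        sa[0],
        random_residues(_INS_NTERM),
        sa[1 : _INS_MID_AFTER + 1],
        random_residues(1),
        sa[_INS_MID_AFTER + 1 : _DEL_AT],
        sa[_DEL_AT + 1 :],
        random_residues(_INS_CTERM),
    ]
    seq = list("".join(pieces))

    # forced landmark substitutions: E782->Q, N968->Y (R1015 and D10 are kept)
    forced = {
        _sa_index_to_synthetic_position(781) - 1: "Q",
        _sa_index_to_synthetic_position(967) - 1: "Y",
    }
    for idx, res in forced.items():
        seq[idx] = res

    # positions protected from random substitution: landmarks plus small
    # windows around each landmark and indel, to pin the optimal alignment
    protected: set[int] = set()
    for sa_idx in (0, SACAS9_CATALYTIC_D - 1, 781, 967, 1014):
        protected.update(range(sa_idx - 4, sa_idx + 5))
    for sa_idx in (_INS_MID_AFTER, _DEL_AT):
        protected.update(range(sa_idx - 5, sa_idx + 6))
    protected.update(range(len(sa) - 5, len(sa)))
    candidates = [i for i in range(len(sa)) if i != _DEL_AT and i not in protected]

    n_random = _N_SUBSTITUTED_COLUMNS - len(forced)
    chosen = rng.choice(len(candidates), size=n_random, replace=False)
    for c in sorted(chosen):
        sa_idx = candidates[c]
        pos = _sa_index_to_synthetic_position(sa_idx) - 1
        original = seq[pos]
        options = aa[aa != original]
        seq[pos] = options[rng.integers(0, len(options))]

    sequence = "".join(seq)
    orf = reverse_translate(sequence) if with_orf else None
    return ProteinRecord(name="SauriCas9-synthetic", sequence=sequence, orf=orf)


def synthetic_sauricas9_orf(seed: int = _DEFAULT_SEED) -> str:
    """ORF (with terminal stop) of the synthetic ortholog stand-in."""
    return synthetic_sauricas9(seed).orf
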