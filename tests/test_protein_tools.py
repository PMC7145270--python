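"""Protein arithmetic: translation, affine global alignment vs an
independent DP oracle, residue mapping, mutagenesis and chimeras."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from pamprofiler import (
    DomainSpan,
    ProteinRecord,
    apply_mutations,
    build_chimera,
    global_align,
    map_residue,
    parse_mutations,
    translate_orf,
)
from pamprofiler.orthologs import (
    SACAS9_PID_SPAN,
    sacas9,
    synthetic_ortholog_truth,
    synthetic_sauricas9,
)
from pamprofiler.protein_tools import reverse_translate

AA = "ACDEFGHIKLMNPQRSTVWY"
protein_seq = st.text(alphabet=AA, min_size=1, max_size=60)


class TestTranslation:
    @pytest.mark.parametrize("orf,expected", [("ATGGATTAA", "MD"), ("ATGTAA", "M")])
    def test_standard_code(self, orf, expected):
        assert translate_orf(orf).sequence == expected

    def test_length_not_multiple_of_three_is_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate_orf("ATGGA")

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate_orf("ATGTAAGATTAA")

    def test_missing_terminal_stop_is_error(self):
        with pytest.raises(ValueError, match="stop codon"):
            translate_orf("ATGGAT")

    @given(protein_seq)
    @settings(max_examples=50, deadline=None)
    def test_reverse_translation_round_trips(self, seq):
        assert translate_orf(reverse_translate(seq)).sequence == seq


class TestGlobalAlign:
    def test_identical_sequences_are_100_pct_without_gaps(self):
        a = ProteinRecord("a", "MKVLHEQ")
        aln = global_align(a, ProteinRecord("b", "MKVLHEQ"))
        assert aln.identity_pct == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_deletion_example(self):
        aln = global_align(ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACE"))
        assert aln.aligned_a == "ACDE"
        assert aln.aligned_b.count("-") == 1
        mat = substitution_matrices.load("BLOSUM62")
        expected = _oracles.affine_global_score(
            "ACDE", "ACE", lambda x, y: float(mat[x, y]), gap_open=10.0, gap_extend=1.0
        )
        assert math.isclose(aln.score, expected)

    def test_score_matches_gotoh_oracle_on_random_pairs(self):
        """100 random pairs up to 60 aa: optimal score equals an independent
        quadratic-time Gotoh implementation."""
        rng = np.random.default_rng(11)
        mat = substitution_matrices.load("BLOSUM62")

        def score(x, y):
            return float(mat[x, y])

        aa = np.array(list(AA))
        for trial in range(100):
            a = "".join(aa[rng.integers(0, 20, size=rng.integers(1, 61))])
            b = "".join(aa[rng.integers(0, 20, size=rng.integers(1, 61))])
            aln = global_align(ProteinRecord("a", a), ProteinRecord("b", b))
            assert math.isclose(
                aln.score, _oracles.affine_global_score(a, b, score, 10.0, 1.0)
            ), f"trial {trial}: {a} vs {b}"

    @given(protein_seq, protein_seq)
    @settings(max_examples=30, deadline=None)
    def test_identity_is_symmetric(self, a, b):
        fwd = global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        rev = global_align(ProteinRecord("b", b), ProteinRecord("a", a))
        assert math.isclose(fwd.identity_pct, rev.identity_pct, abs_tol=1e-9)

    def test_degapped_rows_equal_inputs_and_pairs_increase(self):
        aln = global_align(ProteinRecord("a", "MKVLHEQWYA"), ProteinRecord("b", "MKVHEWYA"))
        assert aln.aligned_a.replace("-", "") == "MKVLHEQWYA"
        assert aln.aligned_b.replace("-", "") == "MKVHEWYA"
        for (i1, j1), (i2, j2) in zip(aln.pairs, aln.pairs[1:]):
            assert i2 > i1 and j2 > j1


class TestResidueMapping:
    def test_self_alignment_is_identity_mapping(self):
        a = ProteinRecord("a", "MKVLHEQ")
        aln = global_align(a, a)
        for pos in range(1, 8):
            assert map_residue(aln, "a", pos).mapped == pos

    def test_mapping_is_inverse_consistent(self):
        aln = global_align(ProteinRecord("a", "MKVLHEQWYAD"), ProteinRecord("b", "MKVHEWYACD"))
        for i, j in aln.pairs:
            assert map_residue(aln, "a", i).mapped == j
            assert map_residue(aln, "b", j).mapped == i

    def test_gap_reports_flanking_positions(self):
        aln = global_align(ProteinRecord("a", "MKVLHEQ"), ProteinRecord("b", "MKVHEQ"))
        gapped = [i for i in range(1, 8) if map_residue(aln, "a", i).mapped is None]
        assert len(gapped) == 1
        m = map_residue(aln, "a", gapped[0])
        assert m.flank_left is not None and m.flank_right is not None
        assert m.flank_right == m.flank_left + 1


class TestMutagenesis:
    def test_point_mutation_applied(self):
        protein = ProteinRecord("p", "MKVLHEQWYADSTRVD")
        mutated = apply_mutations(protein, "D11A")
        assert mutated.sequence[10] == "A"
        assert len(mutated) == len(protein)

    def test_empty_spec_is_identity(self):
        protein = ProteinRecord("p", "MKVL")
        assert apply_mutations(protein, "").sequence == protein.sequence

    def test_reference_mismatch_names_position_and_residue(self):
        protein = ProteinRecord("p", "MKEL")
        with pytest.raises(ValueError, match="expected D at position 3, found E"):
            apply_mutations(protein, "D3A")

    def test_parse_kkh_style_spec(self):
        muts = parse_mutations("Q788K/Y973K/R1020H")
        assert [(m.reference, m.position, m.replacement) for m in muts] == [
            ("Q", 788, "K"), ("Y", 973, "K"), ("R", 1020, "H"),
        ]


class TestChimera:
    def test_self_swap_is_identity(self):
        p = ProteinRecord("p", "MKVLHEQWYAD")
        span = DomainSpan("PID", 4, 8)
        assert build_chimera(p, span, p, span).sequence == p.sequence

    @given(protein_seq, protein_seq, st.data())
    @settings(max_examples=30, deadline=None)
    def test_length_arithmetic_on_random_spans(self, a, b, data):
        pa, pb = ProteinRecord("a", a), ProteinRecord("b", b)
        sa_start = data.draw(st.integers(1, len(a)))
        sa_end = data.draw(st.integers(sa_start, len(a)))
        sb_start = data.draw(st.integers(1, len(b)))
        sb_end = data.draw(st.integers(sb_start, len(b)))
        span_a, span_b = DomainSpan("x", sa_start, sa_end), DomainSpan("y", sb_start, sb_end)
        chimera = build_chimera(pa, span_a, pb, span_b)
        assert len(chimera) == len(pa) - (sa_end - sa_start + 1) + (sb_end - sb_start + 1)

    def test_round_trip_restores_backbone(self):
        backbone = ProteinRecord("bb", "MKVLHEQWYADSTRV")
        donor = ProteinRecord("d", "GGGPPPLLL")
        b_span, d_span = DomainSpan("dom", 5, 9), DomainSpan("dom", 2, 7)
        chimera = build_chimera(backbone, b_span, donor, d_span)
        # the spliced-in region sits at backbone positions 5..(5+len-1)
        spliced = DomainSpan("dom", 5, 5 + (d_span.end - d_span.start))
        restored = build_chimera(chimera, spliced, backbone, b_span)
        assert restored.sequence == backbone.sequence

    def test_span_outside_protein_rejected(self):
        with pytest.raises(ValueError):
            DomainSpan("x", 2, 10).validate(ProteinRecord("p", "MKV"))


class TestSyntheticOrthologPair:
    """The bundled SaCas9 vs the synthetic S. auricularis-style stand-in,
    whose alignment arithmetic is known by construction."""

    def test_stand_in_has_designed_landmarks(self):
        sauri = synthetic_sauricas9()
        truth = synthetic_ortholog_truth()
        assert len(sauri) == truth["length"] == 1061
        assert sauri.residue(truth["catalytic_d_position"]) == "D"
        assert sauri.residue(788) == "Q"
        assert sauri.residue(973) == "Y"
        assert sauri.residue(1020) == "R"

    def test_orf_translates_to_the_stand_in(self):
        sauri = synthetic_sauricas9()
        assert translate_orf(sauri.orf).sequence == sauri.sequence

    def test_alignment_recovers_designed_identity_and_mapping(self):
        sauri, sa = synthetic_sauricas9(), sacas9()
        truth = synthetic_ortholog_truth()
        aln = global_align(sauri, sa)
        assert abs(aln.identity_pct - truth["designed_identity_pct"]) < 1.5
        for sa_pos, sauri_pos in truth["kkh_positions"].items():
            assert map_residue(aln, "b", sa_pos).mapped == sauri_pos

    def test_kkh_and_nickase_mutations_apply_cleanly(self):
        sauri = synthetic_sauricas9()
        kkh = apply_mutations(sauri, "Q788K/Y973K/R1020H")
        assert kkh.sequence[787] == "K" and kkh.sequence[972] == "K" and kkh.sequence[1019] == "H"
        nickase = apply_mutations(sauri, "D15A")
        assert nickase.sequence[14] == "A"

    def test_pid_swap_chimera_length(self):
        sauri, sa = synthetic_sauricas9(), sacas9()
        aln = global_align(sa, sauri)
        donor_start = map_residue(aln, "a", SACAS9_PID_SPAN.start).mapped
        assert donor_start is not None
        donor_span = DomainSpan("PID", donor_start, len(sauri))
        chimera = build_chimera(sa, SACAS9_PID_SPAN, sauri, donor_span)
        expected = len(sa) - (SACAS9_PID_SPAN.end - SACAS9_PID_SPAN.start + 1) + (len(sauri) - donor_start + 1)
        assert len(chimera) == expected
        # backbone N-terminus untouched
        assert chimera.sequence[: SACAS9_PID_SPAN.start - 1] == sa.sequence[: SACAS9_PID_SPAN.start - 1]
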