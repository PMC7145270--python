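"""PAM-discovery stage: anchor location, classification, extraction,
tallies, profiles, information content, wheel and consensus."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from pamprofiler import (
    PamActivityModel,
    PamCounts,
    ReporterDesign,
    ScreenSimConfig,
    build_pam_wheel,
    call_consensus,
    classify_read,
    classify_reads,
    discover,
    extract_pam7,
    information_content,
    locate_anchors,
    pam_table,
    position_frequencies,
    simulate_library,
    simulate_sorted_reads,
    tally_pams,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


class TestDesign:
    def test_default_design_matches_reporter_layout(self, design):
        assert design.target.endswith("GCG")
        assert len(design.upstream_anchor) == len(design.downstream_anchor) == 20
        assert design.inner_reference_length == 32

    @pytest.mark.parametrize("field,value", [
        ("target", "GAACGGCTCGGAGATCATCATTGCA"),  # does not end with fixer
        ("random_length", 3),
        ("upstream_anchor", ""),
    ])
    def test_invalid_designs_rejected(self, field, value):
        with pytest.raises(ValueError):
            ReporterDesign(**{field: value})


class TestLocateAnchors:
    def test_exact_anchors_return_inner(self, design):
        read = design.construct("TCTGGAA")
        assert locate_anchors(read, design, 0) == design.target + "TCTGGAA"

    def test_missing_downstream_anchor_is_unanchored(self, design):
        read = design.upstream_anchor + design.target + "TCTGGAA"
        assert locate_anchors(read, design, 1) is None

    def test_one_substitution_tolerated_only_when_allowed(self, design):
        up = "C" + design.upstream_anchor[1:]
        read = up + design.target + "TCTGGAA" + design.downstream_anchor
        assert locate_anchors(read, design, 1) == design.target + "TCTGGAA"
        assert locate_anchors(read, design, 0) is None

    @given(prefix=dna, suffix=dna, pam=st.text(alphabet="ACGT", min_size=7, max_size=7))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_sliding_hamming_oracle(self, prefix, suffix, pam):
        design = ReporterDesign()
        read = prefix + design.construct(pam) + suffix
        inner = locate_anchors(read, design, 1)
        up = _oracles.sliding_hamming_find(read, design.upstream_anchor, 1)
        down = _oracles.sliding_hamming_find(read, design.downstream_anchor, 1, up + 20)
        expected = read[up + 20 : down] if up >= 0 and down >= 0 else None
        assert inner == expected


class TestClassifyAndExtract:
    def test_wildtype_read(self, design):
        inner = design.target + "TCTGGAA"
        c = classify_read(inner, design)
        assert c.frame_class == "wildtype" and c.net_indel == 0 and c.pam7 == "TCTGGAA"

    def test_inframe_deletion_upstream_of_fixer(self, design):
        inner = design.target[:10] + design.target[13:] + "TCTGGAA"
        c = classify_read(inner, design)
        assert c.frame_class == "in_frame_edit" and c.net_indel == -3
        assert c.pam7 == "TCTGGAA"

    def test_plus_two_insertion_is_frameshift(self, design):
        inner = design.target[:10] + "AT" + design.target[10:] + "TCTGGAA"
        assert classify_read(inner, design).frame_class == "frameshift"

    def test_deletion_destroying_fixer_yields_absent_pam(self, design):
        # remove the fixer and the first 2 random bases: -5 net, unextractable
        inner = design.target[:-3] + "TGGAA"
        assert extract_pam7(inner, design) is None
        c = classify_read(inner, design)
        assert c.pam7 is None

    def test_extraction_requires_exact_fixer(self, design):
        inner = design.target[:-3] + "GAG" + "TCTGGAA"
        assert extract_pam7(inner, design) is None

    def test_non_acgt_in_random_region_is_absent(self, design):
        assert extract_pam7(design.target + "TCTGGAN", design) is None


class TestTally:
    def test_only_in_frame_reads_counted(self, design):
        full = design.construct("TCTGGAA")
        reads = (
            [full[:30] + full[33:]] * 3  # -3 bp deletion inside the target
            + [design.upstream_anchor + design.target[:-1] + "TATAAAT" + design.downstream_anchor] * 5
        )
        cls = classify_reads(reads, design)
        assert Counter(c.frame_class for c in cls) == {"in_frame_edit": 3, "frameshift": 5}
        counts = tally_pams(cls, k=4)
        assert counts.counts == {"TCTG": 3}
        assert counts.total == 3

    def test_all_wildtype_totals_zero(self, design):
        reads = [design.construct("ACGTACG")] * 4
        counts = tally_pams(classify_reads(reads, design), k=4)
        assert counts.total == 0

    def test_enumerated_in_frame_library_counts_each_4mer_64_times(self, design):
        classifications = []
        from pamprofiler.reporter_pam import ReadClassification

        for kmer in map("".join, itertools.product("ACGT", repeat=7)):
            classifications.append(
                ReadClassification(anchored=True, net_indel=3, frame_class="in_frame_edit", pam7=kmer)
            )
        counts = tally_pams(classifications, k=4)
        assert set(counts.counts.values()) == {64}
        assert counts.total == 16384

    def test_k_above_random_length_rejected(self):
        with pytest.raises(ValueError):
            tally_pams([], k=8, random_length=7)


class TestProfileAndInformation:
    def test_single_kmer_profile_is_degenerate(self):
        counts = PamCounts(k=2, counts=Counter({"GG": 2}))
        profile = position_frequencies(counts, pseudocount=0.0)
        assert profile.frequencies.loc[1, "G"] == 1.0
        assert profile.frequencies.loc[2, "G"] == 1.0
        assert np.allclose(information_content(profile), [2.0, 2.0])

    def test_half_half_column_is_one_bit(self):
        counts = PamCounts(k=2, counts=Counter({"AG": 1, "CG": 1}))
        profile = position_frequencies(counts, pseudocount=0.0)
        assert profile.frequencies.loc[1, "A"] == 0.5
        assert profile.frequencies.loc[1, "C"] == 0.5
        ic = information_content(profile)
        assert math.isclose(ic[0], 1.0)
        assert math.isclose(ic[1], 2.0)

    def test_uniform_column_is_zero_bits(self):
        counts = PamCounts(k=1, counts=Counter({"A": 1, "C": 1, "G": 1, "T": 1}))
        ic = information_content(position_frequencies(counts, pseudocount=0.0))
        assert math.isclose(ic[0], 0.0, abs_tol=1e-12)

    @given(st.dictionaries(
        st.text(alphabet="ACGT", min_size=3, max_size=3),
        st.integers(min_value=1, max_value=50),
        min_size=1, max_size=20,
    ))
    @settings(max_examples=50, deadline=None)
    def test_columns_always_sum_to_one(self, raw):
        counts = PamCounts(k=3, counts=Counter(raw))
        profile = position_frequencies(counts, pseudocount=0.5)
        assert np.allclose(profile.frequencies.sum(axis=1), 1.0)
        ic = information_content(profile)
        assert np.all(ic >= -1e-9) and np.all(ic <= 2 + 1e-9)

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            position_frequencies(PamCounts(k=2, counts=Counter()))

    def test_enrichment_against_uniform_and_presort(self):
        counts = PamCounts(k=2, counts=Counter({"GG": 30, "AA": 10}))
        table = pam_table(counts).set_index("kmer")
        assert math.isclose(table.loc["GG", "enrichment"], 0.75 * 16)
        presort = {"GG": 50, "AA": 50}
        table2 = pam_table(counts, presort=presort).set_index("kmer")
        assert math.isclose(table2.loc["GG", "enrichment"], 0.75 / 0.5)


class TestWheel:
    def test_two_kmer_wheel_structure(self):
        counts = PamCounts(k=4, counts=Counter({"AAGG": 50, "ACGG": 50}))
        root = build_pam_wheel(counts)
        a = root.children["A"]
        assert a.count == 100 and math.isclose(a.conditional_fraction, 1.0)
        assert a.children["A"].count == 50 and math.isclose(a.children["A"].conditional_fraction, 0.5)
        assert a.children["C"].count == 50

    @given(st.dictionaries(
        st.text(alphabet="ACGT", min_size=4, max_size=4),
        st.integers(min_value=1, max_value=99),
        min_size=1, max_size=40,
    ))
    @settings(max_examples=50, deadline=None)
    def test_wheel_round_trips_and_conserves_counts(self, raw):
        counts = PamCounts(k=4, counts=Counter(raw))
        root = build_pam_wheel(counts)
        assert root.leaves("") == dict(counts.counts)
        # each internal node's count equals the sum of its children
        stack = [root]
        while stack:
            node = stack.pop()
            if node.children:
                assert node.count == sum(c.count for c in node.children.values())
                stack.extend(node.children.values())

    def test_wheel_marginals_match_profile(self):
        counts = PamCounts(k=3, counts=Counter({"AGG": 5, "CGG": 3, "CGT": 2}))
        root = build_pam_wheel(counts)
        profile = position_frequencies(counts, pseudocount=0.0)
        # marginal base frequency at each depth from the wheel
        for depth in range(1, 4):
            marg = Counter()
            stack = [root]
            while stack:
                node = stack.pop()
                if node.depth == depth:
                    marg[node.base] += node.count
                else:
                    stack.extend(node.children.values())
            for base in "ACGT":
                assert math.isclose(profile.frequencies.loc[depth, base], marg[base] / counts.total)


class TestConsensus:
    def test_strong_g_positions_with_uniform_head_is_nngg(self):
        counts = Counter()
        for first in itertools.product("ACGT", repeat=2):
            counts["".join(first) + "GG"] += 24  # 0.96 G at 3-4
            counts["".join(first) + "AT"] += 1
        profile = position_frequencies(PamCounts(k=4, counts=counts), pseudocount=0.0)
        assert call_consensus(profile) == "NNGG"

    def test_uniform_profile_is_all_n(self):
        counts = Counter("".join(p) for p in itertools.product("ACGT", repeat=2))
        profile = position_frequencies(PamCounts(k=2, counts=counts), pseudocount=0.0)
        assert call_consensus(profile) == "NN"

    def test_purine_split_calls_r(self):
        counts = Counter({"A": 45, "G": 45, "C": 5, "T": 5})
        profile = position_frequencies(PamCounts(k=1, counts=counts), pseudocount=0.0)
        assert call_consensus(profile, strong_threshold=0.8, pair_threshold=0.8) == "R"

    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=4, max_size=4),
           st.floats(min_value=0.5, max_value=1.0), st.floats(min_value=0.5, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_subset_oracle(self, weights, strong, pair):
        freqs = dict(zip("ACGT", np.array(weights) / sum(weights)))
        counts = PamCounts(k=1, counts=Counter({b: 1 for b in "ACGT"}))
        profile = position_frequencies(counts, pseudocount=0.0)
        profile.frequencies.loc[1] = [freqs[b] for b in "ACGT"]
        assert call_consensus(profile, strong, pair) == _oracles.minimal_iupac_consensus(freqs, strong, pair)

    def test_threshold_bounds_enforced(self):
        counts = PamCounts(k=1, counts=Counter({"A": 1}))
        profile = position_frequencies(counts, pseudocount=0.0)
        with pytest.raises(ValueError):
            call_consensus(profile, strong_threshold=0.2)


class TestEndToEnd:
    def test_filter_total_matches_simulator_truth(self, design):
        """Tally total equals reads from sorted constructs whose randomized
        region survived the repair outcome (oracle from the truth table)."""
        model = PamActivityModel({}, default_weight=0.6, editable_fraction=0.5)
        cfg = ScreenSimConfig(design=design, n_constructs=1500, reads_per_construct=3,
                              sequencing_error_rate=0.0, seed=11)
        reads, truth = simulate_sorted_reads(simulate_library(cfg), model, cfg)
        counts = tally_pams(classify_reads([r.sequence for r in reads], design), k=4)
        expected = int((truth["sorted"] & truth["pam_extractable"]).sum()) * cfg.reads_per_construct
        assert counts.total == expected

    def test_mixed_weight_activity_recovered_by_read_fractions(self, design):
        """Per-4-mer read fractions correlate with injected cleavage weights
        (Pearson r > 0.9 at ~50,000 reads)."""
        rng = np.random.default_rng(12)
        weights = {
            "".join(k): float(w)
            for k, w in zip(itertools.product("ACGT", repeat=4), rng.uniform(0.05, 1.0, 256))
        }
        model = PamActivityModel(weights, editable_fraction=1.0)
        # 3x-enumerated library at 2 reads/construct: ~50k reads with little
        # per-construct read clustering, so sampling noise stays below signal
        cfg = ScreenSimConfig(design=design, n_constructs=49152, reads_per_construct=2,
                              sequencing_error_rate=0.0, seed=13, enumerate_pams=True)
        reads, _ = simulate_sorted_reads(simulate_library(cfg), model, cfg)
        assert len(reads) > 40000
        counts = tally_pams(classify_reads([r.sequence for r in reads], design), k=4)
        kmers = sorted(weights)
        observed = np.array([counts.counts.get(k, 0) for k in kmers], dtype=float)
        injected = np.array([weights[k] for k in kmers])
        r = np.corrcoef(observed / observed.sum(), injected / injected.sum())[0, 1]
        assert r > 0.9
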