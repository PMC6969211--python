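"""Activation-segment, AL/HM site and triad-mapping behaviour.

The AL worked examples use the wild-type and S227D mutant RSK2
activation-loop peptides (HEKKAYSFCGTV / HEKKAYDFCGTV), i.e. the region
around Ser227 where the S/T-x-x-G-T consensus reads SFCGT.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agcphos.motifs import (
    SiteKind,
    State,
    classify_kinome,
    classify_residue,
    find_activation_segment,
    locate_al_site,
    locate_hm_site,
    map_reference_positions,
)
from agcphos.seqio import Alignment, KinaseSeq

AL_WT = "HEKKAYSFCGTV"  # wild-type RSK2 AL peptide, consensus SFCGT
AL_SD = "HEKKAYDFCGTV"  # S->D phosphomimetic mutant of the same peptide


def domain_with(peptide: str, pad: str = "AA") -> KinaseSeq:
    """Embed an AL peptide in a minimal DFG..APE activation segment."""
    return KinaseSeq(id="k", residues="DFG" + pad + peptide + pad + "APE")


class TestClassifyResidue:
    @pytest.mark.parametrize(
        "aa,state",
        [(a, State.PHOSPHORYLATABLE) for a in "ST"]
        + [(a, State.PHOSPHOMIMETIC) for a in "DE"]
        + [(a, State.OTHER) for a in "ACFGHIKLMNPQRVWYX"],
    )
    def test_partitions_the_alphabet(self, aa, state):
        assert classify_residue(aa) is state

    @pytest.mark.parametrize("bad", ["B", "1", "", "SS", "s"])
    def test_rejects_non_residues(self, bad):
        with pytest.raises(ValueError):
            classify_residue(bad)


class TestActivationSegment:
    def test_minimal_25_residue_segment(self):
        # DFG + 19 arbitrary residues + APE: inclusive span of 25, the
        # shortest activation segment in the family (PKAalpha)
        seq = KinaseSeq(id="k", residues="DFG" + "A" * 19 + "APE")
        seg = find_activation_segment(seq)
        assert seg is not None and seg.length == 25
        assert seg.dfg_start == 0 and seg.ape_end == 24

    def test_no_dfg_is_absent(self):
        assert find_activation_segment(KinaseSeq(id="k", residues="MKRH" * 20)) is None

    def test_no_downstream_ape_is_absent(self):
        assert find_activation_segment(KinaseSeq(id="k", residues="DFG" + "K" * 40)) is None

    def test_too_close_ape_skipped_for_next(self):
        # first APE-like triplet gives length < 20; the next one is taken
        seq = KinaseSeq(id="k", residues="DFG" + "K" * 5 + "APE" + "K" * 10 + "APE")
        seg = find_activation_segment(seq)
        assert seg is not None and seg.length == 24

    def test_degenerate_ape_terminator_accepted(self):
        seq = KinaseSeq(id="k", residues="DFG" + "K" * 19 + "SVE")
        seg = find_activation_segment(seq)
        assert seg is not None and seg.length == 25

    @settings(max_examples=50, derandomize=True)
    @given(gap=st.integers(min_value=17, max_value=55))
    def test_length_invariant(self, gap):
        seq = KinaseSeq(id="k", residues="MKR" + "DFG" + "A" * gap + "APE" + "MKR")
        seg = find_activation_segment(seq)
        if seg is not None:
            assert seg.length == seg.ape_end - seg.dfg_start + 1
            assert 20 <= seg.length <= 60
        else:
            assert gap + 6 > 60 or gap + 6 < 20


class TestALSite:
    def test_wild_type_peptide_is_phosphorylatable(self):
        seq = domain_with(AL_WT)
        seg = find_activation_segment(seq)
        call = locate_al_site(seq, seg)
        assert call.state is State.PHOSPHORYLATABLE
        assert seq.residues[call.position] == "S"
        assert "SFCGT" in call.context

    def test_mutant_peptide_needs_the_column_hint(self):
        seq = domain_with(AL_SD)
        seg = find_activation_segment(seq)
        assert locate_al_site(seq, seg).state is State.ABSENT
        msa = Alignment(rows=[(seq.id, seq.residues)])
        hint = seq.residues.index("D", 3)  # the substituted site
        call = locate_al_site(seq, seg, column_hint=hint, msa=msa)
        assert call.state is State.PHOSPHOMIMETIC and call.residue == "D"

    def test_hinted_other_residue(self):
        seq = domain_with("HEKKAYAFCGAV")  # no consensus anywhere
        seg = find_activation_segment(seq)
        msa = Alignment(rows=[(seq.id, seq.residues)])
        call = locate_al_site(seq, seg, column_hint=11, msa=msa)
        assert call.state is State.OTHER

    def test_consensus_has_priority_over_hint(self):
        seq = domain_with(AL_WT)
        seg = find_activation_segment(seq)
        msa = Alignment(rows=[(seq.id, seq.residues)])
        hinted = locate_al_site(seq, seg, column_hint=0, msa=msa)
        unhinted = locate_al_site(seq, seg)
        assert hinted == unhinted
        assert hinted.residue == "S"

    def test_hint_outside_alignment_is_error(self):
        seq = domain_with(AL_SD)
        seg = find_activation_segment(seq)
        msa = Alignment(rows=[(seq.id, seq.residues)])
        with pytest.raises(IndexError):
            locate_al_site(seq, seg, column_hint=msa.length + 5, msa=msa)

    def test_rightmost_match_wins(self):
        # two consensus instances inside one segment: the one nearest the
        # APE end (where the AL site sits) must be reported
        peptide = "SAAGT" + "AAA" + "TAAGT"
        seq = KinaseSeq(id="k", residues="DFG" + "AAA" + peptide + "AAAA" + "APE")
        seg = find_activation_segment(seq)
        call = locate_al_site(seq, seg)
        assert call.residue == "T"
        assert call.position == seq.residues.rindex("TAAGT")


class TestHMSite:
    def test_phosphorylatable_hm(self):
        seq = KinaseSeq(id="k", residues="MKRH" * 10 + "QLGKWVRKEAFLGFSFA")
        call = locate_hm_site(seq)
        assert call.state is State.PHOSPHORYLATABLE and call.residue == "S"

    def test_phosphomimetic_hm(self):
        seq = KinaseSeq(id="k", residues="MKRH" * 10 + "QLGKWVRKEAFLGFDFA")
        call = locate_hm_site(seq)
        assert call.state is State.PHOSPHOMIMETIC and call.residue == "D"

    def test_absent_hm(self):
        seq = KinaseSeq(id="k", residues="MKRH" * 20)
        assert locate_hm_site(seq).state is State.ABSENT

    def test_truncated_head_at_extreme_terminus(self):
        # the PKA situation: F-x-x-F right at the C-terminus, phospho
        # position missing entirely
        seq = KinaseSeq(id="k", residues="MKRH" * 10 + "AAKWNVRTEF")
        call = locate_hm_site(KinaseSeq(id="k", residues=seq.residues[:-1] + "FTEF"))
        assert call.truncated and call.state is State.OTHER
        assert call.position is not None

    def test_window_restricts_the_scan(self):
        seq = KinaseSeq(id="k", residues="FLGFSFA" + "MKRH" * 30)
        assert locate_hm_site(seq, tail_window=60).state is State.ABSENT

    def test_tiny_window_is_error(self):
        with pytest.raises(ValueError):
            locate_hm_site(KinaseSeq(id="k", residues="FLGFSFA"), tail_window=6)


class TestTriadMapping:
    def test_gap_row_maps_to_gap(self):
        msa = Alignment(rows=[("r1", "AR-K"), ("r2", "A-QK")])
        calls = map_reference_positions(msa, "r1", [1], site_names=("R114_site",))
        assert calls["r1"][0].mapped_residue == "R" and calls["r1"][0].is_basic
        assert calls["r2"][0].mapped_residue == "-" and not calls["r2"][0].is_basic

    def test_row_order_invariance(self):
        rows = [("a", "ARQK"), ("b", "AHQK"), ("c", "AMQK")]
        m1 = Alignment(rows=rows)
        m2 = Alignment(rows=rows[::-1])
        c1 = map_reference_positions(m1, "a", [1, 3])
        c2 = map_reference_positions(m2, "a", [1, 3])
        assert c1 == c2

    def test_histidine_counts_as_basic(self):
        # the PKA case: His87 occupies the alpha-C-helix site and counts as
        # a positively charged homologue
        msa = Alignment(rows=[("rsk2", "AR"), ("pka", "AH")])
        calls = map_reference_positions(msa, "rsk2", [1])
        assert calls["pka"][0].mapped_residue == "H" and calls["pka"][0].is_basic

    def test_missing_reference_is_error(self):
        msa = Alignment(rows=[("a", "AR")])
        with pytest.raises(KeyError):
            map_reference_positions(msa, "nope", [0])


class TestClassifyKinome:
    def test_recovers_planted_truth_exactly(self, clean_kinome):
        seqs, msa, truth = clean_kinome
        records = classify_kinome(
            seqs, msa=msa, ref_id=seqs[0].id,
            ref_positions=[85, 160, 175], al_column_hint=190,
        )
        for rec in records:
            assert rec.al_call.state.value == truth.al_state[rec.id]
            assert rec.hm_call.state.value == truth.hm_state[rec.id]
            for t in rec.triad:
                assert t.mapped_residue == truth.triad[rec.id][t.site]

    def test_noise_off_motif_columns_does_not_hurt(self, noisy_kinome):
        seqs, msa, truth = noisy_kinome
        records = classify_kinome(
            seqs, msa=msa, ref_id=seqs[0].id,
            ref_positions=[85, 160, 175], al_column_hint=190,
        )
        assert all(
            rec.al_call.state.value == truth.al_state[rec.id]
            and rec.hm_call.state.value == truth.hm_state[rec.id]
            for rec in records
        )

    def test_empty_input_gives_empty_list(self):
        assert classify_kinome([]) == []

    def test_errors_are_annotated_with_the_kinase_id(self):
        seq = KinaseSeq(id="badkin", residues="MKRH" * 20)
        with pytest.raises(ValueError, match="badkin"):
            classify_kinome([seq], tail_window=3)
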