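import numpy as np
import pytest

from hsqcvar import (
    AGC,
    CAMK2,
    DEFAULT_MOTIFS,
    GSK3,
    MODE1_1433,
    MODE2_1433,
    Haplotype,
    ProteinSequence,
    Substitution,
    apply_substitutions,
    evaluate_1433_binding,
    generate_toy_sequence,
    propagate_priming,
    relaxed_motifs,
    scan_motifs,
    variant_impact,
)

from _oracles import regex_motif_sites


def cascade_fixture() -> ProteinSequence:
    """N-terminal toy layout: mode-2 site at S18 (P21), CaMK2/mode-1 site at
    S26 (R23, P28), tandem serines S18/S22/S26 four residues apart."""
    return generate_toy_sequence(
        40,
        planted=[(MODE2_1433, 18), (GSK3, 18), (GSK3, 22), (CAMK2, 26), (MODE1_1433, 26)],
    )


class TestApplySubstitutions:
    def test_empty_haplotype_is_identity(self):
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        assert apply_substitutions(seq, Haplotype()) == seq

    def test_substitution_applied(self):
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        out = apply_substitutions(seq, Haplotype.from_string("S7P"))
        assert out.at(7) == "P"
        assert seq.at(7) == "S"  # original untouched

    def test_wrong_reference_residue_errors(self):
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        with pytest.raises(ValueError, match=r"position 7.*found S"):
            apply_substitutions(seq, Haplotype.from_string("T7P"))


class TestScan:
    def test_mode2_toy(self):
        hits = scan_motifs(ProteinSequence("AARAAASAAPAA"), [MODE2_1433])
        assert [(h.motif, h.phosphosite) for h in hits] == [("mode2_1433", 7)]
        assert hits[0].span == (3, 10)

    def test_mode1_hit_is_also_camk2_hit(self):
        # R at i-3, S at i, P at i+2 satisfies both mode1 and the CaMK2 consensus
        seq = ProteinSequence("AARAASAPAA")
        by_name = {h.motif: h.phosphosite for h in scan_motifs(seq)}
        assert by_name.get("mode1_1433") == 6
        assert by_name.get("camk2") == 6

    def test_all_alanine_no_hits(self):
        assert scan_motifs(ProteinSequence("A" * 60)) == []

    def test_gsk3_hit_records_priming_site_and_proline_flag(self):
        hits = scan_motifs(ProteinSequence("AASPAASAA"), [GSK3])
        (h,) = hits
        assert h.phosphosite == 3 and h.priming_site == 7
        assert h.proline_plus1  # P immediately C-terminal: annotated, not required

    def test_numbering_offset_respected(self):
        shifted = ProteinSequence("AARAAASAAPAA", numbering_offset=100)
        hits = scan_motifs(shifted, [MODE2_1433])
        assert [h.phosphosite for h in hits] == [107]

    def test_agrees_with_regex_oracle_on_random_sequences(self, rng):
        alphabet = np.array(list("RSTPAG"))
        for _ in range(60):
            length = int(rng.integers(10, 500))
            residues = "".join(rng.choice(alphabet, size=length))
            seq = ProteinSequence(residues)
            for motif in DEFAULT_MOTIFS:
                got = {h.phosphosite for h in scan_motifs(seq, [motif])}
                assert got == regex_motif_sites(residues, motif.name), motif.name

    def test_relaxed_modes_drop_the_proline(self):
        seq = ProteinSequence("AARAAASAAAAA")  # R at 3, S at 7, no P
        assert scan_motifs(seq, [MODE2_1433]) == []
        hits = scan_motifs(seq, relaxed_motifs())
        assert any(h.motif == "mode2_1433_relaxed" and h.phosphosite == 7 for h in hits)


class TestPriming:
    def test_tandem_cascade_reaches_fixpoint_26_22_18(self):
        pred = propagate_priming(cascade_fixture(), primary_kinases=("camk2",))
        assert {26, 22, 18} <= set(pred.sites)
        assert pred.provenance[26] == "camk2"
        assert pred.chain(18) == [26, 22, 18]

    def test_supplied_t151_primes_s147(self):
        seq = generate_toy_sequence(160, [(MODE2_1433, 147)], extra_residues={151: "T"})
        pred = propagate_priming(seq, primary_kinases=(), extra_phospho=[151])
        assert 147 in pred.sites
        assert pred.provenance[147] == "gsk3 primed by 151"

    def test_no_inputs_no_sites(self):
        pred = propagate_priming(cascade_fixture(), primary_kinases=())
        assert not pred.sites

    def test_monotone_in_extra_phospho(self):
        seq = cascade_fixture()
        small = propagate_priming(seq, ("camk2",))
        large = propagate_priming(seq, ("camk2",), extra_phospho=[30])
        assert small.sites <= large.sites

    def test_unknown_kinase_rejected(self):
        with pytest.raises(ValueError, match="unknown primary kinases"):
            propagate_priming(cascade_fixture(), primary_kinases=("pka",))


class TestBinding:
    def test_unphosphorylated_hit_excluded(self):
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        rep = evaluate_1433_binding(seq, frozenset())
        assert rep.hits == () and rep.bidentate_pairs == ()

    def test_bidentate_pair_18_26(self):
        seq = cascade_fixture()
        pred = propagate_priming(seq, ("camk2",))
        rep = evaluate_1433_binding(seq, pred)
        sites = {h.phosphosite for h in rep.hits}
        assert {18, 26} <= sites
        assert (18, 26) in rep.bidentate_pairs
        mode2_18 = next(h for h in rep.hits if h.phosphosite == 18)
        assert mode2_18.satisfied_by_cascade

    def test_single_hit_has_no_pairs(self):
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        rep = evaluate_1433_binding(seq, frozenset({7}))
        assert len(rep.hits) == 1 and rep.bidentate_pairs == ()


class TestVariantImpact:
    def test_anchor_destruction_loses_mode2_hit(self):
        """S->P at the phosphoacceptor removes the mode-2 site (the S147P case)."""
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        rep = variant_impact(
            seq, [Haplotype.from_string("S7P")], primary_kinases=(), extra_phospho=[7]
        )
        (imp,) = rep.impacts
        assert [(h.motif, h.phosphosite) for h in imp.hits_lost] == [("mode2_1433", 7)]
        assert imp.hits_gained == ()

    def test_plus3_proline_destruction_loses_mode2_hit(self):
        """P->H at +3 removes the mode-2 site (the P21H case)."""
        seq = generate_toy_sequence(20, [(MODE2_1433, 7)])
        rep = variant_impact(
            seq, [Haplotype.from_string("P10H")], primary_kinases=(), extra_phospho=[7]
        )
        (imp,) = rep.impacts
        assert [(h.motif, h.phosphosite) for h in imp.hits_lost] == [("mode2_1433", 7)]

    def test_filler_substitution_changes_nothing(self):
        seq = generate_toy_sequence(30, [(MODE2_1433, 7)])
        filler_pos = 20
        sub = Substitution(ref_aa=seq.at(filler_pos), position=filler_pos, alt_aa="V")
        rep = variant_impact(seq, [Haplotype({sub})], primary_kinases=(), extra_phospho=[7])
        (imp,) = rep.impacts
        assert imp.hits_lost == () and imp.hits_gained == ()
        assert imp.cascade_sites_lost == () and imp.cascade_sites_gained == ()

    def test_wild_type_haplotype_reports_no_diff(self):
        seq = cascade_fixture()
        rep = variant_impact(seq, [Haplotype()], primary_kinases=("camk2",))
        (imp,) = rep.impacts
        assert imp.hits_lost == () and imp.hits_gained == ()

    def test_cascade_break_loses_downstream_sites_and_pairs(self):
        """Mutating the CaMK2 acceptor S26 kills the whole 26->22->18 cascade."""
        seq = cascade_fixture()
        rep = variant_impact(seq, [Haplotype.from_string("S26A")], ("camk2",))
        (imp,) = rep.impacts
        assert set(imp.cascade_sites_lost) == {18, 22}
        assert (18, 26) in imp.pairs_lost
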