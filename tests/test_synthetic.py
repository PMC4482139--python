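import dataclasses

import numpy as np
import pytest

from hsqcvar import (
    GSK3,
    MODE2_1433,
    CapacityError,
    Haplotype,
    MutationEffect,
    ScenarioSpec,
    Substitution,
    generate_base_peaklist,
    generate_toy_sequence,
    generate_toy_structures,
    generate_variant_family,
    kabsch_superpose,
    range_rmsd,
    reference_haplotypes,
    reference_scenario,
    scan_motifs,
    truncate_to_segment,
)

S147P = Substitution.from_string("S147P")
P21H = Substitution.from_string("P21H")
V261A = Substitution.from_string("V261A")


def _combined(pl, n_weight=0.14):
    h = np.array([p.h_shift for p in pl.peaks])
    n = np.array([p.n_shift for p in pl.peaks])
    dh = h[:, None] - h[None, :]
    dn = n[:, None] - n[None, :]
    d = np.hypot(dh, n_weight * dn)
    np.fill_diagonal(d, np.inf)
    return d


class TestScenario:
    def test_reference_effect_counts(self, scenario):
        by_sub = {e.sub: e for e in scenario.effects}
        assert (by_sub[S147P].n_appear, by_sub[S147P].n_disappear) == (5, 5)
        assert (by_sub[P21H].n_appear, by_sub[P21H].n_disappear) == (1, 3)
        assert (by_sub[V261A].n_appear, by_sub[V261A].n_disappear) == (2, 2)
        assert scenario.n_base_peaks == 200
        assert scenario.window.h_sweep == 14 and scenario.window.n_sweep == 36

    def test_separation_and_jitter_guarantees_enforced(self):
        with pytest.raises(ValueError, match="min_separation"):
            dataclasses.replace(reference_scenario(), min_separation=0.05)
        with pytest.raises(ValueError, match="jitter"):
            dataclasses.replace(reference_scenario(), jitter_sd_h=0.02)

    def test_disappear_budget_checked(self):
        with pytest.raises(ValueError, match="exceed"):
            ScenarioSpec(
                n_base_peaks=2,
                effects=(MutationEffect(S147P, n_disappear=5, n_appear=0),),
            )


class TestBasePeaklist:
    def test_empty(self, scenario):
        empty = dataclasses.replace(scenario, n_base_peaks=0, effects=())
        assert len(generate_base_peaklist(empty, 1)) == 0

    def test_determinism(self, scenario):
        a = generate_base_peaklist(scenario, 7)
        b = generate_base_peaklist(scenario, 7)
        assert a == b
        c = generate_base_peaklist(scenario, 8)
        assert a != c

    def test_pairwise_separation(self, scenario):
        pl = generate_base_peaklist(scenario, 3)
        assert len(pl) == 200
        assert _combined(pl).min() >= scenario.min_separation

    def test_all_peaks_inside_window(self, scenario):
        pl = generate_base_peaklist(scenario, 5)
        assert all(scenario.window.contains(p) for p in pl.peaks)

    def test_crowded_region_raises_density(self, scenario):
        crowded = dataclasses.replace(
            scenario, effects=(), crowded_region=(8.0, 8.6)
        )
        pl = generate_base_peaklist(crowded, 11)
        h = np.array([p.h_shift for p in pl.peaks])
        frac_in = np.mean((h >= 8.0) & (h <= 8.6))
        # the 0.6 ppm strip holds ~4% of the window; boosted sampling puts far more there
        assert frac_in > 0.2

    def test_capacity_error_when_window_too_small(self):
        from hsqcvar import SpectralWindow

        spec = dataclasses.replace(
            reference_scenario(),
            n_base_peaks=100,
            effects=(),
            window=SpectralWindow(h_sweep=0.5, h_center=8.0, n_sweep=2.0, n_center=118.0),
        )
        with pytest.raises(CapacityError):
            generate_base_peaklist(spec, 1)


class TestVariantFamily:
    def test_wild_type_is_jittered_base(self, family, scenario):
        wt = family.wild_type
        assert len(wt) == scenario.n_base_peaks
        assert {p.id for p in wt.peaks} == {p.id for p in family.base.peaks}
        dev_h = max(
            abs(p.h_shift - family.base.by_id(p.id).h_shift) for p in wt.peaks
        )
        assert 0 < dev_h < 6 * scenario.jitter_sd_h

    def test_double_mutant_net_count(self, family, scenario):
        """|double| - |WT| = (5+1) appearing - (5+3) disappearing = -2."""
        double = Haplotype({P21H, S147P})
        assert len(family.lists[double]) - len(family.wild_type) == -2

    def test_zero_jitter_empty_haplotype_equals_base(self, scenario):
        fam = generate_variant_family(
            scenario, [Haplotype()], seed=9, jitter=False
        )
        assert [(p.h_shift, p.n_shift) for p in fam.wild_type.peaks] == [
            (p.h_shift, p.n_shift) for p in fam.base.peaks
        ]

    def test_determinism_and_order_independence(self, scenario):
        haps = reference_haplotypes()
        a = generate_variant_family(scenario, haps, seed=4)
        b = generate_variant_family(scenario, list(reversed(haps)), seed=4)
        for hap in haps:
            assert a.lists[hap] == b.lists[hap]

    def test_planted_effects_disjoint(self, family):
        seen: set[str] = set()
        for dis, app in family.planted.values():
            ids = set(dis) | set(app)
            assert not (ids & seen)
            seen |= ids

    def test_missing_effect_is_configuration_error(self, scenario):
        stray = Haplotype({Substitution.from_string("A99G")})
        with pytest.raises(KeyError, match="A99G"):
            generate_variant_family(scenario, [Haplotype(), stray], seed=0)

    def test_wild_type_required(self, scenario):
        with pytest.raises(ValueError, match="wild type"):
            generate_variant_family(scenario, [Haplotype({S147P})], seed=0)


class TestTruncation:
    def test_keep_fraction_one_keeps_everything(self, family):
        tr = truncate_to_segment(family, (1, 494), 1.0, seed=5)
        for hap, pl in tr.lists.items():
            assert len(pl) == len(family.lists[hap])

    def test_keep_fraction_055_keeps_110_wt_peaks(self, family):
        tr = truncate_to_segment(family, (1, 264), 0.55, seed=5)
        assert len(tr.wild_type) == 110

    def test_planted_s147p_changes_retained_in_1_264(self, family):
        tr = truncate_to_segment(family, (1, 264), 0.25, seed=6)
        dis, app = tr.planted[S147P]
        wt_ids = tr.wild_type.ids()
        mut_ids = tr.lists[Haplotype({S147P})].ids()
        assert set(dis) <= wt_ids
        assert set(app) <= mut_ids

    def test_out_of_segment_substitution_dropped(self, family):
        tr = truncate_to_segment(family, (1, 200), 0.5, seed=6)
        assert tr.planted[V261A] == ((), ())
        orig_dis, orig_app = family.planted[V261A]
        for hap, pl in tr.lists.items():
            assert not (pl.ids() & (set(orig_dis) | set(orig_app)))

    def test_segment_descriptor_updated(self, family):
        tr = truncate_to_segment(family, (1, 264), 0.55, seed=5)
        assert tr.wild_type.segment == (1, 264)

    def test_bad_fraction_rejected(self, family):
        with pytest.raises(ValueError):
            truncate_to_segment(family, (1, 264), 0.0, seed=1)


class TestToySequence:
    def test_mode2_plant_places_r_s_p(self):
        seq = generate_toy_sequence(12, [(MODE2_1433, 7)])
        assert seq.at(3) == "R" and seq.at(7) == "S" and seq.at(10) == "P"
        hits = scan_motifs(seq, [MODE2_1433])
        assert [h.phosphosite for h in hits] == [7]

    def test_filler_only_sequence_has_no_phospho_motifs(self):
        seq = generate_toy_sequence(80)
        assert scan_motifs(seq) == []

    def test_cascade_fixture_layout(self):
        seq = generate_toy_sequence(
            40, [(GSK3, 18), (GSK3, 22)], extra_residues={23: "R"}
        )
        # S at 18, 22, 26 with the CaMK2 arginine at 23
        assert seq.at(18) == seq.at(22) == seq.at(26) == "S"
        assert seq.at(23) == "R"

    def test_conflicting_constraints_rejected(self):
        with pytest.raises(ValueError, match="conflict"):
            generate_toy_sequence(
                12, [(MODE2_1433, 7)], extra_residues={10: "H"}
            )

    def test_plant_outside_length_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_toy_sequence(8, [(MODE2_1433, 7)])


class TestToyStructures:
    def test_pure_rigid_motion_superposes_exactly(self):
        a, b = generate_toy_structures(50, (10, 20), displacement_sd=0.0, seed=1)
        assert kabsch_superpose(a, b).rmsd < 1e-6

    def test_untouched_range_has_zero_rmsd(self):
        a, b = generate_toy_structures(60, (30, 40), displacement_sd=0.8, seed=2)
        assert range_rmsd(a, b, (1, 20), superpose_on="range") < 1e-6
        assert range_rmsd(a, b, (30, 40), superpose_on="range") > 0.1

    def test_displacement_rmsd_matches_sd_sqrt3(self):
        """Monte Carlo: per-axis sd s gives an expected atom RMSD of s*sqrt(3)."""
        sd = 0.5
        sq_devs = []
        for seed in range(60):
            a, b = generate_toy_structures(60, (21, 40), displacement_sd=sd, seed=seed)
            fit = kabsch_superpose(a, b)
            moved = fit.transform(a.coords)
            diff = moved[20:40] - b.coords[20:40]
            sq_devs.append(np.mean(np.sum(diff**2, axis=1)))
        observed = np.sqrt(np.mean(sq_devs))
        assert observed == pytest.approx(sd * np.sqrt(3), rel=0.1)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_structures(10, (5, 20), 0.1, seed=0)
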