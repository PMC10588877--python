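"""Variant screens: orientation, couple/cohort/trio filters, exclusion rule."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from alloscreen import (
    Family,
    ScreenConfig,
    VariantRecord,
    alloantigen_couple_filter,
    candidate_exclusion,
    cohort_homozygous_screen,
    gene_recurrence,
    read_cohort,
    sex_stratified_genotype_counts,
    swap_ref_alt,
    trio_denovo_recessive,
    write_cohort,
)
from alloscreen.simulate import PlantedVariantSpec, SimulationSpec, simulate_cohort

from conftest import build_cohort, trio_family
from oracles import fisher_two_sided_oracle

CONFIG = ScreenConfig()


def duo_samples(n):
    fams = [
        Family(f"F{i}", f"F{i}_M", f"F{i}_F", [], []) for i in range(1, n + 1)
    ]
    samples = [s for f in fams for s in (f.mother_id, f.father_id)]
    return samples, fams


class TestMinorOrientation:
    def test_common_alt_means_ref_is_minor(self):
        v = VariantRecord("1", 10, "A", "C", np.array([0, 1, 2]), alt_af=0.7)
        assert not v.minor_is_alt
        assert v.pop_minor_af == pytest.approx(0.3)
        assert list(v.minor_dosages()) == [2, 1, 0]  # hom-minor is dosage 0

    def test_tie_breaks_to_alt(self):
        v = VariantRecord("1", 10, "A", "C", np.array([2]), alt_af=0.5)
        assert v.minor_is_alt

    def test_swap_preserves_minor_dosages(self):
        v = VariantRecord("1", 10, "A", "C", np.array([0, 1, 2, -1]), alt_af=0.2)
        before = list(v.minor_dosages())
        v.swap_ref_alt()
        assert v.alt_af == pytest.approx(0.8)
        assert list(v.minor_dosages()) == before


class TestCoupleFilter:
    def test_pattern_retained_with_all_families_supporting(self):
        samples, fams = duo_samples(3)
        cohort = build_cohort(
            samples, fams, [dict(dosages=[2, 0] * 3, alt_af=0.05)]
        )
        res = alloantigen_couple_filter(cohort, CONFIG)
        assert len(res.candidates) == 1
        assert res.candidates[0].families == ["F1", "F2", "F3"]
        assert res.candidates[0].details["all_families_support"]

    def test_het_mother_vetoes(self):
        samples, fams = duo_samples(3)
        cohort = build_cohort(
            samples, fams, [dict(dosages=[2, 0, 1, 0, 2, 0], alt_af=0.05)]
        )
        assert alloantigen_couple_filter(cohort, CONFIG).candidates == []

    def test_missing_family_is_noninformative_not_veto(self):
        samples, fams = duo_samples(3)
        cohort = build_cohort(
            samples, fams, [dict(dosages=[2, 0, -1, 0, 2, 0], alt_af=0.05)]
        )
        res = alloantigen_couple_filter(cohort, CONFIG)
        assert len(res.candidates) == 1
        assert res.candidates[0].families == ["F1", "F3"]
        assert res.candidates[0].details["n_noninformative"] == 1
        assert not res.candidates[0].details["all_families_support"]

    def test_non_het_child_vetoes_when_required(self):
        fam = trio_family()
        samples = [fam.mother_id, fam.father_id, fam.child_ids[0]]
        spec = dict(dosages=[2, 0, 2], alt_af=0.05)
        cohort = build_cohort(samples, [fam], [spec])
        assert alloantigen_couple_filter(cohort, CONFIG).candidates == []
        relaxed = ScreenConfig(require_child_het=False)
        assert len(alloantigen_couple_filter(cohort, relaxed).candidates) == 1

    def test_disallowed_consequence_dropped(self):
        samples, fams = duo_samples(2)
        cohort = build_cohort(
            samples, fams,
            [dict(dosages=[2, 0, 2, 0], alt_af=0.05,
                  consequence_class="synonymous")],
        )
        res = alloantigen_couple_filter(cohort, CONFIG)
        assert res.candidates == []
        assert res.stage_counts["consequence_class"] == 0

    def test_requires_a_genotyped_couple(self):
        fam = Family("F1", "F1_M", None, [], [])
        cohort = build_cohort(["F1_M"], [fam], [dict(dosages=[2], alt_af=0.05)])
        with pytest.raises(ValueError, match="both parents"):
            alloantigen_couple_filter(cohort, CONFIG)

    def test_stage_counts_non_increasing(self):
        cohort = simulate_cohort(
            SimulationSpec(n_families=4, n_missing_fathers=1,
                           n_background_variants=60, seed=3)
        )
        counts = list(alloantigen_couple_filter(cohort, CONFIG).stage_counts.values())
        assert counts == sorted(counts, reverse=True)


class TestCohortHomozygousScreen:
    def test_af_bound_and_consequence(self):
        samples, fams = duo_samples(2)
        cohort = build_cohort(
            samples, fams,
            [
                dict(dosages=[2, 0, 0, 0], alt_af=0.12),  # AF too high
                dict(dosages=[2, 0, 0, 0], alt_af=0.05,
                     consequence_class="synonymous"),  # wrong class
                dict(dosages=[2, 0, 0, 0], alt_af=0.05),  # retained
                dict(dosages=[1, 0, 1, 0], alt_af=0.05),  # no hom mother
            ],
        )
        res = cohort_homozygous_screen(cohort, CONFIG)
        assert [c.variant.pos for c in res.candidates] == [300]
        assert res.candidates[0].details["hom_women"] == ["F1_M"]
        counts = list(res.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_spiked_rare_homs_recovered_exactly(self):
        # background AFs all above the cut-off; three spiked rare hom-minor
        # variants are exactly what the screen returns
        spec = SimulationSpec(
            n_families=6, n_missing_fathers=0, n_background_variants=1000,
            background_af_range=(0.3, 0.45), missing_rate=0.0, seed=17,
        )
        cohort = simulate_cohort(spec)
        n_s = len(cohort.samples)
        mother_cols = [cohort.sample_index[m] for m in cohort.mother_ids()]
        for k in range(3):
            dos = np.zeros(n_s, dtype=np.int8)
            dos[mother_cols[k]] = 2
            cohort.variants.append(
                VariantRecord("1", 2_000_000 + k, "A", "T", dos,
                              consequence_class="missense", gene=f"SPIKE{k}",
                              alt_af=0.02)
            )
        res = cohort_homozygous_screen(cohort, CONFIG)
        assert {c.variant.pos for c in res.candidates} == {
            2_000_000, 2_000_001, 2_000_002
        }

    def test_lof_only_mode(self):
        samples, fams = duo_samples(1)
        cohort = build_cohort(
            samples, fams,
            [
                dict(dosages=[2, 0], alt_af=0.05),  # missense
                dict(dosages=[2, 0], alt_af=0.05,
                     consequence_class="frameshift", pos=999),
            ],
        )
        res = cohort_homozygous_screen(cohort, ScreenConfig(lof_only_mode=True))
        assert [c.variant.pos for c in res.candidates] == [999]


class TestGeneRecurrence:
    def _cohort_for(self, variant_specs, n_women=4):
        fams = [Family(f"F{i}", f"F{i}_M", None, [], []) for i in range(1, n_women + 1)]
        samples = [f.mother_id for f in fams]
        return build_cohort(samples, fams, variant_specs)

    def test_same_coordinate_in_three_women_flagged(self):
        cohort = self._cohort_for(
            [dict(dosages=[2, 2, 2, 0], alt_af=0.05, gene="G1",
                  aa_change="p.K5R")]
        )
        base = cohort_homozygous_screen(cohort, CONFIG)
        tab = gene_recurrence(base, CONFIG)
        row = tab.set_index("gene").loc["G1"]
        assert row["max_women_same_coordinate"] == 3
        assert bool(row["flagged"])

    def test_scattered_single_women_not_flagged(self):
        # one woman per site, different coordinates and aa changes
        specs = [
            dict(dosages=[2 if i == j else 0 for j in range(4)], alt_af=0.05,
                 gene="G1", aa_change=f"p.K{i}R", pos=10 + i)
            for i in range(3)
        ]
        cohort = self._cohort_for(specs)
        tab = gene_recurrence(cohort_homozygous_screen(cohort, CONFIG), CONFIG)
        assert not tab["flagged"].any()

    def test_same_aa_change_across_sites_flagged(self):
        # two sites, same amino-acid change, three distinct women in total
        specs = [
            dict(dosages=[2, 2, 0, 0], alt_af=0.04, gene="G2",
                 aa_change="p.A9V", pos=11),
            dict(dosages=[0, 0, 2, 0], alt_af=0.03, gene="G2",
                 aa_change="p.A9V", pos=12),
        ]
        cohort = self._cohort_for(specs)
        tab = gene_recurrence(cohort_homozygous_screen(cohort, CONFIG), CONFIG)
        row = tab.set_index("gene").loc["G2"]
        assert row["max_women_same_coordinate"] == 2
        assert row["max_women_same_aa"] == 3
        assert bool(row["flagged"])


class TestTrioScreens:
    def _trio_cohort(self, specs):
        fam = trio_family()
        samples = [fam.mother_id, fam.father_id, fam.child_ids[0]]
        return build_cohort(samples, [fam], specs), fam

    def test_de_novo_child_allele_absent_from_parents(self):
        cohort, fam = self._trio_cohort(
            [dict(dosages=[0, 0, 1], alt_af=0.001)]
        )
        res = trio_denovo_recessive(cohort, fam, CONFIG)
        assert [c.filter_name for c in res.candidates if c.filter_name == "de_novo"]

    def test_recessive_hom_blocked_by_af_threshold(self):
        # child hom-minor at AF 0.05: above the 2% recessive cut-off
        cohort, fam = self._trio_cohort(
            [dict(dosages=[1, 1, 2], alt_af=0.05)]
        )
        res = trio_denovo_recessive(cohort, fam, CONFIG)
        assert not [c for c in res.candidates if c.filter_name == "recessive_hom"]
        cohort2, fam2 = self._trio_cohort(
            [dict(dosages=[1, 1, 2], alt_af=0.01)]
        )
        res2 = trio_denovo_recessive(cohort2, fam2, CONFIG)
        assert [c for c in res2.candidates if c.filter_name == "recessive_hom"]

    def test_compound_het_one_variant_per_parent(self):
        cohort, fam = self._trio_cohort(
            [
                dict(dosages=[1, 0, 1], alt_af=0.01, gene="GX", pos=10),
                dict(dosages=[0, 1, 1], alt_af=0.01, gene="GX", pos=20),
            ]
        )
        res = trio_denovo_recessive(cohort, fam, CONFIG)
        ch = [c for c in res.candidates if c.filter_name == "compound_het"]
        assert {c.variant.pos for c in ch} == {10, 20}
        assert all(c.details["phase_known"] for c in ch)

    def test_two_maternal_hets_not_compound(self):
        cohort, fam = self._trio_cohort(
            [
                dict(dosages=[1, 0, 1], alt_af=0.01, gene="GX", pos=10),
                dict(dosages=[1, 0, 1], alt_af=0.01, gene="GX", pos=20),
            ]
        )
        res = trio_denovo_recessive(cohort, fam, CONFIG)
        assert not [c for c in res.candidates if c.filter_name == "compound_het"]

    def test_fallback_without_father_is_phase_unknown(self):
        fam = Family("F1", "F1_M", None, ["F1_C1"], [True])
        samples = ["F1_M", "F1_C1"]
        cohort = build_cohort(
            samples, [fam],
            [
                dict(dosages=[1, 1], alt_af=0.01, gene="GX", pos=10),
                dict(dosages=[0, 1], alt_af=0.01, gene="GX", pos=20),
            ],
        )
        res = trio_denovo_recessive(cohort, fam, CONFIG)
        ch = [c for c in res.candidates if c.filter_name == "compound_het"]
        assert len(ch) == 2
        assert not any(c.details["phase_known"] for c in ch)

    def test_family_without_child_rejected(self):
        samples, fams = duo_samples(1)
        cohort = build_cohort(samples, fams, [dict(dosages=[0, 0], alt_af=0.1)])
        with pytest.raises(ValueError, match="child"):
            trio_denovo_recessive(cohort, fams[0], CONFIG)


class TestSexCountsAndExclusion:
    def test_tally_cohort_counts_reproduced(self, tally_cohort):
        counts = sex_stratified_genotype_counts(
            tally_cohort, tally_cohort.variants[0]
        )
        assert (counts.men.hom_minor, counts.men.het, counts.men.hom_major) == (
            3, 8, 11
        )
        assert (counts.women.hom_minor, counts.women.het,
                counts.women.hom_major) == (4, 6, 16)
        assert counts.children.het == 2

    def test_all_missing_goes_to_missing(self, tally_cohort):
        v = tally_cohort.variants[0]
        v.dosages[:] = -1
        counts = sex_stratified_genotype_counts(tally_cohort, v)
        assert counts.men.missing == 22 and counts.men.n_called == 0
        assert counts.women.missing == 26

    def test_counts_sum_to_sex_totals_on_random_cohorts(self):
        for seed in range(5):
            cohort = simulate_cohort(
                SimulationSpec(n_families=8, n_missing_fathers=2,
                               n_background_variants=10, missing_rate=0.2,
                               child_per_family=1, seed=seed)
            )
            for v in cohort.variants[:3]:
                c = sex_stratified_genotype_counts(cohort, v)
                assert c.men.total == 6
                assert c.women.total == 8
                assert c.children.total == 8

    def test_hom_minor_father_excludes(self, tally_cohort):
        counts = sex_stratified_genotype_counts(
            tally_cohort, tally_cohort.variants[0]
        )
        decision = candidate_exclusion(counts)
        assert decision.excluded
        assert "homozygous" in decision.reason

    def test_pattern_consistent_with_hypothesis_is_retained(self):
        from alloscreen import GenotypeCountsBySex, SexCounts

        counts = GenotypeCountsBySex(
            men=SexCounts(hom_minor=0, het=4, hom_major=18),
            women=SexCounts(hom_minor=26, het=0, hom_major=0),
            children=SexCounts(),
        )
        assert candidate_exclusion(counts).decision == "RETAINED"

    def test_single_hom_minor_father_suffices_regardless_of_other_counts(self):
        from alloscreen import GenotypeCountsBySex, SexCounts

        for het, hom_major in [(0, 0), (20, 0), (0, 50)]:
            counts = GenotypeCountsBySex(
                men=SexCounts(hom_minor=1, het=het, hom_major=hom_major),
                women=SexCounts(hom_minor=10, het=0, hom_major=0),
                children=SexCounts(),
            )
            assert candidate_exclusion(counts).excluded

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[3, 19], [4, 22]]
        _, p_scipy = fisher_exact(table, alternative="two-sided")
        assert p_scipy == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_no_adults_is_an_error(self):
        from alloscreen import GenotypeCountsBySex, SexCounts

        empty = GenotypeCountsBySex(SexCounts(), SexCounts(), SexCounts())
        with pytest.raises(ValueError):
            candidate_exclusion(empty)


class TestOrientationInvariance:
    def test_screens_unchanged_under_ref_alt_swap(self):
        spec = SimulationSpec(
            n_families=4, n_missing_fathers=1, n_background_variants=80,
            planted=PlantedVariantSpec(minor_af=0.05,
                                       force_father_hom_major=True),
            child_per_family=1, missing_rate=0.05, seed=23,
        )
        cohort = simulate_cohort(spec)
        swapped = swap_ref_alt(cohort, range(0, cohort.n_variants, 2))
        for screen_fn in (alloantigen_couple_filter, cohort_homozygous_screen):
            a = screen_fn(cohort, CONFIG)
            b = screen_fn(swapped, CONFIG)
            assert {
                (k[0], k[1]) for k in a.candidate_keys()
            } == {(k[0], k[1]) for k in b.candidate_keys()}
            assert a.stage_counts == b.stage_counts


class TestReadCohortEdgeCases:
    def test_sidecar_af_overrides_info(self, tmp_path):
        spec = SimulationSpec(n_families=2, n_missing_fathers=0,
                              n_background_variants=3, missing_rate=0.0, seed=1)
        cohort = simulate_cohort(spec)
        vcf, ped = tmp_path / "c.vcf", tmp_path / "c.ped"
        write_cohort(cohort, vcf, ped)
        side = tmp_path / "af.tsv"
        v = cohort.variants[0]
        side.write_text(
            "chrom\tpos\tref\talt\taf\n"
            f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t0.123456\n"
        )
        back = read_cohort(vcf, ped, side)
        assert back.variants[0].alt_af == pytest.approx(0.123456)
        assert back.variants[1].alt_af == pytest.approx(
            cohort.variants[1].alt_af, abs=1e-6
        )

    def test_pedigree_sample_missing_from_vcf_is_named(self, tmp_path):
        spec = SimulationSpec(n_families=2, n_missing_fathers=0,
                              n_background_variants=2, missing_rate=0.0, seed=1)
        cohort = simulate_cohort(spec)
        vcf, ped = tmp_path / "c.vcf", tmp_path / "c.ped"
        write_cohort(cohort, vcf, ped)
        ped_text = ped.read_text() + "FAM9\tGHOST\t0\t0\t2\t1\n"
        ped2 = tmp_path / "bad.ped"
        ped2.write_text(ped_text)
        with pytest.raises(ValueError, match="GHOST"):
            read_cohort(vcf, ped2)

    def test_multiallelic_record_split_into_biallelic(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000000>\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\t.\tA\tC,G\t.\t.\tAF=0.10,0.70\tGT\t0/1\t1/2\t2/2\n"
        )
        ped = tmp_path / "m.ped"
        ped.write_text(
            "F1\tS1\t0\t0\t2\t1\nF1\tS2\t0\t0\t1\t1\nF1\tS3\t"
            "S2\tS1\t1\t2\n"
        )
        cohort = read_cohort(vcf, ped)
        assert cohort.n_variants == 2
        first, second = cohort.variants
        assert (first.alt, second.alt) == ("C", "G")
        assert list(first.dosages) == [1, 1, 0]
        assert list(second.dosages) == [0, 1, 2]
        assert first.minor_is_alt          # AF 0.10
        assert not second.minor_is_alt     # AF 0.70: minor allele is REF
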