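"""Fixture construction, gene drop, causal planting, and cohort simulation."""

import itertools
import random

import pytest

from mendelsieve import (
    Affection,
    InfeasibleModelError,
    PipelineConfig,
    Zygosity,
    build_paper_fixture,
    gene_drop,
    plant_causal,
    run_pipeline,
    simulate_cohort,
)
from mendelsieve.simulate import (
    FIXTURE_VARIANTS,
    SimulationConfig,
    fixture_genome,
    make_pedigree,
)

from .oracles import mendelian_consistent


class TestPaperFixture:
    def test_totals(self, bundle):
        assert len(bundle.samples) == 20
        assert sum(len(p.affected_members()) for p in bundle.pedigrees) == 8

    def test_family_a_zygosities(self, bundle, variant_by_label):
        v = variant_by_label["p.Tyr131Cys"]
        assert v.zygosity("FAM_A_II.1") is Zygosity.HOM_ALT
        assert v.zygosity("FAM_A_II.2") is Zygosity.HOM_ALT
        assert v.zygosity("FAM_A_I.1") is Zygosity.HET
        assert v.zygosity("FAM_A_I.2") is Zygosity.HET

    def test_family_d_zygosities(self, bundle, variant_by_label):
        v = variant_by_label["p.Thr91Ile"]
        assert v.zygosity("FAM_D_II.1") is Zygosity.HET  # affected proband
        assert v.zygosity("FAM_D_I.1") is Zygosity.HET  # unaffected father
        assert v.zygosity("FAM_D_II.2") is Zygosity.HET  # unaffected sister
        assert v.zygosity("FAM_D_I.2") is Zygosity.HOM_REF  # mother

    def test_previously_reported_variant_has_tiny_nonzero_af(self, bundle):
        pos, ref, alt, _tx, _c = FIXTURE_VARIANTS["p.Arg47His"]
        af = bundle.freqs.max_af(("chr11L", pos, ref, alt))
        assert 0 < af <= 0.002
        for label in ("p.Tyr131Cys", "p.Arg150Pro", "p.Val216Ile", "p.Thr91Ile"):
            pos, ref, alt, _tx, _c = FIXTURE_VARIANTS[label]
            assert bundle.freqs.max_af(("chr11L", pos, ref, alt)) == 0.0

    def test_fixture_is_deterministic(self, bundle):
        again = build_paper_fixture()
        assert again.records == bundle.records
        assert [p.members for p in again.pedigrees] == [
            p.members for p in bundle.pedigrees
        ]
        assert again.coding_sequences == bundle.coding_sequences

    def test_genome_agrees_with_coding_sequences(self, bundle):
        genome = fixture_genome()
        for t in bundle.transcripts:
            seq = bundle.coding_sequences[t.transcript_id]
            spliced = "".join(
                genome[s - 1 : e] for s, e in t.cds_intervals
            )
            assert spliced == seq

    def test_fixture_genotypes_are_mendelian(self, bundle, peds_by_id):
        for v in bundle.records:
            for ped in bundle.pedigrees:
                genotypes = {
                    m.individual_id: v.genotypes[m.individual_id].alleles
                    for m in ped.members
                }
                assert mendelian_consistent(ped, genotypes), (v.key, ped.family_id)

    def test_directory_export_round_trips(self, bundle, tmp_path):
        from mendelsieve import (
            FrequencyTable,
            parse_ped,
            read_coding_fasta,
            read_transcripts_tsv,
            read_vcf,
        )

        paths = bundle.write(tmp_path)
        records = read_vcf(paths["vcf"])
        assert {r.key for r in records} == {r.key for r in bundle.records}
        peds = parse_ped(paths["ped"].read_text())
        assert sum(len(p) for p in peds) == 20
        assert read_transcripts_tsv(paths["transcripts"]) == bundle.transcripts
        assert read_coding_fasta(paths["fasta"]) == bundle.coding_sequences
        assert len(FrequencyTable.from_tsv(paths["freqs"])) == len(bundle.freqs)


class TestGeneDrop:
    def test_af_zero_all_hom_ref(self):
        ped = make_pedigree("sextet", "S1")
        calls = gene_drop(ped, 0.0, random.Random(1))
        assert all(c.alleles == (0, 0) for c in calls.values())

    def test_af_one_all_hom_alt(self):
        ped = make_pedigree("sextet", "S1")
        calls = gene_drop(ped, 1.0, random.Random(1))
        assert all(c.alleles == (1, 1) for c in calls.values())

    def test_transmission_always_mendelian(self):
        ped = make_pedigree("sextet", "S1")
        rng = random.Random(42)
        for _ in range(200):
            calls = gene_drop(ped, 0.3, rng)
            genotypes = {iid: c.alleles for iid, c in calls.items()}
            assert mendelian_consistent(ped, genotypes)

    def test_child_het_fraction_matches_enumeration(self):
        """Trio at AF 0.5: compare to the exact transmission probability."""
        af = 0.5
        # brute-force oracle: sum over parental genotype pairs under
        # Hardy-Weinberg of P(child het | transmission)
        hw = {0: (1 - af) ** 2, 1: 2 * af * (1 - af), 2: af**2}
        p_het = 0.0
        for gf, gm in itertools.product(hw, repeat=2):
            p_alt_f, p_alt_m = gf / 2, gm / 2
            p_child_het = p_alt_f * (1 - p_alt_m) + (1 - p_alt_f) * p_alt_m
            p_het += hw[gf] * hw[gm] * p_child_het
        ped = make_pedigree("trio", "T1")
        rng = random.Random(2024)
        n = 10_000
        hets = sum(
            gene_drop(ped, af, rng)["T1_II.1"].zygosity() is Zygosity.HET
            for _ in range(n)
        )
        se = (p_het * (1 - p_het) / n) ** 0.5
        assert abs(hets / n - p_het) < 3 * se


class TestPlantCausal:
    def test_ar_hom_quartet_pattern(self):
        ped = make_pedigree("quartet", "Q1")
        (genos,), affection = plant_causal(ped, "ar_hom", 1.0, random.Random(5))
        assert genos["Q1_I.1"].zygosity() is Zygosity.HET
        assert genos["Q1_I.2"].zygosity() is Zygosity.HET
        hom_children = [
            iid
            for iid in ("Q1_II.1", "Q1_II.2")
            if genos[iid].zygosity() is Zygosity.HOM_ALT
        ]
        assert hom_children
        for iid in hom_children:
            assert affection[iid] is Affection.AFFECTED

    def test_comp_het_sextet_pattern(self):
        ped = make_pedigree("sextet", "S1")
        (ga, gb), affection = plant_causal(
            ped, "comp_het", 1.0, random.Random(7)
        )
        # each parent carries exactly one of the two variants
        assert ga["S1_I.1"].zygosity() is Zygosity.HET
        assert gb["S1_I.1"].zygosity() is Zygosity.HOM_REF
        assert ga["S1_I.2"].zygosity() is Zygosity.HOM_REF
        assert gb["S1_I.2"].zygosity() is Zygosity.HET
        for iid, aff in affection.items():
            double = (
                ga[iid].zygosity() is Zygosity.HET
                and gb[iid].zygosity() is Zygosity.HET
            )
            assert (aff is Affection.AFFECTED) == double

    def test_ad_incomplete_penetrance_produces_unaffected_carriers(self):
        ped = make_pedigree("quartet", "D1")
        rng = random.Random(11)
        carrier_outcomes = []
        for _ in range(400):
            (genos,), affection = plant_causal(ped, "ad", 0.5, rng)
            affected_ids = {
                iid for iid, a in affection.items() if a is Affection.AFFECTED
            }
            proband = next(iter(affected_ids))  # at least one by construction
            for iid, g in genos.items():
                if g.zygosity() is Zygosity.HET and iid != proband:
                    carrier_outcomes.append(affection[iid] is Affection.UNAFFECTED)
        frac_unaffected = sum(carrier_outcomes) / len(carrier_outcomes)
        n = len(carrier_outcomes)
        se = (0.5 * 0.5 / n) ** 0.5
        assert abs(frac_unaffected - 0.5) < 4 * se

    def test_infeasible_model_raises(self):
        from mendelsieve import Individual, Pedigree

        founders_only = Pedigree(
            "F",
            [Individual("A", "F"), Individual("B", "F")],
        )
        with pytest.raises(InfeasibleModelError):
            plant_causal(founders_only, "comp_het", 1.0, random.Random(0))


class TestSimulatedCohort:
    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(seed=3, n_families=2, background_variant_count=20)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        for f1, f2 in zip(c1.families, c2.families):
            assert f1.records == f2.records
            assert f1.pedigree.members == f2.pedigree.members
        assert c1.truth.equals(c2.truth)

    def test_written_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_families=2, background_variant_count=10)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(cfg).write(d1)
        simulate_cohort(cfg).write(d2)
        for path in sorted(d1.iterdir()):
            assert path.read_bytes() == (d2 / path.name).read_bytes()

    def test_error_free_cohort_is_mendelian(self):
        cfg = SimulationConfig(seed=9, n_families=3, background_variant_count=30)
        cohort = simulate_cohort(cfg)
        for fam in cohort.families:
            for rec in fam.records:
                genotypes = {
                    m.individual_id: rec.genotypes[m.individual_id].alleles
                    for m in fam.pedigree.members
                }
                assert mendelian_consistent(fam.pedigree, genotypes)

    def test_common_background_never_survives_rarity_filter(self, bundle):
        cfg = SimulationConfig(
            seed=5,
            n_families=2,
            background_variant_count=50,
            background_af_points=((0.05, 1.0),),
        )
        cohort = simulate_cohort(cfg)
        for fam in cohort.families:
            for rec in fam.records:
                if rec.key in fam.causal_keys:
                    continue
                assert cohort.freqs.max_af(rec.site) > 0.002

    def test_genotyping_errors_cost_some_recoveries(self, bundle):
        noisy = SimulationConfig(
            seed=21,
            n_families=25,
            background_variant_count=0,
            genotyping_error_rate=0.05,
        )
        cohort = simulate_cohort(noisy)
        lost = 0
        for fam in cohort.families:
            rep = run_pipeline(
                fam.records,
                [fam.pedigree],
                bundle.transcripts,
                cohort.freqs,
                PipelineConfig(),
                bundle.coding_sequences,
            )
            if not set(fam.causal_keys) <= rep.distinct_variants():
                lost += 1
        # with 4-6 genotypes per variant at 5% error, some but not all
        # families should lose their causal variant under strict handling
        assert 0 < lost < 25

    def test_fixture_pipeline_reproduces_study_assignments(self, bundle):
        """Full-funnel round trip of the fixture recovers the study table."""
        rep = run_pipeline(
            bundle.records,
            bundle.pedigrees,
            bundle.transcripts,
            bundle.freqs,
            PipelineConfig(
                panel_genes=bundle.panel_genes,
                review_genes=bundle.review_genes,
            ),
            bundle.coding_sequences,
        )
        expected = {
            ("FAM_A", "AR_hom"),
            ("FAM_B", "AR_hom"),
            ("FAM_C", "comp_het"),
            ("FAM_D", "AD_incomplete_penetrance"),
        }
        assert {(r.family_id, r.model) for r in rep.rows} == expected
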