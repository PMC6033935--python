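"""Inheritance-model verdicts, trans inference, and oracle equivalence."""

import itertools

import pytest

from mendelsieve import (
    Affection,
    GenotypeCall,
    Individual,
    Pedigree,
    SegregationConfig,
    Sex,
    VariantRecord,
    Zygosity,
    find_compound_het,
    fits_dominant,
    fits_recessive_hom,
    known_gene_review,
    segregation_scan,
)
from mendelsieve.segregation import ExceptionKind, ModelType, SegregationError

from .oracles import oracle_ar_hom, oracle_comp_het, oracle_dominant

HOM_REF, HET, HOM_ALT = (
    GenotypeCall(0, 0),
    GenotypeCall(0, 1),
    GenotypeCall(1, 1),
)
ZYG_OF = {
    (0, 0): Zygosity.HOM_REF,
    (0, 1): Zygosity.HET,
    (1, 1): Zygosity.HOM_ALT,
}


def quartet(affections, family="F"):
    """Father, mother, two children with the given affection statuses."""
    f, m, c1, c2 = affections
    return Pedigree(
        family,
        [
            Individual(f"{family}_F", family, None, None, Sex.MALE, f),
            Individual(f"{family}_M", family, None, None, Sex.FEMALE, m),
            Individual(f"{family}_C1", family, f"{family}_F", f"{family}_M", Sex.MALE, c1),
            Individual(f"{family}_C2", family, f"{family}_F", f"{family}_M", Sex.FEMALE, c2),
        ],
    )


def record(genotypes, pos=100):
    return VariantRecord("chr11L", pos, "A", ("G",), dict(genotypes))


AFF, UNAFF = Affection.AFFECTED, Affection.UNAFFECTED


class TestRecessiveHom:
    def test_family_a_fits(self, bundle, peds_by_id, variant_by_label):
        """Homozygous in both affected sons, het in both unaffected parents."""
        res = fits_recessive_hom(
            variant_by_label["p.Tyr131Cys"], peds_by_id["FAM_A"]
        )
        assert res.fits
        assert res.carriers["FAM_A_II.1"] == (Zygosity.HOM_ALT,)
        assert res.carriers["FAM_A_I.1"] == (Zygosity.HET,)

    def test_family_b_fits_with_hom_ref_brother(
        self, peds_by_id, variant_by_label
    ):
        res = fits_recessive_hom(
            variant_by_label["p.Arg150Pro"], peds_by_id["FAM_B"]
        )
        assert res.fits
        assert res.carriers["FAM_B_II.2"] == (Zygosity.HOM_REF,)

    def test_unaffected_hom_alt_vetoes(self):
        ped = quartet([UNAFF, UNAFF, AFF, AFF])
        v = record(
            {"F_F": HOM_ALT, "F_M": HET, "F_C1": HOM_ALT, "F_C2": HOM_ALT}
        )
        assert not fits_recessive_hom(v, ped).fits

    def test_het_affected_vetoes(self):
        ped = quartet([UNAFF, UNAFF, AFF, AFF])
        v = record({"F_F": HET, "F_M": HET, "F_C1": HOM_ALT, "F_C2": HET})
        assert not fits_recessive_hom(v, ped).fits

    def test_missing_genotype_strict_vs_lenient(self):
        ped = quartet([UNAFF, UNAFF, AFF, UNAFF])
        v = record(
            {
                "F_F": HET,
                "F_M": GenotypeCall(None, None),
                "F_C1": HOM_ALT,
                "F_C2": HET,
            }
        )
        strict = fits_recessive_hom(v, ped)
        assert not strict.fits
        assert any(
            e.kind is ExceptionKind.MISSING_GENOTYPE for e in strict.exceptions
        )
        lenient = fits_recessive_hom(
            v, ped, SegregationConfig(strict_missing=False)
        )
        assert lenient.fits


class TestDominant:
    def test_family_d_incomplete_penetrance(
        self, peds_by_id, variant_by_label
    ):
        """Unaffected carrier father and sister are tolerated exceptions."""
        v = variant_by_label["p.Thr91Ile"]
        ped = peds_by_id["FAM_D"]
        strict = fits_dominant(v, ped, "strict")
        assert not strict.fits
        incomplete = fits_dominant(v, ped, "incomplete_penetrance")
        assert incomplete.fits
        carriers = {
            e.individual_id
            for e in incomplete.exceptions
            if e.kind is ExceptionKind.UNAFFECTED_CARRIER
        }
        assert carriers == {"FAM_D_I.1", "FAM_D_II.2"}

    def test_affected_noncarrier_fails_both_modes(self):
        ped = quartet([UNAFF, UNAFF, AFF, AFF])
        v = record({"F_F": HET, "F_M": HOM_REF, "F_C1": HET, "F_C2": HOM_REF})
        assert not fits_dominant(v, ped, "strict").fits
        assert not fits_dominant(v, ped, "incomplete_penetrance").fits

    def test_de_novo_dominant_fits_strict(self):
        ped = quartet([UNAFF, UNAFF, AFF, UNAFF])
        v = record(
            {"F_F": HOM_REF, "F_M": HOM_REF, "F_C1": HET, "F_C2": HOM_REF}
        )
        assert fits_dominant(v, ped, "strict").fits


class TestCompoundHet:
    def test_family_c_single_fitting_pair(
        self, bundle, peds_by_id, variant_by_label
    ):
        """Four affected carry both variants; unaffecteds carry exactly one."""
        ped = peds_by_id["FAM_C"]
        variants = [
            variant_by_label["p.Arg47His"],
            variant_by_label["p.Val216Ile"],
        ]
        results = find_compound_het(variants, ped)
        fitting = [r for r in results if r.fits]
        assert len(fitting) == 1
        (res,) = fitting
        both = res.carriers_of_all()
        assert sorted(both) == [
            "FAM_C_II.1",
            "FAM_C_II.2",
            "FAM_C_II.3",
            "FAM_C_II.4",
        ]
        for m in ped.unaffected_members():
            zs = res.carriers[m.individual_id]
            n_carried = sum(z in (Zygosity.HET, Zygosity.HOM_ALT) for z in zs)
            assert n_carried == 1

    def test_single_variant_gives_no_pairs(self, peds_by_id, variant_by_label):
        assert (
            find_compound_het(
                [variant_by_label["p.Arg47His"]], peds_by_id["FAM_C"]
            )
            == []
        )

    def test_cis_configuration_rejected(self):
        # both variants from the father; the mother carries neither, so the
        # child's two alt alleles sit on one paternal haplotype
        ped = quartet([UNAFF, UNAFF, AFF, UNAFF])
        a = record(
            {"F_F": HET, "F_M": HOM_REF, "F_C1": HET, "F_C2": HOM_REF}, pos=100
        )
        b = record(
            {"F_F": HET, "F_M": HOM_REF, "F_C1": HET, "F_C2": HOM_REF}, pos=200
        )
        (res,) = find_compound_het([a, b], ped)
        assert not res.fits

    def test_double_carrier_parent_is_phase_unknown(self):
        # the father carries both variants and nothing pins his phase, so
        # the affected child's pair could be cis or trans
        ped = trio([UNAFF, UNAFF, AFF])
        a = record({"F_F": HET, "F_M": HET, "F_C1": HET}, pos=100)
        b = record({"F_F": HET, "F_M": HOM_REF, "F_C1": HET}, pos=200)
        (res,) = find_compound_het([a, b], ped)
        assert not res.fits
        assert any(
            e.kind is ExceptionKind.PHASE_UNKNOWN for e in res.exceptions
        )
        (relaxed,) = find_compound_het(
            [a, b], ped, SegregationConfig(allow_phase_unknown=True)
        )
        assert relaxed.fits

    def test_symmetry_in_argument_order(self, peds_by_id, variant_by_label):
        ped = peds_by_id["FAM_C"]
        a = variant_by_label["p.Arg47His"]
        b = variant_by_label["p.Val216Ile"]
        assert find_compound_het([a, b], ped) == find_compound_het([b, a], ped)


def _genotype_sweep(ped, n_variants):
    """All per-member zygosity assignments for n variants."""
    states = [(0, 0), (0, 1), (1, 1)]
    ids = [m.individual_id for m in ped.members]
    per_member = list(itertools.product(states, repeat=n_variants))
    for combo in itertools.product(per_member, repeat=len(ids)):
        yield {
            iid: tuple(GenotypeCall(*gt) for gt in member_gts)
            for iid, member_gts in zip(ids, combo)
        }


def _records_from(assignment, n_variants):
    return [
        VariantRecord(
            "c",
            100 * (k + 1),
            "A",
            ("G",),
            {iid: gts[k] for iid, gts in assignment.items()},
        )
        for k in range(n_variants)
    ]


def _zyg(assignment, k):
    return {iid: ZYG_OF[gts[k].alleles] for iid, gts in assignment.items()}


def trio(affections, family="F"):
    f, m, c = affections
    return Pedigree(
        family,
        [
            Individual(f"{family}_F", family, None, None, Sex.MALE, f),
            Individual(f"{family}_M", family, None, None, Sex.FEMALE, m),
            Individual(f"{family}_C1", family, f"{family}_F", f"{family}_M", Sex.MALE, c),
        ],
    )


def _affection_patterns(n):
    return list(itertools.product([AFF, UNAFF], repeat=n))


class TestOracleEquivalence:
    """Model verdicts equal brute-force transmission/phase enumeration."""

    @pytest.mark.parametrize("shape", ["trio", "quartet"])
    def test_single_variant_models_exhaustive(self, shape):
        make = trio if shape == "trio" else quartet
        n = 3 if shape == "trio" else 4
        for affections in _affection_patterns(n):
            ped = make(affections)
            for assignment in _genotype_sweep(ped, 1):
                (v,) = _records_from(assignment, 1)
                zyg = _zyg(assignment, 0)
                assert fits_recessive_hom(v, ped).fits == oracle_ar_hom(
                    ped, zyg
                )
                assert fits_dominant(v, ped, "strict").fits == oracle_dominant(
                    ped, zyg, "strict"
                )
                assert fits_dominant(
                    v, ped, "incomplete_penetrance"
                ).fits == oracle_dominant(ped, zyg, "incomplete")

    def test_compound_het_trio_exhaustive(self):
        for affections in _affection_patterns(3):
            ped = trio(affections)
            for assignment in _genotype_sweep(ped, 2):
                a, b = _records_from(assignment, 2)
                (res,) = find_compound_het([a, b], ped)
                expected = oracle_comp_het(
                    ped, _zyg(assignment, 0), _zyg(assignment, 1)
                )
                assert res.fits == expected, assignment

    @pytest.mark.parametrize(
        "affections",
        [
            (UNAFF, UNAFF, AFF, UNAFF),
            (UNAFF, UNAFF, AFF, AFF),
            (AFF, UNAFF, AFF, UNAFF),
        ],
    )
    def test_compound_het_quartet_exhaustive(self, affections):
        ped = quartet(affections)
        for assignment in _genotype_sweep(ped, 2):
            a, b = _records_from(assignment, 2)
            (res,) = find_compound_het([a, b], ped)
            expected = oracle_comp_het(
                ped, _zyg(assignment, 0), _zyg(assignment, 1)
            )
            assert res.fits == expected, assignment

    def test_sibling_genotypes_can_pin_parental_phase(self):
        # both parents het for both variants would normally be ambiguous,
        # but a sibling homozygous for one variant and reference for the
        # other proves each parent has a haplotype carrying only the first
        # variant, pinning both parents to the trans phase; the unaffected
        # double-carrier parents are flagged as penetrance exceptions
        ped = quartet([UNAFF, UNAFF, AFF, UNAFF])
        a = record(
            {"F_F": HET, "F_M": HET, "F_C1": HET, "F_C2": HOM_ALT}, pos=100
        )
        b = record(
            {"F_F": HET, "F_M": HET, "F_C1": HET, "F_C2": HOM_REF}, pos=200
        )
        (res,) = find_compound_het([a, b], ped)
        assert res.fits
        assert not any(
            e.kind is ExceptionKind.PHASE_UNKNOWN for e in res.exceptions
        )
        flagged = {
            e.individual_id
            for e in res.exceptions
            if e.kind is ExceptionKind.UNAFFECTED_CARRIER
        }
        assert flagged == {"F_F", "F_M"}


class TestMonotonicity:
    def test_adding_unaffected_noncarrier_never_rescues(self):
        base = trio((UNAFF, UNAFF, AFF))
        extended = quartet((UNAFF, UNAFF, AFF, UNAFF))
        for assignment in _genotype_sweep(base, 2):
            ext = {
                **assignment,
                "F_C2": (HOM_REF, HOM_REF),
            }
            a, b = _records_from(assignment, 2)
            a_ext, b_ext = _records_from(ext, 2)
            for v, v_ext in ((a, a_ext), (b, b_ext)):
                before = fits_recessive_hom(v, base).fits
                after = fits_recessive_hom(v_ext, extended).fits
                assert not (after and not before)
                for mode in ("strict", "incomplete_penetrance"):
                    before_d = fits_dominant(v, base, mode).fits
                    after_d = fits_dominant(v_ext, extended, mode).fits
                    assert not (after_d and not before_d)
            (before_ch,) = find_compound_het([a, b], base)
            (after_ch,) = find_compound_het([a_ext, b_ext], extended)
            assert not (after_ch.fits and not before_ch.fits)


class TestScanAndReview:
    def test_four_family_models(self, bundle, peds_by_id):
        expected = {
            "FAM_A": {ModelType.AR_HOM},
            "FAM_B": {ModelType.AR_HOM},
            "FAM_C": {ModelType.COMP_HET},
            "FAM_D": {ModelType.AD_INCOMPLETE},
        }
        rare = [v for v in bundle.records if bundle.freqs.max_af(v.site) <= 0.002]
        for fam, models in expected.items():
            results = segregation_scan(
                rare,
                peds_by_id[fam],
                bundle.transcripts,
                bundle.coding_sequences,
            )
            best1l = [
                r
                for r in results
                if any("chr11L:5" not in k for k in r.variants)
            ]
            assert models <= {r.model for r in results}

    def test_scan_requires_all_members_genotyped(self, peds_by_id):
        v = record({"FAM_A_I.1": HET})
        with pytest.raises(SegregationError, match="genotype"):
            segregation_scan([v], peds_by_id["FAM_A"], [], {})

    def test_known_gene_review_is_unfiltered(self, bundle):
        # the family-D het variant surfaces even though no recessive model
        # fits, and a common synonymous decoy in the gene would be included
        reviewed = known_gene_review(
            bundle.records,
            "BEST1L",
            bundle.transcripts,
            bundle.coding_sequences,
        )
        keys = {v.key for v in reviewed}
        assert "chr11L:1532:C>T" in keys  # the dominant-family variant
        assert len(keys) == 5
        assert (
            known_gene_review(
                bundle.records,
                "NO_SUCH_GENE",
                bundle.transcripts,
                bundle.coding_sequences,
            )
            == []
        )
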