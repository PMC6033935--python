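"""Synthetic inputs: the packaged four-family fixture and gene-drop cohorts.

The packaged fixture encodes the study conditions this package is tested
against: four nuclear bestrophinopathy-style pedigrees (20 members, 8
affected), a toy two-isoform disease gene, and five planted missense
variants whose codon arithmetic, amino-acid changes, and per-member
zygosities match the published findings — recessive homozygotes in families
A and B, a cross-isoform compound heterozygote in family C, and a dominant
variant with an unaffected carrier father in family D.

The toy gene ("BEST1L") is synthetic: its coding sequence is generated, not
the real BEST1 sequence. Only the constrained facts are preserved — the
canonical isoform carries Arg47, Thr91, Tyr131 and Arg150 at those codon
indices; the alternate isoform has a private exon placing Val at codon 216;
both isoforms share their first 160 codons. Genomic coordinates are
arbitrary fixed constants on a toy contig (see the geometry constants
below), scaled down from the real 585-codon protein.

Cohort simulation plants model-consistent causal genotypes by gene drop
(founders from Hardy-Weinberg, one allele transmitted per parent) plus
frequency-matched background variants, for recovery experiments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .annotation import (
    FrequencyTable,
    TranscriptModel,
    codon_change,
    project_genomic_to_cds,
    write_coding_fasta,
    write_transcripts_tsv,
    Effect,
)
from .junctions import AlignmentRecord, junctions_of
from .pedigree import Affection, Individual, Pedigree, Sex, write_ped
from .variants import GenotypeCall, VariantRecord, write_vcf


class SimulationError(ValueError):
    pass


class InfeasibleModelError(SimulationError):
    """The requested inheritance model cannot be planted on this pedigree."""


# -- toy gene geometry (fixed constants, 1-based inclusive) -------------------

CHROM = "chr11L"
GENOME_LENGTH = 6000
GENE_ID = "BEST1L"
CANONICAL_TX = "BEST1L-201"  # 180 codons; stands in for the 585-aa isoform
ALTERNATE_TX = "BEST1L-202"  # 240 codons via a private exon
OTHER_GENE_ID = "OTHER"
OTHER_TX = "OTHER-201"

_CANON_EXONS = ((1001, 1240), (1501, 1740), (3001, 3060))
_ALT_EXONS = ((1001, 1240), (1501, 1740), (2601, 2780), (2901, 2960))
_OTHER_EXONS = ((5001, 5300),)

#: The alternate-isoform-private junction (between its 3rd and 4th exon);
#: the split-read evidence for alternate-isoform expression is counted here.
ALT_UNIQUE_JUNCTION = (2780, 2901)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _build_coding_sequences() -> tuple[str, str, str]:
    rng = random.Random(11)  # fixed: the fixture is a constant, not a sample
    canon = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(178)] + ["TAA"]
    canon[46] = "CGC"  # Arg47  (c.140 G>A -> His)
    canon[90] = "ACC"  # Thr91  (c.272 C>T -> Ile)
    canon[130] = "TAT"  # Tyr131 (c.392 A>G -> Cys)
    canon[149] = "CGC"  # Arg150 (c.449 G>C -> Pro)
    alt = canon[:160] + [rng.choice(_SENSE_CODONS) for _ in range(79)] + ["TAA"]
    alt[215] = "GTT"  # Val216 (c.646 G>A -> Ile), inside the private exon
    other = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(98)] + ["TAA"]
    other[16] = "GCT"  # decoy: common missense site (c.50 C>A)
    other[19] = "GCT"  # decoy: synonymous site (c.60 T>C)
    other[26] = "GCT"  # decoy: off-panel recessive site (c.80 C>G)
    return "".join(canon), "".join(alt), "".join(other)


_CANON_CDS, _ALT_CDS, _OTHER_CDS = _build_coding_sequences()


def fixture_transcripts() -> list[TranscriptModel]:
    return [
        TranscriptModel(
            transcript_id=CANONICAL_TX,
            gene_id=GENE_ID,
            chrom=CHROM,
            strand="+",
            exons=_CANON_EXONS,
            cds_start=_CANON_EXONS[0][0],
            cds_end=_CANON_EXONS[-1][1],
        ),
        TranscriptModel(
            transcript_id=ALTERNATE_TX,
            gene_id=GENE_ID,
            chrom=CHROM,
            strand="+",
            exons=_ALT_EXONS,
            cds_start=_ALT_EXONS[0][0],
            cds_end=_ALT_EXONS[-1][1],
        ),
        TranscriptModel(
            transcript_id=OTHER_TX,
            gene_id=OTHER_GENE_ID,
            chrom=CHROM,
            strand="+",
            exons=_OTHER_EXONS,
            cds_start=_OTHER_EXONS[0][0],
            cds_end=_OTHER_EXONS[-1][1],
        ),
    ]


def fixture_coding_sequences() -> dict[str, str]:
    return {
        CANONICAL_TX: _CANON_CDS,
        ALTERNATE_TX: _ALT_CDS,
        OTHER_TX: _OTHER_CDS,
    }


def fixture_genome() -> str:
    """The toy contig: random background with exon content pasted in."""
    rng = random.Random(13)
    genome = [rng.choice("ACGT") for _ in range(GENOME_LENGTH)]

    def paste(intervals, cds):
        offset = 0
        for s, e in intervals:
            n = e - s + 1
            genome[s - 1 : e] = list(cds[offset : offset + n])
            offset += n

    paste(_CANON_EXONS, _CANON_CDS)
    paste(_ALT_EXONS, _ALT_CDS)  # shared exons rewritten identically
    paste(_OTHER_EXONS, _OTHER_CDS)
    return "".join(genome)


# -- the four-family fixture --------------------------------------------------


def _nuclear(
    family_id: str,
    children: Sequence[tuple[str, Sex, Affection]],
    founders_affection: tuple[Affection, Affection] = (
        Affection.UNAFFECTED,
        Affection.UNAFFECTED,
    ),
) -> Pedigree:
    f_id, m_id = f"{family_id}_I.1", f"{family_id}_I.2"
    members = [
        Individual(f_id, family_id, None, None, Sex.MALE, founders_affection[0]),
        Individual(m_id, family_id, None, None, Sex.FEMALE, founders_affection[1]),
    ]
    for child_id, sex, aff in children:
        members.append(
            Individual(child_id, family_id, f_id, m_id, sex, aff)
        )
    return Pedigree(family_id, members)


def fixture_pedigrees() -> list[Pedigree]:
    """The four study families: 20 members, 8 affected.

    Family C follows the pedigree-figure labeling (proband II.3; affected
    siblings II.1, II.2, II.4) and includes the proband's two unaffected
    children with an ungenotyped, absent father.
    """
    AFF, UNAFF = Affection.AFFECTED, Affection.UNAFFECTED
    fam_a = _nuclear(
        "FAM_A",
        [("FAM_A_II.1", Sex.MALE, AFF), ("FAM_A_II.2", Sex.MALE, AFF)],
    )
    fam_b = _nuclear(
        "FAM_B",
        [("FAM_B_II.1", Sex.MALE, AFF), ("FAM_B_II.2", Sex.MALE, UNAFF)],
    )
    fam_c_members = _nuclear(
        "FAM_C",
        [
            ("FAM_C_II.1", Sex.MALE, AFF),
            ("FAM_C_II.2", Sex.FEMALE, AFF),
            ("FAM_C_II.3", Sex.FEMALE, AFF),  # proband
            ("FAM_C_II.4", Sex.MALE, AFF),
        ],
    ).members
    fam_c_members += [
        Individual(
            "FAM_C_III.1", "FAM_C", None, "FAM_C_II.3", Sex.MALE, UNAFF
        ),
        Individual(
            "FAM_C_III.2", "FAM_C", None, "FAM_C_II.3", Sex.FEMALE, UNAFF
        ),
    ]
    fam_c = Pedigree("FAM_C", fam_c_members)
    fam_d = _nuclear(
        "FAM_D",
        [("FAM_D_II.1", Sex.MALE, AFF), ("FAM_D_II.2", Sex.FEMALE, UNAFF)],
    )
    return [fam_a, fam_b, fam_c, fam_d]


_HOM_REF = GenotypeCall(0, 0)
_HET = GenotypeCall(0, 1)
_HOM_ALT = GenotypeCall(1, 1)


def _genotypes(
    samples: Sequence[str], non_ref: dict[str, GenotypeCall]
) -> dict[str, GenotypeCall]:
    return {s: non_ref.get(s, _HOM_REF) for s in samples}


#: fixture variant constants: (label, pos, ref, alt, cds on which isoform)
FIXTURE_VARIANTS = {
    "p.Tyr131Cys": (1652, "A", "G", CANONICAL_TX, 392),
    "p.Arg150Pro": (1709, "G", "C", CANONICAL_TX, 449),
    "p.Arg47His": (1140, "G", "A", CANONICAL_TX, 140),
    "p.Val216Ile": (2766, "G", "A", ALTERNATE_TX, 646),
    "p.Thr91Ile": (1532, "C", "T", CANONICAL_TX, 272),
}


@dataclass
class FixtureBundle:
    """Everything the pipeline consumes, in memory, plus directory export."""

    pedigrees: list[Pedigree]
    records: list[VariantRecord]
    transcripts: list[TranscriptModel]
    coding_sequences: dict[str, str]
    freqs: FrequencyTable
    panel_genes: frozenset[str]
    review_genes: frozenset[str]
    genome: str = ""
    chrom: str = CHROM

    @property
    def samples(self) -> list[str]:
        return [m.individual_id for ped in self.pedigrees for m in ped.members]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "ped": outdir / "families.ped",
            "transcripts": outdir / "transcripts.tsv",
            "fasta": outdir / "coding.fa",
            "freqs": outdir / "population_af.tsv",
            "panel": outdir / "panel_genes.tsv",
        }
        write_vcf(
            self.records,
            paths["vcf"],
            samples=self.samples,
            contig_lengths={self.chrom: max(GENOME_LENGTH, len(self.genome))},
        )
        paths["ped"].write_text(write_ped(self.pedigrees))
        write_transcripts_tsv(self.transcripts, paths["transcripts"])
        write_coding_fasta(self.coding_sequences, paths["fasta"])
        self.freqs.to_tsv(paths["freqs"])
        paths["panel"].write_text(
            "\n".join(sorted(self.panel_genes)) + "\n"
        )
        return paths


def build_paper_fixture() -> FixtureBundle:
    """Deterministic four-family fixture reproducing the study's genotypes.

    Per-member zygosities: family A homozygous p.Tyr131Cys-analog in both
    affected sons, parents het; family B homozygous p.Arg150Pro-analog,
    unaffected brother hom-ref; family C all four affected het for both the
    canonical-isoform p.Arg47His-analog and the alternate-isoform
    p.Val216Ile-analog, each unaffected member carrying exactly one;
    family D het p.Thr91Ile-analog in the proband, unaffected father, and
    sister, absent in the mother. The p.Arg47His-analog carries a tiny
    nonzero reference-cohort frequency (it was previously observed); the
    other four are absent from every cohort. Three decoy variants in an
    off-panel second gene exercise the frequency, impact, and panel filters.
    """
    pedigrees = fixture_pedigrees()
    samples = [m.individual_id for ped in pedigrees for m in ped.members]

    def var(label, non_ref, annotations=None):
        pos, ref, alt, _tx, _cds = FIXTURE_VARIANTS[label]
        return VariantRecord(
            chrom=CHROM,
            pos=pos,
            ref=ref,
            alts=(alt,),
            genotypes=_genotypes(samples, non_ref),
            annotations=annotations or {},
        )

    records = [
        var(
            "p.Tyr131Cys",
            {
                "FAM_A_I.1": _HET,
                "FAM_A_I.2": _HET,
                "FAM_A_II.1": _HOM_ALT,
                "FAM_A_II.2": _HOM_ALT,
            },
            {"SIFT": "deleterious", "POLYPHEN": "probably_damaging"},
        ),
        var(
            "p.Arg150Pro",
            {
                "FAM_B_I.1": _HET,
                "FAM_B_I.2": _HET,
                "FAM_B_II.1": _HOM_ALT,
            },
            {"SIFT": "deleterious", "POLYPHEN": "probably_damaging"},
        ),
        var(
            "p.Arg47His",
            {
                "FAM_C_I.1": _HET,
                "FAM_C_II.1": _HET,
                "FAM_C_II.2": _HET,
                "FAM_C_II.3": _HET,
                "FAM_C_II.4": _HET,
                "FAM_C_III.1": _HET,
            },
            {"SIFT": "deleterious", "POLYPHEN": "probably_damaging"},
        ),
        var(
            "p.Val216Ile",
            {
                "FAM_C_I.2": _HET,
                "FAM_C_II.1": _HET,
                "FAM_C_II.2": _HET,
                "FAM_C_II.3": _HET,
                "FAM_C_II.4": _HET,
                "FAM_C_III.2": _HET,
            },
            {"SIFT": "damaging", "POLYPHEN": "benign"},
        ),
        var(
            "p.Thr91Ile",
            {
                "FAM_D_I.1": _HET,
                "FAM_D_II.1": _HET,
                "FAM_D_II.2": _HET,
            },
            {"SIFT": "deleterious", "POLYPHEN": "probably_damaging"},
        ),
        # decoys in the off-panel gene
        VariantRecord(  # common: removed by the 0.2% frequency filter
            chrom=CHROM,
            pos=5050,
            ref="C",
            alts=("A",),
            genotypes=_genotypes(
                samples, {"FAM_A_I.1": _HET, "FAM_B_I.1": _HET}
            ),
        ),
        VariantRecord(  # rare synonymous: removed by the impact filter
            chrom=CHROM,
            pos=5060,
            ref="T",
            alts=("C",),
            genotypes=_genotypes(
                samples, {"FAM_A_I.1": _HET, "FAM_A_II.1": _HET}
            ),
        ),
        VariantRecord(  # rare recessive-fitting: removed by panel intersection
            chrom=CHROM,
            pos=5080,
            ref="C",
            alts=("G",),
            genotypes=_genotypes(
                samples,
                {
                    "FAM_A_I.1": _HET,
                    "FAM_A_I.2": _HET,
                    "FAM_A_II.1": _HOM_ALT,
                    "FAM_A_II.2": _HOM_ALT,
                },
            ),
        ),
    ]

    freqs = FrequencyTable()
    arg47 = FIXTURE_VARIANTS["p.Arg47His"]
    freqs.add((CHROM, arg47[0], arg47[1], arg47[2]), "EXAC", 0.0001)
    freqs.add((CHROM, 5050, "C", "A"), "KG1000", 0.05)

    return FixtureBundle(
        pedigrees=pedigrees,
        records=records,
        transcripts=fixture_transcripts(),
        coding_sequences=fixture_coding_sequences(),
        freqs=freqs,
        panel_genes=frozenset({GENE_ID}),
        review_genes=frozenset({GENE_ID}),
        genome=fixture_genome(),
    )


# -- gene drop and causal planting --------------------------------------------


def _topological_members(ped: Pedigree) -> list[Individual]:
    ordered: list[Individual] = []
    placed: set[str] = set()
    pending = list(ped.members)
    while pending:
        for m in list(pending):
            deps = [p for p in (m.father_id, m.mother_id) if p in ped]
            if all(d in placed for d in deps):
                ordered.append(m)
                placed.add(m.individual_id)
                pending.remove(m)
                break
        else:  # pragma: no cover - pedigrees are validated acyclic
            raise SimulationError("cannot order pedigree")
    return ordered


def gene_drop(
    ped: Pedigree, af: float, rng: random.Random
) -> dict[str, GenotypeCall]:
    """Drop one biallelic locus through a pedigree.

    Founder alleles are Hardy-Weinberg draws at frequency ``af``; each
    non-founder receives one uniformly chosen allele from each genotyped
    parent (an absent parent contributes a fresh population draw).
    """
    if not 0.0 <= af <= 1.0:
        raise SimulationError(f"allele frequency {af} outside [0, 1]")
    alleles: dict[str, tuple[int, int]] = {}

    def draw() -> int:
        return 1 if rng.random() < af else 0

    for m in _topological_members(ped):
        inherited = []
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid in ped:
                inherited.append(rng.choice(alleles[pid]))
            else:
                inherited.append(draw())
        alleles[m.individual_id] = (inherited[0], inherited[1])
    return {iid: GenotypeCall(a, b) for iid, (a, b) in alleles.items()}


def _proband_candidates(ped: Pedigree) -> list[Individual]:
    return [
        m
        for m in ped.members
        if m.father_id in ped and m.mother_id in ped
    ]


def plant_causal(
    ped: Pedigree,
    model: str,
    penetrance: float = 1.0,
    rng: Optional[random.Random] = None,
) -> tuple[list[dict[str, GenotypeCall]], dict[str, Affection]]:
    """Plant a model-consistent causal genotype configuration.

    Returns one genotype map per causal variant (two for ``comp_het``) and
    affection statuses assigned from the causal genotype: members with the
    disease genotype (homozygous for ``ar_hom``, double-carrier for
    ``comp_het``, any carrier for ``ad``) are affected with probability
    ``penetrance``; everyone else is unaffected (no phenocopies). One
    proband is always affected, mirroring how families are ascertained.
    """
    rng = rng or random.Random()
    if not 0.0 < penetrance <= 1.0:
        raise SimulationError("penetrance must be in (0, 1]")
    candidates = _proband_candidates(ped)
    if model in ("ar_hom", "comp_het") and not candidates:
        raise InfeasibleModelError(
            f"{model} needs a member with both parents in the pedigree"
        )

    members = _topological_members(ped)
    if model == "ar_hom":
        proband = rng.choice(candidates)
        haps: dict[str, tuple[int, int]] = {}
        for m in members:
            if m.individual_id == proband.individual_id:
                haps[m.individual_id] = (1, 1)
            elif m.individual_id in (proband.father_id, proband.mother_id):
                haps[m.individual_id] = rng.choice([(0, 1), (1, 0)])
            elif m.is_founder or m.father_id not in ped or m.mother_id not in ped:
                haps[m.individual_id] = (0, 0)
            else:
                haps[m.individual_id] = (
                    rng.choice(haps[m.father_id]),
                    rng.choice(haps[m.mother_id]),
                )
        genotypes = {iid: GenotypeCall(*h) for iid, h in haps.items()}
        disease = {iid for iid, h in haps.items() if sum(h) == 2}
        geno_maps = [genotypes]
    elif model == "ad":
        if candidates:
            proband = rng.choice(candidates)
            carrier_parent = rng.choice(
                [proband.father_id, proband.mother_id]
            )
        else:
            proband = rng.choice(ped.members)
            carrier_parent = None
        haps = {}
        for m in members:
            if m.individual_id == carrier_parent:
                haps[m.individual_id] = rng.choice([(0, 1), (1, 0)])
            elif m.individual_id == proband.individual_id:
                if carrier_parent is None:
                    haps[m.individual_id] = (0, 1)  # de novo proband
                else:
                    from_f = (
                        1
                        if proband.father_id == carrier_parent
                        else 0
                    )
                    haps[m.individual_id] = (from_f, 1 - from_f)
            elif m.is_founder or m.father_id not in ped or m.mother_id not in ped:
                haps[m.individual_id] = (0, 0)
            else:
                haps[m.individual_id] = (
                    rng.choice(haps[m.father_id]),
                    rng.choice(haps[m.mother_id]),
                )
        genotypes = {iid: GenotypeCall(*h) for iid, h in haps.items()}
        disease = {iid for iid, h in haps.items() if sum(h) >= 1}
        geno_maps = [genotypes]
    elif model == "comp_het":
        proband = rng.choice(candidates)
        father, mother = proband.father_id, proband.mother_id
        # haplotype per member and variant: father carries variant 1,
        # mother carries variant 2; no recombination within the gene
        haps_a: dict[str, tuple[int, int]] = {}
        haps_b: dict[str, tuple[int, int]] = {}
        for m in members:
            iid = m.individual_id
            if iid == father:
                haps_a[iid], haps_b[iid] = (1, 0), (0, 0)
            elif iid == mother:
                haps_a[iid], haps_b[iid] = (0, 0), (1, 0)
            elif iid == proband.individual_id:
                haps_a[iid], haps_b[iid] = (1, 0), (0, 1)
            elif m.is_founder or m.father_id not in ped or m.mother_id not in ped:
                haps_a[iid], haps_b[iid] = (0, 0), (0, 0)
            else:
                pick_f, pick_m = rng.randrange(2), rng.randrange(2)
                haps_a[iid] = (
                    haps_a[m.father_id][pick_f],
                    haps_a[m.mother_id][pick_m],
                )
                haps_b[iid] = (
                    haps_b[m.father_id][pick_f],
                    haps_b[m.mother_id][pick_m],
                )
        geno_maps = [
            {iid: GenotypeCall(*h) for iid, h in haps_a.items()},
            {iid: GenotypeCall(*h) for iid, h in haps_b.items()},
        ]
        disease = {
            iid
            for iid in haps_a
            if sum(haps_a[iid]) >= 1 and sum(haps_b[iid]) >= 1
        }
    else:
        raise SimulationError(f"unknown causal model {model!r}")

    affection = {}
    for m in ped.members:
        if m.individual_id in disease:
            affected = (
                m.individual_id == proband.individual_id
                or rng.random() < penetrance
            )
            affection[m.individual_id] = (
                Affection.AFFECTED if affected else Affection.UNAFFECTED
            )
        else:
            affection[m.individual_id] = Affection.UNAFFECTED
    return geno_maps, affection


# -- cohort simulation --------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Gene-drop cohort parameters.

    Defaults emulate an error-free rare-disease cohort: quartet families,
    a fully penetrant recessive causal variant that is effectively novel
    (population frequency 0.001, below the 0.2% rarity cutoff), and 200
    background variants per family with reference-cohort frequencies of at
    least 1% — all of which the frequency cascade should remove.
    """

    seed: int = 0
    n_families: int = 50
    pedigree_shape: Union[str, Pedigree] = "quartet"
    causal_model: str = "ar_hom"
    causal_allele_freq: float = 0.001
    background_variant_count: int = 200
    background_af_range: tuple[float, float] = (0.01, 0.5)
    background_af_points: tuple[tuple[float, float], ...] = ()
    genotyping_error_rate: float = 0.0
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise SimulationError("n_families must be >= 1")
        for frac in (
            self.causal_allele_freq,
            self.genotyping_error_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"fraction {frac} outside [0, 1]")


_SHAPE_CHILDREN = {"trio": 1, "quartet": 2, "sextet": 4}


def make_pedigree(shape: Union[str, Pedigree], family_id: str) -> Pedigree:
    if isinstance(shape, Pedigree):
        return shape
    try:
        n_children = _SHAPE_CHILDREN[shape]
    except KeyError:
        raise SimulationError(f"unknown pedigree shape {shape!r}") from None
    children = [
        (
            f"{family_id}_II.{i + 1}",
            Sex.MALE if i % 2 == 0 else Sex.FEMALE,
            Affection.UNKNOWN,
        )
        for i in range(n_children)
    ]
    return _nuclear(family_id, children)


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    records: list[VariantRecord]
    causal_keys: tuple[str, ...]


@dataclass
class SimulatedCohort:
    families: list[SimulatedFamily]
    freqs: FrequencyTable
    truth: pd.DataFrame  # family_id, key, model

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        peds = [f.pedigree for f in self.families]
        (outdir / "families.ped").write_text(write_ped(peds))
        for fam in self.families:
            write_vcf(
                fam.records,
                outdir / f"{fam.pedigree.family_id}.vcf",
                samples=[m.individual_id for m in fam.pedigree.members],
                contig_lengths={CHROM: GENOME_LENGTH},
            )
        self.freqs.to_tsv(outdir / "population_af.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_transcripts_tsv(
            fixture_transcripts(), outdir / "transcripts.tsv"
        )
        write_coding_fasta(
            fixture_coding_sequences(), outdir / "coding.fa"
        )


def _missense_sites(
    t: TranscriptModel, cds: str, cds_range: tuple[int, int]
) -> list[tuple[int, str, str]]:
    """(genomic pos, ref, alt) of every missense-capable CDS position."""
    by_cds = {}
    for s, e in t.cds_intervals:
        for gpos in range(s, e + 1):
            by_cds[project_genomic_to_cds(t, gpos)] = gpos
    sites = []
    for cds_pos in range(cds_range[0], cds_range[1] + 1):
        ref = cds[cds_pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            _, _, effect = codon_change(cds, cds_pos, ref, alt)
            if effect is Effect.MISSENSE:
                sites.append((by_cds[cds_pos], ref, alt))
                break
    return sites


def _causal_site_pools() -> tuple[list, list]:
    canon, alt = fixture_transcripts()[:2]
    shared = _missense_sites(canon, _CANON_CDS, (4, 477))
    alt_unique = _missense_sites(alt, _ALT_CDS, (484, 717))
    return shared, alt_unique


_ERROR_CALLS = (
    GenotypeCall(0, 0),
    GenotypeCall(0, 1),
    GenotypeCall(1, 1),
    GenotypeCall.MISSING,
)


def _apply_errors(
    genotypes: dict[str, GenotypeCall], rate: float, rng: random.Random
) -> dict[str, GenotypeCall]:
    if rate <= 0:
        return genotypes
    out = {}
    for iid, call in genotypes.items():
        if rng.random() < rate:
            choices = [c for c in _ERROR_CALLS if c != call]
            out[iid] = rng.choice(choices)
        else:
            out[iid] = call
    return out


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Simulate families with planted causal variants and rare-ish background.

    Causal variants are missense substitutions in the toy gene (for
    ``comp_het``, one on the canonical isoform and one in the alternate
    isoform's private exon, mirroring the cross-isoform pair). Background
    variants land anywhere on the toy contig with genotypes gene-dropped at
    their population frequency. Fully reproducible from ``cfg.seed``.
    """
    rng = random.Random(cfg.seed)
    shared_pool, alt_pool = _causal_site_pools()
    rng.shuffle(shared_pool)
    rng.shuffle(alt_pool)
    genome = fixture_genome()
    freqs = FrequencyTable()
    sources = ("KG1000", "EVS", "EXAC")

    # reserve every family's causal site up front so no background variant
    # can collide with a causal (chrom, pos, ref, alt) and shadow its
    # population frequency
    n_causal = 2 if cfg.causal_model == "comp_het" else 1
    sites_by_family: list[list[tuple[int, str, str]]] = []
    used_positions: set[int] = set()
    pool_i = 0
    for i in range(cfg.n_families):
        sites = []
        for k in range(n_causal):
            if cfg.causal_model == "comp_het" and k == 1:
                site = alt_pool[i % len(alt_pool)]
            else:
                site = shared_pool[(pool_i + k) % len(shared_pool)]
            sites.append(site)
            used_positions.add(site[0])
        pool_i += n_causal
        sites_by_family.append(sites)

    families: list[SimulatedFamily] = []
    truth_rows = []
    for i in range(cfg.n_families):
        family_id = f"SIM{i + 1:03d}"
        ped = make_pedigree(cfg.pedigree_shape, family_id)
        geno_maps, affection = plant_causal(
            ped, cfg.causal_model, cfg.penetrance, rng
        )
        ped = Pedigree(
            ped.family_id,
            [replace(m, affected=affection[m.individual_id]) for m in ped.members],
        )
        causal_sites = sites_by_family[i]
        records = []
        causal_keys = []
        for (gpos, ref, alt), genotypes in zip(causal_sites, geno_maps):
            rec = VariantRecord(
                chrom=CHROM,
                pos=gpos,
                ref=ref,
                alts=(alt,),
                genotypes=_apply_errors(
                    genotypes, cfg.genotyping_error_rate, rng
                ),
            )
            records.append(rec)
            causal_keys.append(rec.key)
            if cfg.causal_allele_freq > 0:
                freqs.add(rec.site, "EXAC", cfg.causal_allele_freq)
            truth_rows.append(
                {
                    "family_id": family_id,
                    "key": rec.key,
                    "model": cfg.causal_model,
                }
            )
        n_bg = 0
        while n_bg < cfg.background_variant_count:
            pos = rng.randrange(1, GENOME_LENGTH + 1)
            if pos in used_positions:
                continue
            ref = genome[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            if cfg.background_af_points and rng.random() < sum(
                p for _, p in cfg.background_af_points
            ):
                r = rng.random() * sum(p for _, p in cfg.background_af_points)
                acc = 0.0
                af = cfg.background_af_points[-1][0]
                for value, p in cfg.background_af_points:
                    acc += p
                    if r <= acc:
                        af = value
                        break
            else:
                af = rng.uniform(*cfg.background_af_range)
            key = (CHROM, pos, ref, alt)
            freqs.add(key, rng.choice(sources), af)
            genotypes = _apply_errors(
                gene_drop(ped, af, rng), cfg.genotyping_error_rate, rng
            )
            records.append(
                VariantRecord(
                    chrom=CHROM,
                    pos=pos,
                    ref=ref,
                    alts=(alt,),
                    genotypes=genotypes,
                )
            )
            n_bg += 1
        families.append(
            SimulatedFamily(
                pedigree=ped,
                records=records,
                causal_keys=tuple(causal_keys),
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["family_id", "key", "model"])
    return SimulatedCohort(families=families, freqs=freqs, truth=truth)


# -- spliced-read simulation --------------------------------------------------


def simulate_spliced_reads(
    t: TranscriptModel,
    n_spanning_per_junction: int,
    read_len: int = 75,
    seed: int = 0,
    n_nonspanning: int = 0,
    min_overhang: int = 3,
) -> list[AlignmentRecord]:
    """Plant exactly ``n_spanning_per_junction`` split reads per junction.

    Spanning reads straddle the junction with random (seeded) overhangs of
    at least ``min_overhang`` on each side; non-spanning reads lie entirely
    within single exons. Coordinates are consistent with the transcript's
    exon structure, so every planted read passes exact-junction counting.
    """
    if read_len < 2 * min_overhang:
        raise SimulationError("read_len must be >= 2 * min_overhang")
    rng = random.Random(seed)
    reads: list[AlignmentRecord] = []
    exon_len = {(s, e): e - s + 1 for s, e in t.exons}
    for j_idx, j in enumerate(junctions_of(t)):
        up = next(e for e in t.exons if e[1] == j.donor_end)
        down = next(e for e in t.exons if e[0] == j.acceptor_start)
        lo = max(min_overhang, read_len - exon_len[down])
        hi = min(read_len - min_overhang, exon_len[up])
        for i in range(n_spanning_per_junction):
            left = rng.randint(lo, hi)
            right = read_len - left
            reads.append(
                AlignmentRecord(
                    read_id=f"{t.transcript_id}.J{j_idx}.{i}",
                    chrom=t.chrom,
                    blocks=(
                        (j.donor_end - left + 1, j.donor_end),
                        (j.acceptor_start, j.acceptor_start + right - 1),
                    ),
                )
            )
    for i in range(n_nonspanning):
        s, e = t.exons[rng.randrange(len(t.exons))]
        length = min(read_len, e - s + 1)
        start = rng.randint(s, e - length + 1)
        reads.append(
            AlignmentRecord(
                read_id=f"{t.transcript_id}.E.{i}",
                chrom=t.chrom,
                blocks=((start, start + length - 1),),
            )
        )
    return reads
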