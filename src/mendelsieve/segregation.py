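"""Pedigree segregation models: recessive-homozygous, compound-heterozygous
with trans-phase inference from parental genotypes, and dominant with an
incomplete-penetrance mode.

All models are autosomal. Genotype phase in the input is ignored: compound
heterozygosity is established purely from pedigree transmission. A pair of
variants is accepted in trans only when the genotype configuration *forces*
trans: among all haplotype assignments consistent with Mendelian
transmission of the two sites (no recombination within a gene), every one
places the two variants on different parental haplotypes in every affected
member. In the common case this reduces to each parent of an affected
carrying exactly one of the two variants; a parent heterozygous for both
usually leaves phase ambiguous (``phase_unknown``), and a configuration
where both alleles can only have arrived on one parental haplotype is cis
and is rejected outright.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .pedigree import Affection, Individual, Pedigree
from .variants import VariantRecord, Zygosity


class SegregationError(ValueError):
    pass


class ModelType(Enum):
    AR_HOM = "AR_hom"
    COMP_HET = "comp_het"
    AD_STRICT = "AD_strict"
    AD_INCOMPLETE = "AD_incomplete_penetrance"
    KNOWN_GENE_REVIEW = "known_gene_review"


class ExceptionKind(Enum):
    UNAFFECTED_CARRIER = "unaffected_carrier"
    PHASE_UNKNOWN = "phase_unknown"
    MISSING_GENOTYPE = "missing_genotype"


@dataclass(frozen=True)
class SegException:
    individual_id: str
    kind: ExceptionKind


@dataclass(frozen=True)
class SegregationConfig:
    """Strictness knobs shared by all models.

    ``strict_missing``: a missing genotype in a pedigree member fails the
    model (the study had complete genotypes for all twenty members);
    lenient mode treats missing as compatible.
    ``allow_phase_unknown``: accept comp-het pairs whose trans configuration
    cannot be forced from parental genotypes.
    """

    strict_missing: bool = True
    allow_phase_unknown: bool = False


@dataclass(frozen=True)
class SegregationResult:
    family_id: str
    model: ModelType
    variants: tuple[str, ...]  # one key, or two for comp_het
    fits: bool
    carriers: dict[str, tuple[Zygosity, ...]]  # member -> zygosity per variant
    exceptions: tuple[SegException, ...] = ()

    def carriers_of_all(self) -> list[str]:
        return [
            iid
            for iid, zs in self.carriers.items()
            if all(z in (Zygosity.HET, Zygosity.HOM_ALT) for z in zs)
        ]


_CARRIER = (Zygosity.HET, Zygosity.HOM_ALT)


def _zygosities(
    v: VariantRecord, ped: Pedigree
) -> dict[str, Zygosity]:
    return {m.individual_id: v.zygosity(m.individual_id) for m in ped.members}


def _missing_exceptions(
    zyg: Mapping[str, Zygosity]
) -> list[SegException]:
    return [
        SegException(iid, ExceptionKind.MISSING_GENOTYPE)
        for iid, z in zyg.items()
        if z is Zygosity.MISSING
    ]


def fits_recessive_hom(
    v: VariantRecord,
    ped: Pedigree,
    config: SegregationConfig = SegregationConfig(),
) -> SegregationResult:
    """Autosomal-recessive homozygous model.

    Fits when every affected member is homozygous for the ALT allele, no
    unaffected member is, and every genotyped parent of an affected member
    is heterozygous (the obligate-carrier constraint).
    """
    zyg = _zygosities(v, ped)
    exceptions = _missing_exceptions(zyg)
    fits = True
    for m in ped.members:
        z = zyg[m.individual_id]
        if z is Zygosity.MISSING:
            if config.strict_missing:
                fits = False
            continue
        if m.affected is Affection.AFFECTED and z is not Zygosity.HOM_ALT:
            fits = False
        if m.affected is Affection.UNAFFECTED and z is Zygosity.HOM_ALT:
            fits = False
    for aff in ped.affected_members():
        for parent in ped.parents_of(aff.individual_id):
            if parent is None:
                continue
            z = zyg[parent.individual_id]
            if z is Zygosity.MISSING:
                if config.strict_missing:
                    fits = False
                continue
            if z is not Zygosity.HET:
                fits = False
    return SegregationResult(
        family_id=ped.family_id,
        model=ModelType.AR_HOM,
        variants=(v.key,),
        fits=fits,
        carriers={iid: (z,) for iid, z in zyg.items()},
        exceptions=tuple(exceptions),
    )


def fits_dominant(
    v: VariantRecord,
    ped: Pedigree,
    mode: str = "strict",
    config: SegregationConfig = SegregationConfig(),
) -> SegregationResult:
    """Autosomal-dominant model.

    ``strict``: every affected member carries the ALT allele and no
    unaffected member does (de novo in a single affected child is allowed).
    ``incomplete_penetrance``: every affected member is a carrier;
    unaffected carriers are tolerated but each is reported as an
    ``unaffected_carrier`` exception.
    """
    if mode not in ("strict", "incomplete_penetrance"):
        raise SegregationError(f"unknown dominant mode {mode!r}")
    zyg = _zygosities(v, ped)
    exceptions = _missing_exceptions(zyg)
    fits = True
    for m in ped.members:
        z = zyg[m.individual_id]
        if z is Zygosity.MISSING:
            if config.strict_missing:
                fits = False
            continue
        carrier = z in _CARRIER
        if m.affected is Affection.AFFECTED and not carrier:
            fits = False
        if m.affected is Affection.UNAFFECTED and carrier:
            if mode == "strict":
                fits = False
            else:
                exceptions.append(
                    SegException(
                        m.individual_id, ExceptionKind.UNAFFECTED_CARRIER
                    )
                )
    model = (
        ModelType.AD_STRICT if mode == "strict" else ModelType.AD_INCOMPLETE
    )
    return SegregationResult(
        family_id=ped.family_id,
        model=model,
        variants=(v.key,),
        fits=fits,
        carriers={iid: (z,) for iid, z in zyg.items()},
        exceptions=tuple(exceptions),
    )


# A haplotype is (carries_a, carries_b); an individual is an ordered pair
# (paternal hap, maternal hap).
_HAPS = ((False, False), (True, False), (False, True), (True, True))


def _member_hap_pairs(
    na: Optional[int], nb: Optional[int]
) -> list[tuple[tuple[bool, bool], tuple[bool, bool]]]:
    """Ordered haplotype pairs consistent with per-variant alt counts.

    ``None`` (missing genotype) leaves that variant unconstrained.
    """
    out = []
    for h1 in _HAPS:
        for h2 in _HAPS:
            if na is not None and h1[0] + h2[0] != na:
                continue
            if nb is not None and h1[1] + h2[1] != nb:
                continue
            out.append((h1, h2))
    return out


_ALT_COUNT = {
    Zygosity.HOM_REF: 0,
    Zygosity.HET: 1,
    Zygosity.HOM_ALT: 2,
    Zygosity.MISSING: None,
}


def _trans_classification(
    ped: Pedigree,
    za: Mapping[str, Zygosity],
    zb: Mapping[str, Zygosity],
    max_assignments: int = 1_000_000,
) -> str:
    """Classify the pair's phase over all transmission-consistent assignments.

    Enumerates every assignment of two-site haplotypes to family members
    that respects the observed genotypes and Mendelian transmission (a
    child's paternal haplotype must be one of the father's two, likewise
    maternal; an absent parent leaves that haplotype free; recombination
    between the two sites of one gene is ignored). Returns:

    - ``"trans"``: assignments exist and all place the two variants on
      different haplotypes in every affected member (trans is forced);
    - ``"cis"``: assignments exist but none is trans for all affecteds;
    - ``"ambiguous"``: both trans and non-trans assignments exist;
    - ``"inconsistent"``: no Mendelian-consistent assignment exists.
    """
    # parents before children
    ordered: list[Individual] = []
    placed: set[str] = set()
    pending = list(ped.members)
    while pending:
        progressed = False
        for m in list(pending):
            deps = [p for p in (m.father_id, m.mother_id) if p in ped]
            if all(d in placed for d in deps):
                ordered.append(m)
                placed.add(m.individual_id)
                pending.remove(m)
                progressed = True
        if not progressed:  # pragma: no cover - pedigrees are validated acyclic
            raise SegregationError("cannot order pedigree members")

    options = {
        m.individual_id: _member_hap_pairs(
            _ALT_COUNT[za[m.individual_id]], _ALT_COUNT[zb[m.individual_id]]
        )
        for m in ped.members
    }
    total = 1
    for opts in options.values():
        total *= max(len(opts), 1)
        if total > max_assignments:
            return "ambiguous"

    affected_ids = [m.individual_id for m in ped.affected_members()]
    exists_trans = exists_nontrans = False

    def assignment_is_trans(
        haps: dict[str, tuple[tuple[bool, bool], tuple[bool, bool]]]
    ) -> bool:
        for iid in affected_ids:
            h1, h2 = haps[iid]
            if (h1[0] and h1[1]) or (h2[0] and h2[1]):
                return False
        return True

    def walk(
        idx: int,
        haps: dict[str, tuple[tuple[bool, bool], tuple[bool, bool]]],
    ) -> None:
        nonlocal exists_trans, exists_nontrans
        if exists_trans and exists_nontrans:
            return
        if idx == len(ordered):
            if assignment_is_trans(haps):
                exists_trans = True
            else:
                exists_nontrans = True
            return
        m = ordered[idx]
        father = m.father_id if m.father_id in ped else None
        mother = m.mother_id if m.mother_id in ped else None
        for h1, h2 in options[m.individual_id]:
            if father is not None and h1 not in haps[father]:
                continue
            if mother is not None and h2 not in haps[mother]:
                continue
            haps[m.individual_id] = (h1, h2)
            walk(idx + 1, haps)
            del haps[m.individual_id]

    walk(0, {})
    if not exists_trans and not exists_nontrans:
        return "inconsistent"
    if exists_trans and exists_nontrans:
        return "ambiguous"
    return "trans" if exists_trans else "cis"


def _comp_het_pair(
    a: VariantRecord,
    b: VariantRecord,
    ped: Pedigree,
    config: SegregationConfig,
) -> SegregationResult:
    za = _zygosities(a, ped)
    zb = _zygosities(b, ped)
    exceptions: list[SegException] = []
    for iid in za:
        if za[iid] is Zygosity.MISSING or zb[iid] is Zygosity.MISSING:
            exceptions.append(
                SegException(iid, ExceptionKind.MISSING_GENOTYPE)
            )
    fits = True
    if config.strict_missing and exceptions:
        fits = False

    parent_ids = {
        pid
        for aff in ped.affected_members()
        for pid in (aff.father_id, aff.mother_id)
        if pid is not None
    }
    for m in ped.members:
        za_m, zb_m = za[m.individual_id], zb[m.individual_id]
        if m.affected is Affection.AFFECTED:
            # a true compound heterozygote is het for both variants
            if za_m is not Zygosity.MISSING and za_m is not Zygosity.HET:
                fits = False
            if zb_m is not Zygosity.MISSING and zb_m is not Zygosity.HET:
                fits = False
        elif m.affected is Affection.UNAFFECTED:
            # an unaffected double carrier vetoes the pair, except a parent
            # of an affected member: there the double carriage is a phase
            # question (cis, or trans with incomplete penetrance), settled
            # by the transmission enumeration below
            if (
                za_m in _CARRIER
                and zb_m in _CARRIER
                and m.individual_id not in parent_ids
            ):
                fits = False

    phase = _trans_classification(ped, za, zb)
    if phase in ("cis", "inconsistent"):
        fits = False
    elif phase == "trans":
        # a double-carrier parent whose phase is pinned to trans is an
        # unaffected compound heterozygote, tolerable only under
        # incomplete penetrance: flag it
        for m in ped.members:
            if (
                m.affected is Affection.UNAFFECTED
                and m.individual_id in parent_ids
                and za[m.individual_id] in _CARRIER
                and zb[m.individual_id] in _CARRIER
            ):
                exceptions.append(
                    SegException(
                        m.individual_id, ExceptionKind.UNAFFECTED_CARRIER
                    )
                )
    elif phase == "ambiguous":
        for aff in ped.affected_members():
            exceptions.append(
                SegException(aff.individual_id, ExceptionKind.PHASE_UNKNOWN)
            )
        if not config.allow_phase_unknown:
            fits = False

    keys = tuple(sorted((a.key, b.key)))
    ordered = (a, b) if keys[0] == a.key else (b, a)
    zmaps = (za, zb) if keys[0] == a.key else (zb, za)
    return SegregationResult(
        family_id=ped.family_id,
        model=ModelType.COMP_HET,
        variants=keys,
        fits=fits,
        carriers={
            iid: (zmaps[0][iid], zmaps[1][iid]) for iid in zmaps[0]
        },
        exceptions=tuple(exceptions),
    )


def find_compound_het(
    variants: Sequence[VariantRecord],
    ped: Pedigree,
    config: SegregationConfig = SegregationConfig(),
) -> list[SegregationResult]:
    """Evaluate every unordered pair of same-gene variants for comp-het fit.

    Returns one result per pair (fitting or not); callers typically keep
    ``fits`` rows. Fewer than two variants yields an empty list.
    """
    results = []
    for a, b in itertools.combinations(
        sorted(variants, key=lambda v: v.key), 2
    ):
        if a.key == b.key:
            continue
        results.append(_comp_het_pair(a, b, ped, config))
    return results


def known_gene_review(
    records: Sequence[VariantRecord],
    gene_id: str,
    transcripts: Sequence,
    coding_sequences: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """All variants annotated to a known disease gene, unfiltered.

    Mirrors the manual-review step applied to an established disease gene:
    every variant touching any transcript of ``gene_id`` is returned
    regardless of frequency, predicted impact, or segregation fit.
    """
    from .annotation import Effect, annotate_all_transcripts

    out = []
    for v in records:
        for c in annotate_all_transcripts(v, transcripts, coding_sequences):
            if c.gene_id == gene_id and c.effect is not Effect.INTERGENIC:
                out.append(v)
                break
    return out


def segregation_scan(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    transcripts: Sequence,
    coding_sequences: Optional[Mapping[str, str]] = None,
    models: Sequence[str] = ("ar_hom", "comp_het", "ad"),
    penetrance_mode: str = "incomplete_penetrance",
    config: SegregationConfig = SegregationConfig(),
    include_potentially_altering: bool = False,
    report_all: bool = False,
) -> list[SegregationResult]:
    """Apply every enabled inheritance model to each variant in one family.

    ``records`` are assumed already frequency-filtered biallelic sites;
    impact filtering (protein-altering on any isoform) happens here because
    gene-level collapsing is needed to group comp-het candidates. Raises
    :class:`SegregationError` if a pedigree member is absent from the
    genotype columns.
    """
    from .annotation import protein_altering_genes

    for m in ped.members:
        for v in records:
            if m.individual_id not in v.genotypes:
                raise SegregationError(
                    f"pedigree member {m.individual_id!r} has no genotype "
                    f"column at {v.key}"
                )

    carried = [
        v
        for v in records
        if any(
            v.zygosity(m.individual_id) in _CARRIER for m in ped.members
        )
    ]
    gene_map: dict[str, list[VariantRecord]] = {}
    altering: list[VariantRecord] = []
    for v in carried:
        genes = protein_altering_genes(
            v, transcripts, coding_sequences, include_potentially_altering
        )
        if genes:
            altering.append(v)
        for g in sorted(genes):
            gene_map.setdefault(g, []).append(v)

    results: list[SegregationResult] = []
    if "ar_hom" in models:
        for v in altering:
            results.append(fits_recessive_hom(v, ped, config))
    if "ad" in models:
        for v in altering:
            results.append(fits_dominant(v, ped, penetrance_mode, config))
    if "comp_het" in models:
        for gene in sorted(gene_map):
            results.extend(find_compound_het(gene_map[gene], ped, config))
    if not report_all:
        results = [r for r in results if r.fits]
    return results
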