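"""The prioritization funnel: rarity -> impact -> segregation -> panel ->
known-gene review.

Stages run in a fixed order on the joint cohort: multiallelic sites are
split; variants above the population-frequency ceiling are removed (max
across reference cohorts, default 0.2%); non-protein-altering variants are
removed (on every isoform); each family is tested against the enabled
inheritance models; candidates are intersected with the disease-gene panel;
and finally every variant in an explicitly reviewed gene is added back per
family regardless of earlier filters. The funnel records the number of
distinct surviving variants after each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .annotation import (
    FrequencyTable,
    TranscriptModel,
    annotate_all_transcripts,
    is_protein_altering,
    max_population_af,
)
from .pedigree import Pedigree
from .segregation import (
    ModelType,
    SegregationConfig,
    SegregationResult,
    known_gene_review,
    segregation_scan,
)
from .variants import (
    CandidateReport,
    CandidateRow,
    VariantRecord,
    Zygosity,
    split_multiallelic,
)

logger = logging.getLogger("mendelsieve")

DEFAULT_MAX_AF = 0.002  # the 0.2% rarity ceiling, strict inequality


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Funnel configuration.

    ``max_af``: variants with maximum reference-cohort frequency strictly
    above this are filtered out (default 0.2%). ``models`` enables
    inheritance models; ``penetrance_mode`` selects strict or
    incomplete-penetrance dominance. ``panel_genes`` restricts candidates to
    a disease-gene panel (skipped when empty and ``panel_optional``);
    ``review_genes`` are unconditionally re-reviewed genes whose variants
    surface even without a fitting model.
    """

    max_af: float = DEFAULT_MAX_AF
    include_potentially_altering: bool = False
    models: tuple[str, ...] = ("ar_hom", "comp_het", "ad")
    penetrance_mode: str = "incomplete_penetrance"
    panel_genes: frozenset[str] = frozenset()
    panel_optional: bool = True
    review_genes: frozenset[str] = frozenset()
    strict_missing: bool = True
    allow_phase_unknown: bool = False
    report_all: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_af <= 1.0:
            raise PipelineError(f"max_af {self.max_af} outside [0, 1]")
        if not self.models:
            raise PipelineError("at least one segregation model is required")

    @property
    def segregation(self) -> SegregationConfig:
        return SegregationConfig(
            strict_missing=self.strict_missing,
            allow_phase_unknown=self.allow_phase_unknown,
        )


#: reporting precedence when several models fit the same family/variant
_MODEL_PRIORITY = {
    ModelType.AR_HOM: 0,
    ModelType.COMP_HET: 1,
    ModelType.AD_STRICT: 2,
    ModelType.AD_INCOMPLETE: 3,
    ModelType.KNOWN_GENE_REVIEW: 4,
}


def _result_genes(
    result: SegregationResult,
    gene_by_key: Mapping[str, set[str]],
) -> set[str]:
    genes: set[str] = set()
    for key in result.variants:
        genes |= gene_by_key.get(key, set())
    return genes


def intersect_panel(
    results: Sequence[CandidateRow],
    panel_genes: frozenset[str],
    panel_optional: bool = True,
) -> list[CandidateRow]:
    """Keep rows whose gene is on the panel; identity for an empty optional panel."""
    if not panel_genes and panel_optional:
        return list(results)
    return [r for r in results if r.gene_id in panel_genes]


def funnel_counts(report: CandidateReport) -> list[tuple[str, int]]:
    """Ordered (stage, surviving distinct variant count) pairs."""
    return list(report.funnel)


def run_pipeline(
    records: Sequence[VariantRecord],
    pedigrees: Sequence[Pedigree],
    transcripts: Sequence[TranscriptModel],
    freqs: FrequencyTable,
    config: PipelineConfig = PipelineConfig(),
    coding_sequences: Optional[Mapping[str, str]] = None,
) -> CandidateReport:
    """Run the full funnel over a joint cohort and emit the candidate report.

    Every pedigree member must be a sample of every record (joint-called
    cohort); violating that is an error. Unknown gene ids in the panel or
    review sets produce a warning only. Output ordering is deterministic.
    """
    for ped in pedigrees:
        for m in ped.members:
            for v in records:
                if m.individual_id not in v.genotypes:
                    raise PipelineError(
                        f"pedigree member {m.individual_id!r} is not a "
                        f"sample of the cohort at {v.key}"
                    )
                break  # sample columns are uniform across records

    known_genes = {t.gene_id for t in transcripts}
    for label, genes in (
        ("panel", config.panel_genes),
        ("review", config.review_genes),
    ):
        unknown = set(genes) - known_genes
        if unknown:
            logger.warning(
                "%s gene(s) not in transcript set: %s",
                label,
                ", ".join(sorted(unknown)),
            )

    funnel: list[tuple[str, int]] = [("input_sites", len(records))]
    biallelic: list[VariantRecord] = []
    for v in records:
        biallelic.extend(split_multiallelic(v))
    funnel.append(("biallelic", len(biallelic)))
    logger.info("stage biallelic: %d variants", len(biallelic))

    rare = [
        v for v in biallelic if max_population_af(v, freqs) <= config.max_af
    ]
    funnel.append(("rare", len(rare)))
    logger.info("stage rare (max AF <= %g): %d variants", config.max_af, len(rare))

    gene_by_key: dict[str, set[str]] = {}
    altering: list[VariantRecord] = []
    for v in rare:
        consequences = annotate_all_transcripts(
            v, transcripts, coding_sequences
        )
        genes = {
            c.gene_id
            for c in consequences
            if c.gene_id is not None
            and is_protein_altering(c, config.include_potentially_altering)
        }
        if genes:
            altering.append(v)
            gene_by_key[v.key] = genes
    funnel.append(("protein_altering", len(altering)))
    logger.info("stage protein-altering: %d variants", len(altering))

    # per-family segregation (families are independent)
    fitting: list[SegregationResult] = []
    for ped in pedigrees:
        fitting.extend(
            segregation_scan(
                altering,
                ped,
                transcripts,
                coding_sequences,
                models=config.models,
                penetrance_mode=(
                    "strict"
                    if config.penetrance_mode == "strict"
                    else "incomplete_penetrance"
                ),
                config=config.segregation,
                include_potentially_altering=config.include_potentially_altering,
                report_all=config.report_all,
            )
        )

    # one row per family/variant-set, best-priority model first
    best: dict[tuple[str, tuple[str, ...]], SegregationResult] = {}
    for r in sorted(
        fitting, key=lambda r: (_MODEL_PRIORITY[r.model], r.variants)
    ):
        if not r.fits and not config.report_all:
            continue
        best.setdefault((r.family_id, r.variants), r)
    # drop single-variant AD rows for variants already explained by a
    # higher-priority model in the same family
    rows: list[CandidateRow] = []
    for (family_id, variants), r in sorted(best.items()):
        if r.model in (ModelType.AD_STRICT, ModelType.AD_INCOMPLETE):
            explained = {
                key
                for (fam, vs), other in best.items()
                if fam == family_id
                and _MODEL_PRIORITY[other.model] < _MODEL_PRIORITY[r.model]
                for key in vs
            }
            if set(variants) <= explained:
                continue
        genes = _result_genes(r, gene_by_key)
        rows.append(
            CandidateRow(
                family_id=family_id,
                gene_id=min(genes) if genes else "",
                variants=r.variants,
                model=r.model.value,
                zygosities=r.carriers,
                notes=";".join(
                    f"{e.individual_id}:{e.kind.value}" for e in r.exceptions
                ),
            )
        )
    funnel.append(
        ("segregating", len({k for row in rows for k in row.variants}))
    )

    rows = intersect_panel(rows, config.panel_genes, config.panel_optional)
    funnel.append(("panel", len({k for row in rows for k in row.variants})))
    logger.info("stage panel: %d rows", len(rows))

    # known-gene review: unconditional addition, after the panel so a review
    # gene outside the panel still surfaces
    peds_by_id = {ped.family_id: ped for ped in pedigrees}
    reported = {(row.family_id, key) for row in rows for key in row.variants}
    for gene in sorted(config.review_genes):
        for v in known_gene_review(
            biallelic, gene, transcripts, coding_sequences
        ):
            for ped in pedigrees:
                carried = any(
                    v.zygosity(m.individual_id)
                    in (Zygosity.HET, Zygosity.HOM_ALT)
                    for m in ped.members
                )
                if not carried or (ped.family_id, v.key) in reported:
                    continue
                reported.add((ped.family_id, v.key))
                rows.append(
                    CandidateRow(
                        family_id=ped.family_id,
                        gene_id=gene,
                        variants=(v.key,),
                        model=ModelType.KNOWN_GENE_REVIEW.value,
                        zygosities={
                            m.individual_id: (v.zygosity(m.individual_id),)
                            for m in ped.members
                        },
                        notes="unfiltered review of known disease gene",
                    )
                )
    funnel.append(
        ("with_review", len({k for row in rows for k in row.variants}))
    )

    rows.sort(key=lambda r: (r.family_id, r.gene_id, r.variants, r.model))
    return CandidateReport(rows=rows, funnel=funnel)
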