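"""Transcript-isoform-aware consequence annotation and population rarity.

A variant is projected onto every transcript model that spans it, giving one
:class:`Consequence` per isoform. The same genomic substitution can be a
missense change on one isoform and intronic on another — both consequences
are retained, because recessive inheritance may pair variants annotated on
different isoforms of the same gene.

Coordinates are 1-based inclusive throughout (VCF/GFF convention). CDS
positions ("c." coordinates) count along the spliced coding sequence in
translation order, so they are strand-aware; codon index is ceil(c/3).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .variants import VariantRecord


class AnnotationError(ValueError):
    pass


class ReferenceMismatchError(AnnotationError):
    """Coding sequence and variant REF disagree — wrong strand or fixture."""


class Effect(Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    NONCODING_FOR_THIS_TRANSCRIPT = "noncoding_for_this_transcript"
    INTERGENIC = "intergenic"


#: Fixed severity order used for gene-level collapsing (higher = more severe).
SEVERITY: dict[Effect, int] = {
    Effect.STOP_GAINED: 10,
    Effect.FRAMESHIFT: 9,
    Effect.STOP_LOST: 8,
    Effect.START_LOST: 8,
    Effect.SPLICE_SITE: 7,
    Effect.MISSENSE: 6,
    Effect.INFRAME_INDEL: 5,
    Effect.SPLICE_REGION: 4,
    Effect.SYNONYMOUS: 3,
    Effect.NONCODING_FOR_THIS_TRANSCRIPT: 1,
    Effect.INTERGENIC: 0,
}

#: Effects that always count as protein-altering.
PROTEIN_ALTERING: frozenset[Effect] = frozenset(
    {
        Effect.MISSENSE,
        Effect.STOP_GAINED,
        Effect.STOP_LOST,
        Effect.START_LOST,
        Effect.FRAMESHIFT,
        Effect.INFRAME_INDEL,
        Effect.SPLICE_SITE,
    }
)

# Intronic distances from the exon edge: 1-2 = splice site (canonical GT/AG
# dinucleotides), 3-8 = splice region ("potentially protein-altering").
_SPLICE_SITE_RANGE = (1, 2)
_SPLICE_REGION_RANGE = (3, 8)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one isoform; intervals 1-based inclusive."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]
    cds_start: int  # genomic, cds_start <= cds_end regardless of strand
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise AnnotationError(f"exon interval {start}-{end} inverted")
            if start <= prev_end:
                raise AnnotationError("exons must be sorted and non-overlapping")
            prev_end = end
        if not self._contained(self.cds_start) or not self._contained(self.cds_end):
            raise AnnotationError("CDS bounds must fall within exons")
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"spliced CDS length {self.cds_length} of "
                f"{self.transcript_id} not divisible by 3"
            )

    def _contained(self, gpos: int) -> bool:
        return any(s <= gpos <= e for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon pieces inside the CDS, in genomic order."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs <= ce:
                out.append((cs, ce))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Consequence:
    """Effect of one variant on one transcript (or intergenic marker)."""

    transcript_id: Optional[str]
    gene_id: Optional[str]
    effect: Effect
    cds_pos: Optional[int] = None
    codon_index: Optional[int] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None

    @property
    def severity(self) -> int:
        return SEVERITY[self.effect]


# -- coordinate arithmetic ----------------------------------------------------


def project_genomic_to_cds(t: TranscriptModel, gpos: int) -> Optional[int]:
    """Spliced CDS coordinate of a genomic position, or None if non-coding.

    Counts 1-based in translation order: ascending genomic order on "+",
    descending on "-" (position ``cds_end`` maps to 1 on the minus strand).
    """
    offset = 0
    if t.strand == "+":
        for s, e in t.cds_intervals:
            if s <= gpos <= e:
                return offset + (gpos - s) + 1
            offset += e - s + 1
    else:
        for s, e in reversed(t.cds_intervals):
            if s <= gpos <= e:
                return offset + (e - gpos) + 1
            offset += e - s + 1
    return None


def cds_position_to_codon(cds_pos: int) -> int:
    """Codon index of a CDS coordinate: ceil(c/3); e.g. c.392 -> codon 131."""
    if cds_pos < 1:
        raise AnnotationError(f"CDS position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)


def codon_change(
    coding_sequence: str,
    cds_pos: int,
    ref_base: str,
    alt_base: str,
) -> tuple[str, str, Effect]:
    """Amino-acid change of a single-nucleotide substitution.

    ``ref_base``/``alt_base`` must already be in translation orientation
    (complemented for minus-strand transcripts). Returns one-letter codes,
    with '*' for a stop, and the effect class.
    """
    if not 1 <= cds_pos <= len(coding_sequence):
        raise AnnotationError(
            f"CDS position {cds_pos} outside coding sequence "
            f"of length {len(coding_sequence)}"
        )
    if coding_sequence[cds_pos - 1].upper() != ref_base.upper():
        raise ReferenceMismatchError(
            f"coding sequence has {coding_sequence[cds_pos - 1]!r} at "
            f"c.{cds_pos}, variant REF is {ref_base!r}"
        )
    codon_idx = cds_position_to_codon(cds_pos)
    start = (codon_idx - 1) * 3
    ref_codon = coding_sequence[start : start + 3].upper()
    within = cds_pos - 1 - start
    alt_codon = (
        ref_codon[:within] + alt_base.upper() + ref_codon[within + 1 :]
    )
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        effect = Effect.SYNONYMOUS
    elif aa_alt == "*":
        effect = Effect.STOP_GAINED
    elif aa_ref == "*":
        effect = Effect.STOP_LOST
    elif codon_idx == 1:
        effect = Effect.START_LOST
    else:
        effect = Effect.MISSENSE
    return aa_ref, aa_alt, effect


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _intronic_effect(t: TranscriptModel, gpos: int) -> Optional[Effect]:
    for istart, iend in t.intron_intervals():
        if istart <= gpos <= iend:
            dist = min(gpos - istart, iend - gpos) + 1
            if _SPLICE_SITE_RANGE[0] <= dist <= _SPLICE_SITE_RANGE[1]:
                return Effect.SPLICE_SITE
            if _SPLICE_REGION_RANGE[0] <= dist <= _SPLICE_REGION_RANGE[1]:
                return Effect.SPLICE_REGION
            return Effect.NONCODING_FOR_THIS_TRANSCRIPT
    return None


def annotate_transcript(
    v: VariantRecord,
    t: TranscriptModel,
    coding_sequence: Optional[str] = None,
) -> Consequence:
    """Consequence of a (biallelic) variant on a single spanning transcript."""
    gpos = v.pos
    alt = v.alts[0]
    base = dict(
        transcript_id=t.transcript_id, gene_id=t.gene_id
    )
    if len(v.ref) != len(alt):
        # indel: classify by frame only (no repeat left-alignment)
        cds_pos = project_genomic_to_cds(t, gpos)
        if cds_pos is None:
            eff = _intronic_effect(t, gpos)
            return Consequence(
                effect=eff or Effect.NONCODING_FOR_THIS_TRANSCRIPT, **base
            )
        shift = abs(len(v.ref) - len(alt)) % 3
        effect = Effect.FRAMESHIFT if shift else Effect.INFRAME_INDEL
        return Consequence(
            effect=effect,
            cds_pos=cds_pos,
            codon_index=cds_position_to_codon(cds_pos),
            **base,
        )
    cds_pos = project_genomic_to_cds(t, gpos)
    if cds_pos is None:
        eff = _intronic_effect(t, gpos)
        return Consequence(
            effect=eff or Effect.NONCODING_FOR_THIS_TRANSCRIPT, **base
        )
    if coding_sequence is None:
        raise AnnotationError(
            f"coding sequence for {t.transcript_id} required to annotate "
            f"a coding substitution at {v.chrom}:{v.pos}"
        )
    ref_b, alt_b = v.ref, alt
    if t.strand == "-":
        ref_b = ref_b.translate(_COMPLEMENT)
        alt_b = alt_b.translate(_COMPLEMENT)
    aa_ref, aa_alt, effect = codon_change(coding_sequence, cds_pos, ref_b, alt_b)
    return Consequence(
        effect=effect,
        cds_pos=cds_pos,
        codon_index=cds_position_to_codon(cds_pos),
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        **base,
    )


def annotate_all_transcripts(
    v: VariantRecord,
    transcripts: Iterable[TranscriptModel],
    coding_sequences: Optional[Mapping[str, str]] = None,
) -> list[Consequence]:
    """One consequence per transcript spanning the variant.

    A variant inside no transcript span yields a single intergenic marker.
    Consequences on different isoforms of the same gene are all retained.
    """
    coding_sequences = coding_sequences or {}
    out: list[Consequence] = []
    for t in transcripts:
        lo, hi = t.span
        if t.chrom == v.chrom and lo <= v.pos <= hi:
            out.append(
                annotate_transcript(v, t, coding_sequences.get(t.transcript_id))
            )
    if not out:
        out.append(Consequence(None, None, Effect.INTERGENIC))
    return out


def is_protein_altering(
    c: Consequence, include_potentially_altering: bool = False
) -> bool:
    """Whether a consequence passes the impact filter.

    Splice-region changes (intronic bases 3-8 from the junction) count only
    when ``include_potentially_altering`` is set.
    """
    if c.effect in PROTEIN_ALTERING:
        return True
    return include_potentially_altering and c.effect is Effect.SPLICE_REGION


def protein_altering_genes(
    v: VariantRecord,
    transcripts: Iterable[TranscriptModel],
    coding_sequences: Optional[Mapping[str, str]] = None,
    include_potentially_altering: bool = False,
) -> set[str]:
    """Gene-level collapsing: genes with >=1 protein-altering consequence."""
    return {
        c.gene_id
        for c in annotate_all_transcripts(v, transcripts, coding_sequences)
        if c.gene_id is not None
        and is_protein_altering(c, include_potentially_altering)
    }


# -- population frequency -----------------------------------------------------


class FrequencyTable:
    """Per-source allele frequencies keyed by (chrom, pos, ref, alt).

    Absent keys mean the variant has never been observed in any reference
    cohort and score an allele frequency of 0.
    """

    def __init__(
        self,
        entries: Optional[
            Mapping[tuple[str, int, str, str], Mapping[str, float]]
        ] = None,
    ) -> None:
        self._table: dict[tuple[str, int, str, str], dict[str, float]] = {}
        for key, sources in (entries or {}).items():
            for source, af in sources.items():
                self.add(key, source, af)

    def add(
        self, key: tuple[str, int, str, str], source: str, af: float
    ) -> None:
        if not 0.0 <= af <= 1.0:
            raise AnnotationError(f"allele frequency {af} outside [0, 1]")
        self._table.setdefault(key, {})[source] = af

    def sources(self, key: tuple[str, int, str, str]) -> dict[str, float]:
        return dict(self._table.get(key, {}))

    def max_af(self, key: tuple[str, int, str, str]) -> float:
        sources = self._table.get(key)
        return max(sources.values()) if sources else 0.0

    def __len__(self) -> int:
        return len(self._table)

    # TSV columns: chrom, pos, ref, alt, source, af
    @classmethod
    def from_tsv(cls, source: str | os.PathLike) -> "FrequencyTable":
        df = pd.read_csv(source, sep="\t", comment="#", dtype={"chrom": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.add(
                (row.chrom, int(row.pos), row.ref, row.alt),
                row.source,
                float(row.af),
            )
        return table

    def to_tsv(self, path: str | os.PathLike) -> None:
        rows = [
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "source": source,
                "af": af,
            }
            for (chrom, pos, ref, alt), sources in sorted(self._table.items())
            for source, af in sorted(sources.items())
        ]
        pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "source", "af"]
        ).to_csv(path, sep="\t", index=False)


def max_population_af(v: VariantRecord, freqs: FrequencyTable) -> float:
    """Maximum allele frequency across reference cohorts; 0 if unobserved."""
    return freqs.max_af(v.site)


# -- transcript TSV / FASTA interfaces ---------------------------------------

TRANSCRIPT_COLUMNS = (
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "exons",
    "cds_start",
    "cds_end",
)


def _format_exons(exons: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in exons)


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for chunk in text.split(";"):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def read_transcripts_tsv(source: str | os.PathLike) -> list[TranscriptModel]:
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"chrom": str})
    return [
        TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            exons=_parse_exons(row.exons),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
        for row in df.itertuples(index=False)
    ]


def write_transcripts_tsv(
    transcripts: Iterable[TranscriptModel], path: str | os.PathLike
) -> None:
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "exons": _format_exons(t.exons),
            "cds_start": t.cds_start,
            "cds_end": t.cds_end,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows, columns=list(TRANSCRIPT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_coding_fasta(source: str | os.PathLike) -> dict[str, str]:
    """Coding sequences keyed by transcript id, via Biopython."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(os.fspath(source), "fasta")
    }


def write_coding_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for tid in sorted(sequences):
            fh.write(f">{tid}\n")
            seq = sequences[tid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
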