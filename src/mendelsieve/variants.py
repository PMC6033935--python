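"""Multi-sample variant I/O, multiallelic normalization, and the candidate report.

VCF reading and writing is delegated to :mod:`pysam`; in memory a site is a
plain :class:`VariantRecord` with 1-based coordinates and one
:class:`GenotypeCall` per sample. INFO annotations (population allele
frequencies, SIFT/PolyPhen verdicts and the like) are carried as opaque
strings — this package never computes them. Genotype phase flags from the
input are recorded but downstream inheritance logic re-derives phase from
the pedigree, not from phased calls.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pysam


class VariantIOError(ValueError):
    pass


class Zygosity(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid genotype as allele indices; ``None`` marks a missing allele."""

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool = False

    MISSING: "GenotypeCall" = None  # set below

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None and self.allele_b is None

    @property
    def alleles(self) -> tuple[Optional[int], Optional[int]]:
        return (self.allele_a, self.allele_b)

    def alt_count(self, alt_index: int = 1) -> int:
        return sum(1 for a in self.alleles if a == alt_index)

    def zygosity(self, alt_index: int = 1) -> Zygosity:
        """Zygosity with respect to one ALT allele.

        A half-missing call still counts as het when the known allele is the
        ALT (the convention produced by multiallelic splitting); a
        half-missing reference call is indistinguishable from het and is
        reported missing.
        """
        if self.is_missing:
            return Zygosity.MISSING
        n_alt = self.alt_count(alt_index)
        n_known = sum(1 for a in self.alleles if a is not None)
        if n_alt >= 1:
            return Zygosity.HOM_ALT if n_alt == 2 else Zygosity.HET
        return Zygosity.HOM_REF if n_known == 2 else Zygosity.MISSING


GenotypeCall.MISSING = GenotypeCall(None, None)


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site: 1-based position, REF/ALTs, per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alts:
            raise VariantIOError("REF and at least one ALT are required")
        if any(a == self.ref for a in self.alts):
            raise VariantIOError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def key(self) -> str:
        """Canonical variant key, e.g. ``chr11L:1652:A>G`` (first ALT)."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alts[0]}"

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alts[0])

    def zygosity(self, individual_id: str, alt_index: int = 1) -> Zygosity:
        call = self.genotypes.get(individual_id, GenotypeCall.MISSING)
        return call.zygosity(alt_index)


# -- VCF round trip -----------------------------------------------------------


def _stringify_info(value: object) -> str:
    if isinstance(value, (tuple, list)):
        return ",".join(_stringify_info(v) for v in value)
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def read_vcf(source: str | os.PathLike | io.IOBase) -> list[VariantRecord]:
    """Read an uncompressed or bgzipped VCF into VariantRecords.

    ``source`` may be a path or a text stream (streams are spooled to a
    temporary file for pysam). All INFO fields are lifted into
    ``annotations`` as strings.
    """
    if isinstance(source, io.IOBase):
        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return read_vcf(path)
        finally:
            os.unlink(path)

    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(source)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            genotypes: dict[str, GenotypeCall] = {}
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT", (None, None))
                if gt is None or len(gt) == 0:
                    gt = (None, None)
                elif len(gt) == 1:
                    gt = (gt[0], None)
                genotypes[s] = GenotypeCall(gt[0], gt[1], phased=call.phased)
            annotations = {
                k: _stringify_info(v) for k, v in rec.info.items()
            }
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    genotypes=genotypes,
                    annotations=annotations,
                )
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    samples: Optional[Sequence[str]] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write records as VCF 4.2 text. Sample order defaults to first record's."""
    if samples is None:
        samples = []
        seen: set[str] = set()
        for r in records:
            for s in r.genotypes:
                if s not in seen:
                    seen.add(s)
                    samples.append(s)
    contigs: dict[str, int] = dict(contig_lengths or {})
    for r in records:
        need = r.pos + len(r.ref) + 1000
        if contigs.get(r.chrom, 0) < need:
            contigs[r.chrom] = need
    info_keys: list[str] = []
    for r in records:
        for k in r.annotations:
            if k not in info_keys:
                info_keys.append(k)

    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for k in info_keys:
        header.add_meta(
            "INFO",
            items=[
                ("ID", k),
                ("Number", "."),
                ("Type", "String"),
                ("Description", "passthrough annotation"),
            ],
        )
    header.add_meta(
        "FORMAT",
        items=[
            ("ID", "GT"),
            ("Number", "1"),
            ("Type", "String"),
            ("Description", "Genotype"),
        ],
    )
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, *r.alts)
            )
            for k, v in r.annotations.items():
                rec.info[k] = tuple(v.split(",")) if "," in v else v
            for s in samples:
                call = r.genotypes.get(s, GenotypeCall.MISSING)
                rec.samples[s]["GT"] = call.alleles
                rec.samples[s].phased = call.phased
            out.write(rec)


def split_multiallelic(v: VariantRecord) -> list[VariantRecord]:
    """Decompose a site into one biallelic record per ALT.

    Genotype allele indices are remapped per output: the focal ALT becomes 1,
    REF stays 0, and alleles belonging to *other* ALTs become missing.
    Annotation values with exactly one comma-separated entry per ALT are
    split positionally; all others are copied verbatim.
    """
    if v.is_biallelic:
        return [v]
    n_alts = len(v.alts)
    out: list[VariantRecord] = []
    for k, alt in enumerate(v.alts, start=1):
        genotypes = {}
        for sample, call in v.genotypes.items():
            remapped = tuple(
                None if a is None or (a != 0 and a != k) else (1 if a == k else 0)
                for a in call.alleles
            )
            genotypes[sample] = GenotypeCall(
                remapped[0], remapped[1], phased=call.phased
            )
        annotations = {}
        for key, value in v.annotations.items():
            parts = value.split(",")
            annotations[key] = parts[k - 1] if len(parts) == n_alts else value
        out.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alts=(alt,),
                genotypes=genotypes,
                annotations=annotations,
            )
        )
    return out


# -- candidate report ---------------------------------------------------------


@dataclass(frozen=True)
class CandidateRow:
    """One prioritized finding: a variant (or comp-het pair) in one family."""

    family_id: str
    gene_id: str
    variants: tuple[str, ...]  # canonical variant keys
    model: str
    zygosities: dict[str, tuple[Zygosity, ...]]  # member -> per-variant
    notes: str = ""

    def carriers_of_all(self) -> list[str]:
        """Members carrying every variant of the row (het or hom-alt)."""
        return [
            iid
            for iid, zs in self.zygosities.items()
            if all(z in (Zygosity.HET, Zygosity.HOM_ALT) for z in zs)
        ]


@dataclass
class CandidateReport:
    rows: list[CandidateRow] = field(default_factory=list)
    funnel: list[tuple[str, int]] = field(default_factory=list)

    def distinct_variants(self) -> set[str]:
        return {key for row in self.rows for key in row.variants}


def _variant_key_pos(key: str) -> tuple[str, int]:
    chrom, pos, _ = key.split(":", 2)
    return chrom, int(pos)


REPORT_COLUMNS = ("family", "gene", "variant", "model", "zygosities", "notes")


def write_report(report: CandidateReport) -> str:
    """Render the report as deterministic TSV.

    The filter funnel is emitted as a commented header block; rows are
    sorted by (family, gene, position, variant key, model), one line per
    variant (compound-het partners cross-reference each other in notes).
    """
    lines = [f"## funnel\t{stage}\t{count}" for stage, count in report.funnel]
    lines.append("\t".join(REPORT_COLUMNS))
    flat: list[tuple] = []
    for row in report.rows:
        for i, key in enumerate(row.variants):
            partner = [k for k in row.variants if k != key]
            notes = row.notes
            if partner:
                extra = f"in trans with {partner[0]}"
                notes = f"{notes}; {extra}" if notes else extra
            zyg = ";".join(
                f"{iid}={row.zygosities[iid][i].value}"
                for iid in sorted(row.zygosities)
            )
            chrom, pos = _variant_key_pos(key)
            flat.append(
                (
                    row.family_id,
                    row.gene_id,
                    chrom,
                    pos,
                    key,
                    row.model,
                    zyg,
                    notes,
                )
            )
    flat.sort()
    for fam, gene, _chrom, _pos, key, model, zyg, notes in flat:
        lines.append("\t".join((fam, gene, key, model, zyg, notes)))
    return "\n".join(lines) + "\n"
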