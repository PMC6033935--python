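"""Split-read support for isoform-discriminating intron junctions.

Counts RNA-seq reads whose gapped alignment spans an exon-exon junction
exactly: one aligned block ends on the last base of the upstream exon and
the next block starts on the first base of the downstream exon, with at
least ``min_overhang`` aligned bases on each side. Junctions unique to a
single isoform of a gene discriminate that isoform's expression — the kind
of evidence that establishes an alternate transcript is actually made in
the tissue of interest.

Alignments are a minimal SAM subset (QNAME, RNAME, POS, CIGAR with
M/N/S/I/D ops) read and written through pysam; in memory a read is just its
ordered 1-based inclusive aligned blocks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .annotation import TranscriptModel

DEFAULT_MIN_OVERHANG = 3


class JunctionError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionSpec:
    """One intron: last base of the upstream exon, first of the downstream."""

    chrom: str
    donor_end: int
    acceptor_start: int
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start - 1:
            raise JunctionError(
                f"no intron between {self.donor_end} and {self.acceptor_start}"
            )

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor_end, self.acceptor_start)


@dataclass(frozen=True)
class AlignmentRecord:
    """A gapped read alignment: sorted, non-overlapping 1-based blocks."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.blocks:
            if start > end or start <= prev_end:
                raise JunctionError(
                    f"read {self.read_id}: blocks must be sorted, "
                    "non-overlapping, 1-based"
                )
            prev_end = end


def junctions_of(t: TranscriptModel) -> list[JunctionSpec]:
    """One JunctionSpec per adjacent exon pair, in transcript order.

    Coordinates are genomic regardless of strand; for a minus-strand
    transcript, transcript order runs from the genomically last intron to
    the first. Single-exon transcripts have no junctions.
    """
    pairs = [
        JunctionSpec(
            chrom=t.chrom,
            donor_end=t.exons[i][1],
            acceptor_start=t.exons[i + 1][0],
            transcript_id=t.transcript_id,
        )
        for i in range(len(t.exons) - 1)
    ]
    return list(reversed(pairs)) if t.strand == "-" else pairs


def count_junction_reads(
    alignments: Iterable[AlignmentRecord],
    junction: JunctionSpec,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> int:
    """Split reads spanning a junction with exact donor/acceptor match.

    A read counts when two consecutive blocks end exactly at ``donor_end``
    and start exactly at ``acceptor_start`` with >= ``min_overhang`` aligned
    bases on each side. Duplicate read ids are counted once.
    """
    if min_overhang < 1:
        raise JunctionError("min_overhang must be >= 1")
    seen: set[str] = set()
    count = 0
    for aln in alignments:
        if aln.read_id in seen:
            continue
        seen.add(aln.read_id)
        if aln.chrom != junction.chrom:
            continue
        for (s1, e1), (s2, e2) in zip(aln.blocks, aln.blocks[1:]):
            if (
                e1 == junction.donor_end
                and s2 == junction.acceptor_start
                and e1 - s1 + 1 >= min_overhang
                and e2 - s2 + 1 >= min_overhang
            ):
                count += 1
                break
    return count


@dataclass(frozen=True)
class JunctionSupport:
    junction: JunctionSpec
    count: int
    discriminating: bool  # junction found in exactly one transcript


def isoform_support_table(
    alignments: Sequence[AlignmentRecord],
    transcripts: Sequence[TranscriptModel],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> dict[str, list[JunctionSupport]]:
    """Junction read counts for every junction of every transcript.

    A junction shared by several isoforms carries the same count under
    each; junctions private to one isoform are flagged discriminating. An
    isoform with a supported discriminating junction is positively
    expressed.
    """
    alignments = list(alignments)
    junction_owners: dict[tuple[str, int, int], set[str]] = {}
    per_transcript: dict[str, list[JunctionSpec]] = {}
    for t in transcripts:
        per_transcript[t.transcript_id] = junctions_of(t)
        for j in per_transcript[t.transcript_id]:
            junction_owners.setdefault(j.coords, set()).add(t.transcript_id)
    counts = {
        coords: count_junction_reads(
            alignments,
            JunctionSpec(chrom=coords[0], donor_end=coords[1], acceptor_start=coords[2]),
            min_overhang,
        )
        for coords in junction_owners
    }
    return {
        tid: [
            JunctionSupport(
                junction=j,
                count=counts[j.coords],
                discriminating=len(junction_owners[j.coords]) == 1,
            )
            for j in junctions
        ]
        for tid, junctions in per_transcript.items()
    }


def supported_transcripts(
    table: Mapping[str, Sequence[JunctionSupport]], min_reads: int = 1
) -> set[str]:
    """Isoforms with at least one discriminating junction at min_reads."""
    return {
        tid
        for tid, supports in table.items()
        if any(s.discriminating and s.count >= min_reads for s in supports)
    }


def coverage_depth(
    alignments: Iterable[AlignmentRecord], chrom: str, start: int, end: int
) -> list[int]:
    """Per-base block-overlap depth over [start, end], unnormalized."""
    depth = [0] * (end - start + 1)
    for aln in alignments:
        if aln.chrom != chrom:
            continue
        for s, e in aln.blocks:
            lo, hi = max(s, start), min(e, end)
            for pos in range(lo, hi + 1):
                depth[pos - start] += 1
    return depth


# -- SAM subset I/O -----------------------------------------------------------


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1] - 1
            cigar.append((3, gap))  # N
        cigar.append((0, e - s + 1))  # M
    return cigar


def write_sam(
    alignments: Sequence[AlignmentRecord],
    path: str | os.PathLike,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    contigs: dict[str, int] = dict(contig_lengths or {})
    for aln in alignments:
        need = aln.blocks[-1][1] + 1000
        if contigs.get(aln.chrom, 0) < need:
            contigs[aln.chrom] = need
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in sorted(contigs.items())],
        }
    )
    ref_ids = {c: i for i, c in enumerate(sorted(contigs))}
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.flag = 0
            seg.reference_id = ref_ids[aln.chrom]
            seg.reference_start = aln.blocks[0][0] - 1
            seg.mapping_quality = 60
            seg.cigartuples = _blocks_to_cigar(aln.blocks)
            out.write(seg)


def read_sam(path: str | os.PathLike) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            blocks = tuple(
                (start + 1, end) for start, end in seg.get_blocks()
            )
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    blocks=blocks,
                )
            )
    return out
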