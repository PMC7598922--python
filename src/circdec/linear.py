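"""Linear splice-junction counting around called circRNAs.

The linear isoform's abundance at a circle's boundaries is measured by the
reads spliced across its two flanking junctions: from the upstream
flanking exon into the circle's first exon (upstream junction count, UJC)
and from the circle's last exon into the downstream flanking exon
(downstream junction count, DJC). Junctions are taken from gap ('N')
operations in uniquely mapped primary alignments; both flanking exonic
anchors must reach ``min_anchor`` matched bases. UJC and DJC are reported
in genomic orientation (upstream = genomic left), and their sum is the
linear junction count LJC entering the PBI denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pysam

from .backsplice import BackspliceJunction

__all__ = [
    "LinearJunctionEvent",
    "JunctionCountSet",
    "extract_linear_junctions",
    "count_flanking_junctions",
]


@dataclass(frozen=True)
class LinearJunctionEvent:
    """One gap operation of one read: splice from ``donor`` (end of the
    left exon block, exclusive) to ``acceptor`` (start of the right
    block), with the matched anchor lengths on either side."""

    read_id: str
    chrom: str
    strand: str
    donor: int
    acceptor: int
    left_anchor: int
    right_anchor: int

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError("require donor < acceptor")
        if self.left_anchor < 1 or self.right_anchor < 1:
            raise ValueError("anchors must be >= 1")


@dataclass
class JunctionCountSet:
    """Per-circle, per-sample junction counts; ljc is always ujc + djc."""

    cjc: int = 0
    ujc: int = 0
    djc: int = 0

    @property
    def ljc(self) -> int:
        return self.ujc + self.djc

    def __post_init__(self) -> None:
        if min(self.cjc, self.ujc, self.djc) < 0:
            raise ValueError("counts must be >= 0")


def events_from_cigar(
    read_id: str, chrom: str, strand: str, pos: int, cigartuples
) -> list[LinearJunctionEvent]:
    """Junction events from one alignment's CIGAR (pysam op codes).

    Anchors are the reference-consuming (M/D/=/X) block lengths between
    consecutive gaps, so a read spanning several junctions anchors each
    gap on its neighbouring blocks only.
    """
    events = []
    block = 0  # reference-aligned length since last N
    ref = pos
    pending: list[int] = []  # events awaiting their right anchor
    gaps: list[tuple[int, int, int]] = []  # donor, acceptor, left_anchor
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            block += length
            ref += length
        elif op == 3:  # N
            gaps.append((ref, ref + length, block))
            ref += length
            block = 0
        # I, S, H, P: no reference advance
    out = []
    for i, (donor, acceptor, left) in enumerate(gaps):
        right = gaps[i + 1][2] if i + 1 < len(gaps) else block
        if left >= 1 and right >= 1:
            out.append(
                LinearJunctionEvent(read_id, chrom, strand, donor, acceptor, left, right)
            )
    return out


def extract_linear_junctions(
    alignments: str | pysam.AlignmentFile,
    min_anchor: int = 6,
    min_mapq: int = 20,
) -> list[LinearJunctionEvent]:
    """Extract one event per gap per uniquely mapped primary alignment.

    Secondary, supplementary and duplicate-flagged alignments are skipped.
    Uniqueness is operationalised as MAPQ >= ``min_mapq`` (aligners that
    mark unique alignments with MAPQ 255 pass this). Events with either
    anchor below ``min_anchor`` are dropped.
    """
    handle = (
        alignments
        if isinstance(alignments, pysam.AlignmentFile)
        else pysam.AlignmentFile(str(alignments))
    )
    events: list[LinearJunctionEvent] = []
    for aln in handle:
        if (
            aln.is_unmapped
            or aln.is_secondary
            or aln.is_supplementary
            or aln.is_duplicate
        ):
            continue
        if aln.mapping_quality < min_mapq and aln.mapping_quality != 255:
            continue
        if aln.cigartuples is None:
            continue
        strand = "-" if aln.is_reverse else "+"
        for ev in events_from_cigar(
            aln.query_name, aln.reference_name, strand, aln.reference_start,
            aln.cigartuples,
        ):
            if ev.left_anchor >= min_anchor and ev.right_anchor >= min_anchor:
                events.append(ev)
    return events


def count_flanking_junctions(
    events: Iterable[LinearJunctionEvent],
    junctions: list[BackspliceJunction],
    stranded: bool = False,
) -> dict[tuple, JunctionCountSet]:
    """Count UJC/DJC per back-splice junction from linear junction events.

    For a circle [s, e): UJC counts distinct read ids with an event whose
    acceptor is exactly s and donor lies upstream of s; DJC counts events
    whose donor is exactly e and acceptor lies downstream of e. With
    ``stranded`` the event's alignment strand must match the circle's.
    Returns a mapping from junction key to counts (cjc filled from the
    junction's supporting reads).
    """
    by_acceptor: dict[tuple[str, int], list[BackspliceJunction]] = {}
    by_donor: dict[tuple[str, int], list[BackspliceJunction]] = {}
    for j in junctions:
        by_acceptor.setdefault((j.chrom, j.acceptor), []).append(j)
        by_donor.setdefault((j.chrom, j.donor), []).append(j)

    ujc_reads: dict[tuple, set[str]] = {j.key: set() for j in junctions}
    djc_reads: dict[tuple, set[str]] = {j.key: set() for j in junctions}
    for ev in events:
        for j in by_acceptor.get((ev.chrom, ev.acceptor), ()):
            if stranded and ev.strand != j.strand:
                continue
            if ev.donor < j.acceptor:
                ujc_reads[j.key].add(ev.read_id)
        for j in by_donor.get((ev.chrom, ev.donor), ()):
            if stranded and ev.strand != j.strand:
                continue
            if ev.acceptor > j.donor:
                djc_reads[j.key].add(ev.read_id)

    return {
        j.key: JunctionCountSet(
            cjc=j.cjc, ujc=len(ujc_reads[j.key]), djc=len(djc_reads[j.key])
        )
        for j in junctions
    }
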