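"""Back-splice junction calling from chimeric alignments.

A read crossing a circRNA's back-splice junction aligns as two segments on
the same chromosome and strand, both inside one gene, but in *reverse*
order relative to transcription: the read prefix lands downstream (in
genomic coordinates on '+': to the right) of the read suffix. The joined
coordinates — genomic start of the upstream segment (the circle's 5'
boundary, here ``acceptor``) and genomic end of the downstream segment
(the circle's 3' boundary, ``donor``) — define the candidate circle.
Reads supporting the same (chrom, acceptor, donor, strand) are aggregated
into a circular junction count (CJC), deduplicated by read id so a
paired-end fragment counts once.

Input is the STAR ``Chimeric.out.junction`` tab dialect:

    chrA  posA  strandA  chrB  posB  strandB  jtype  repL  repR
    readName  seg1Start  seg1Cigar  seg2Start  seg2Cigar

Genomic positions are 1-based in the file and converted to the internal
0-based half-open convention at parse time. Segment intervals and read
offsets are recomputed from the per-segment CIGARs, which is robust to
the donor/acceptor column conventions differing between aligner versions.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from .annotation import GenomicInterval, SpliceSiteIndex, fetch_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ChimericRecord",
    "BackspliceJunction",
    "parse_chimeric_file",
    "call_backsplices",
    "snap_to_annotation",
    "classify_circ_type",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_OPS = frozenset("MDN=X")
_READ_OPS = frozenset("MIS=X")


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def _ref_span(ops: list[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in _REF_OPS)


def _read_len(ops: list[tuple[int, str]]) -> int:
    return sum(n for n, op in ops if op in _READ_OPS)


def _segment_from_cigar(
    chrom: str, start0: int, strand: str, cigar: str
) -> tuple[GenomicInterval, int]:
    """Genomic interval covered by the aligned part and the 0-based offset of
    that part within the original read (sequencer orientation)."""
    ops = _parse_cigar(cigar)
    leading = ops[0][0] if ops[0][1] == "S" else 0
    aligned_read = sum(n for n, op in ops if op in "MI=X")
    iv = GenomicInterval(chrom, start0, start0 + _ref_span(ops), strand)
    if strand == "+":
        offset = leading
    else:
        # reverse-strand alignment: the read was reverse-complemented, so a
        # leading reference-order clip is the *tail* of the original read
        offset = _read_len(ops) - leading - aligned_read
    return iv, offset


@dataclass(frozen=True)
class ChimericRecord:
    """One read's two-segment chimeric alignment.

    ``seg_a`` is the segment holding the read prefix (read_offset_a <
    read_offset_b). ``junction_donor`` / ``junction_acceptor`` are the join
    coordinates as reported by the aligner (0-based, informational);
    detection recomputes boundaries from the segment intervals.
    """

    read_id: str
    chrom_a: str
    chrom_b: str
    strand_a: str
    strand_b: str
    seg_a: GenomicInterval
    seg_b: GenomicInterval
    read_offset_a: int
    read_offset_b: int
    junction_donor: int = -1
    junction_acceptor: int = -1

    def __post_init__(self) -> None:
        if self.read_offset_a >= self.read_offset_b:
            raise ValueError("seg_a must hold the read prefix (offset_a < offset_b)")


@dataclass
class BackspliceJunction:
    """A called circRNA: genomic boundaries [acceptor, donor), supporting
    reads, and post-annotation gene/type assignment."""

    chrom: str
    acceptor: int  # circle 5' genomic boundary (0-based start)
    donor: int  # circle 3' genomic boundary (exclusive end)
    strand: str
    gene_id: str = "NA"
    circ_type: str = "unclassified"
    supporting_reads: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.acceptor < self.donor:
            raise ValueError("require acceptor < donor")

    @property
    def cjc(self) -> int:
        return len(self.supporting_reads)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.acceptor, self.donor, self.strand)


def parse_chimeric_file(path) -> list[ChimericRecord]:
    """Parse a STAR-style chimeric junction file into chimeric records.

    Comment lines (``#``) and the ``Nreads`` summary footer are skipped.
    Per-segment intervals and read offsets are derived from columns 11-14.
    """
    records: list[ChimericRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("Nreads"):
                continue
            fields = line.split("\t")
            if len(fields) < 14:
                raise ValueError(
                    f"{path}:{lineno}: expected >=14 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom_a, pos_a, strand_a = fields[0], int(fields[1]), fields[2]
            chrom_b, pos_b, strand_b = fields[3], int(fields[4]), fields[5]
            read_id = fields[9]
            seg1, off1 = _segment_from_cigar(
                chrom_a, int(fields[10]) - 1, strand_a, fields[11]
            )
            seg2, off2 = _segment_from_cigar(
                chrom_b, int(fields[12]) - 1, strand_b, fields[13]
            )
            # order segments so seg_a is the read prefix
            if off1 <= off2:
                (sa, oa), (sb, ob) = (seg1, off1), (seg2, off2)
                ca, sta, cb, stb = chrom_a, strand_a, chrom_b, strand_b
            else:
                (sa, oa), (sb, ob) = (seg2, off2), (seg1, off1)
                ca, sta, cb, stb = chrom_b, strand_b, chrom_a, strand_a
            records.append(
                ChimericRecord(
                    read_id=read_id,
                    chrom_a=ca,
                    chrom_b=cb,
                    strand_a=sta,
                    strand_b=stb,
                    seg_a=sa,
                    seg_b=sb,
                    read_offset_a=oa,
                    read_offset_b=ob,
                    junction_donor=pos_a - 1,
                    junction_acceptor=pos_b - 1,
                )
            )
    return records


def _candidate_boundaries(rec: ChimericRecord) -> tuple[int, int] | None:
    """Circle boundaries implied by a same-chrom/strand record, or None if
    the segment order is colinear (not a back-splice)."""
    if rec.strand_a == "+":
        # back-splice: read prefix downstream in genome
        if rec.seg_b.start < rec.seg_a.end:
            return rec.seg_b.start, rec.seg_a.end
    else:
        # '-' strand: transcription runs right-to-left; read prefix upstream
        # in genomic coordinates
        if rec.seg_a.start < rec.seg_b.end:
            return rec.seg_a.start, rec.seg_b.end
    return None


def call_backsplices(
    records: list[ChimericRecord],
    index: SpliceSiteIndex,
    min_cjc: int = 2,
    max_span: int = 100_000,
) -> list[BackspliceJunction]:
    """Aggregate chimeric records into back-splice junction calls.

    A record is a candidate iff both segments share chromosome and strand,
    lie within the span of a single common gene on that strand (or within
    ``max_span`` of each other when unannotated), and occur in reverse
    order relative to transcription. Identical (chrom, acceptor, donor,
    strand) candidates are merged with read-id deduplication; a read
    supporting more than one distinct junction is discarded as ambiguous.
    Junctions with CJC < ``min_cjc`` are dropped.
    """
    if min_cjc < 1:
        raise ValueError("min_cjc must be >= 1")
    rejects: Counter[str] = Counter()
    read_candidates: dict[str, set[tuple[str, int, int, str]]] = defaultdict(set)
    for rec in records:
        if rec.chrom_a != rec.chrom_b:
            rejects["different_chromosomes"] += 1
            continue
        if rec.strand_a != rec.strand_b:
            rejects["different_strands"] += 1
            continue
        bounds = _candidate_boundaries(rec)
        if bounds is None:
            rejects["colinear_order"] += 1
            continue
        acceptor, donor = bounds
        chrom, strand = rec.chrom_a, rec.strand_a
        genes_a = {g.gene_id for g in index.genes_overlapping(
            chrom, rec.seg_a.start, rec.seg_a.end, strand)}
        genes_b = {g.gene_id for g in index.genes_overlapping(
            chrom, rec.seg_b.start, rec.seg_b.end, strand)}
        if genes_a or genes_b:
            if not genes_a & genes_b:
                rejects["no_common_gene"] += 1
                continue
        elif donor - acceptor > max_span:
            rejects["span_exceeds_max"] += 1
            continue
        read_candidates[rec.read_id].add((chrom, acceptor, donor, strand))

    junctions: dict[tuple[str, int, int, str], BackspliceJunction] = {}
    for read_id, cands in read_candidates.items():
        if len(cands) > 1:
            rejects["ambiguous_read"] += 1
            continue
        (chrom, acceptor, donor, strand) = next(iter(cands))
        key = (chrom, acceptor, donor, strand)
        if key not in junctions:
            junctions[key] = BackspliceJunction(chrom, acceptor, donor, strand)
        junctions[key].supporting_reads.add(read_id)

    if rejects:
        logger.info(
            "call_backsplices rejections: %s",
            ", ".join(f"{k}={v}" for k, v in sorted(rejects.items())),
        )
    out = [j for j in junctions.values() if j.cjc >= min_cjc]
    out.sort(key=lambda j: j.key)
    return out


def snap_to_annotation(
    junction: BackspliceJunction, index: SpliceSiteIndex, tol: int = 2
) -> BackspliceJunction:
    """Snap both circle boundaries to annotated exon boundaries within
    ``tol`` bp, requiring a single common gene on the junction's strand;
    otherwise the junction is returned unchanged.

    The 5' genomic boundary must match an annotated exon *start* and the
    3' boundary an exon *end* (on '-', these are the transcriptional donor
    and acceptor respectively).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    best: tuple[int, int, int, str] | None = None  # (total shift, start, end, gene)
    for ds in range(-tol, tol + 1):
        s = junction.acceptor + ds
        genes_s = index.genes_with_exon_start(junction.chrom, junction.strand, s)
        if not genes_s:
            continue
        for de in range(-tol, tol + 1):
            e = junction.donor + de
            genes_e = index.genes_with_exon_end(junction.chrom, junction.strand, e)
            common = genes_s & genes_e
            if not common:
                continue
            cost = abs(ds) + abs(de)
            if best is None or cost < best[0]:
                best = (cost, s, e, min(common))
    if best is None:
        return junction
    _, s, e, gene = best
    return replace(junction, acceptor=s, donor=e, gene_id=gene)


def classify_circ_type(
    junction: BackspliceJunction, index: SpliceSiteIndex
) -> str:
    """Classify a (snapped) junction as exonic, intronic, or intergenic.

    exonic: both boundaries coincide with exon boundaries of one
    transcript. intergenic: no gene on the junction's strand overlaps it.
    Every other within-gene case — including one boundary off-annotation —
    is reported as intronic.
    """
    genes = index.genes_overlapping(
        junction.chrom, junction.acceptor, junction.donor, junction.strand
    )
    if not genes:
        return "intergenic"
    for gene in genes:
        for tx in gene.transcripts:
            starts = {e.start for e in tx.exons}
            ends = {e.end for e in tx.exons}
            if junction.acceptor in starts and junction.donor in ends:
                return "exonic"
    for gene in genes:
        for tx in gene.transcripts:
            for intron in tx.introns:
                if intron.start <= junction.acceptor and junction.donor <= intron.end:
                    return "intronic"
    return "intronic"


def has_gtag_motif(junction: BackspliceJunction, genome) -> bool:
    """True if the back-splice joins a canonical GT donor to an AG acceptor.

    For a circle [s, e) on '+' the donor dinucleotide is genome[e:e+2]
    ('GT') and the acceptor dinucleotide genome[s-2:s] ('AG'); mirrored on
    '-'. Used by the optional strict-motif filter.
    """
    c, s, e = junction.chrom, junction.acceptor, junction.donor
    try:
        if junction.strand == "+":
            donor = fetch_sequence(genome, GenomicInterval(c, e, e + 2, "+"))
            acceptor = fetch_sequence(genome, GenomicInterval(c, s - 2, s, "+"))
        else:
            donor = fetch_sequence(genome, GenomicInterval(c, s - 2, s, "-"))
            acceptor = fetch_sequence(genome, GenomicInterval(c, e, e + 2, "-"))
    except (KeyError, ValueError):
        return False
    return donor == "GT" and acceptor == "AG"
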