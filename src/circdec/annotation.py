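"""Gene-model parsing and splice-site indexing.

Transcript annotation (GTF or refFlat) is loaded into a uniform internal
representation — 0-based, half-open genomic intervals — and indexed two
ways: exon boundaries by exact coordinate (for snapping back-splice calls
to annotated splice sites) and gene spans by interval (for the
"both segments within one gene" test during circRNA detection).

Coordinate conventions are converted exactly once, at the parse boundary:
GTF is 1-based closed, refFlat is already 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import Iterator

from intervaltree import IntervalTree
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "SpliceSiteIndex",
    "AnnotationError",
    "parse_gtf",
    "parse_refflat",
    "build_splice_index",
    "fetch_sequence",
    "write_gtf",
    "write_refflat",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One transcript: ordered, non-overlapping exons on a single strand."""

    transcript_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]


@dataclass
class GeneModel:
    """All transcripts of one gene; span covers every transcript."""

    gene_id: str
    transcripts: list[TranscriptModel]
    span: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {self.gene_id} mixes chromosomes/strands: {chroms} {strands}"
            )
        self.span = GenomicInterval(
            chroms.pop(),
            min(t.exons[0].start for t in self.transcripts),
            max(t.exons[-1].end for t in self.transcripts),
            strands.pop(),
        )


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _open_text(path) -> Iterator[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from fh


def parse_gtf(path) -> list[GeneModel]:
    """Parse exon features of a GTF file into gene models.

    Only ``exon`` features are consumed; each must carry ``gene_id`` and
    ``transcript_id`` attributes. GTF's 1-based closed coordinates are
    converted to the internal 0-based half-open convention. Exons lacking
    a transcript_id are skipped (counted in the log); structurally
    malformed lines raise :class:`AnnotationError` with the line number.
    """
    exons_by_tx: dict[tuple[str, str], list[GenomicInterval]] = {}
    tx_order: list[tuple[str, str]] = []
    skipped = 0
    for lineno, line in enumerate(_open_text(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        attr = dict(_GTF_ATTR_RE.findall(attrs))
        gene_id = attr.get("gene_id")
        tx_id = attr.get("transcript_id")
        if not gene_id or not tx_id:
            skipped += 1
            continue
        key = (gene_id, tx_id)
        if key not in exons_by_tx:
            exons_by_tx[key] = []
            tx_order.append(key)
        exons_by_tx[key].append(iv)
    if skipped:
        logger.warning("parse_gtf: skipped %d exon records lacking gene_id/transcript_id", skipped)

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for gene_id, tx_id in tx_order:
        if gene_id not in genes:
            genes[gene_id] = []
            gene_order.append(gene_id)
        genes[gene_id].append(TranscriptModel(tx_id, exons_by_tx[(gene_id, tx_id)]))
    return [GeneModel(g, genes[g]) for g in gene_order]


def parse_refflat(path) -> list[GeneModel]:
    """Parse a refFlat annotation (geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds).

    refFlat coordinates are already 0-based half-open and pass through
    unchanged.
    """
    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for lineno, line in enumerate(_open_text(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise AnnotationError(
                f"{path}:{lineno}: refFlat rows need 11 columns, got {len(fields)}"
            )
        gene_id, tx_id, chrom, strand = fields[0], fields[1], fields[2], fields[3]
        exon_count = int(fields[8])
        starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
        ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
        if len(starts) != exon_count or len(ends) != exon_count:
            raise AnnotationError(
                f"{path}:{lineno}: exonCount={exon_count} but "
                f"{len(starts)} starts / {len(ends)} ends"
            )
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)]
        if gene_id not in genes:
            genes[gene_id] = []
            gene_order.append(gene_id)
        genes[gene_id].append(TranscriptModel(tx_id, exons))
    return [GeneModel(g, genes[g]) for g in gene_order]


def write_gtf(genes: list[GeneModel], path) -> None:
    """Emit exon features in GTF (1-based closed) — inverse of parse_gtf."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for ex in tx.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{ex.chrom}\tcircdec\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\t{attrs}\n"
                    )


def write_refflat(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                starts = ",".join(str(e.start) for e in tx.exons) + ","
                ends = ",".join(str(e.end) for e in tx.exons) + ","
                tx_start = tx.exons[0].start
                tx_end = tx.exons[-1].end
                fh.write(
                    "\t".join(
                        [
                            gene.gene_id,
                            tx.transcript_id,
                            tx.chrom,
                            tx.strand,
                            str(tx_start),
                            str(tx_end),
                            str(tx_start),
                            str(tx_start),
                            str(len(tx.exons)),
                            starts,
                            ends,
                        ]
                    )
                    + "\n"
                )


class SpliceSiteIndex:
    """Exact-coordinate lookup of annotated exon boundaries plus an interval
    index of gene spans.

    Exon *starts* and *ends* are indexed under genomic coordinates keyed by
    (chrom, strand). In splice-site vocabulary a genomic exon start is an
    acceptor on '+' and a donor on '-'; callers that care about the
    transcriptional role use :meth:`acceptor_sites` / :meth:`donor_sites`.
    """

    def __init__(self) -> None:
        # (chrom, strand, pos) -> set of gene_ids with an exon boundary there
        self.exon_starts: dict[tuple[str, str, int], set[str]] = {}
        self.exon_ends: dict[tuple[str, str, int], set[str]] = {}
        # (chrom, strand, pos) -> list of exon intervals
        self._start_exons: dict[tuple[str, str, int], list[GenomicInterval]] = {}
        self._end_exons: dict[tuple[str, str, int], list[GenomicInterval]] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self.genes: dict[str, GeneModel] = {}

    def add_gene(self, gene: GeneModel) -> None:
        self.genes[gene.gene_id] = gene
        span = gene.span
        self._gene_trees.setdefault(span.chrom, IntervalTree()).addi(
            span.start, span.end, gene
        )
        for tx in gene.transcripts:
            for ex in tx.exons:
                ks = (ex.chrom, ex.strand, ex.start)
                ke = (ex.chrom, ex.strand, ex.end)
                self.exon_starts.setdefault(ks, set()).add(gene.gene_id)
                self.exon_ends.setdefault(ke, set()).add(gene.gene_id)
                self._start_exons.setdefault(ks, []).append(ex)
                self._end_exons.setdefault(ke, []).append(ex)

    def genes_at(self, chrom: str, pos: int, strand: str | None = None) -> list[GeneModel]:
        """Genes whose span contains ``pos``; optionally strand-filtered."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        if strand is not None:
            hits = [g for g in hits if g.span.strand == strand]
        return hits

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneModel]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.span.strand == strand]
        return hits

    def acceptor_sites(self, chrom: str, strand: str, pos: int) -> set[str]:
        """Gene ids with an annotated splice acceptor at ``pos`` (transcription
        orientation: exon start on '+', exon end on '-')."""
        if strand == "+":
            return self.exon_starts.get((chrom, strand, pos), set())
        return self.exon_ends.get((chrom, strand, pos), set())

    def donor_sites(self, chrom: str, strand: str, pos: int) -> set[str]:
        if strand == "+":
            return self.exon_ends.get((chrom, strand, pos), set())
        return self.exon_starts.get((chrom, strand, pos), set())

    def genes_with_exon_start(self, chrom: str, strand: str, pos: int) -> set[str]:
        return self.exon_starts.get((chrom, strand, pos), set())

    def genes_with_exon_end(self, chrom: str, strand: str, pos: int) -> set[str]:
        return self.exon_ends.get((chrom, strand, pos), set())


def build_splice_index(genes: list[GeneModel]) -> SpliceSiteIndex:
    """Index exon boundaries and gene spans of ``genes`` for point queries."""
    index = SpliceSiteIndex()
    for gene in genes:
        index.add_gene(gene)
    return index


def fetch_sequence(genome: Fasta | str, interval: GenomicInterval) -> str:
    """Uppercase genomic sequence of ``interval``; reverse-complemented on '-'.

    ``genome`` may be a pyfaidx Fasta handle or a FASTA path.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not present in FASTA")
    contig_len = len(genome[interval.chrom])
    if interval.end > contig_len:
        raise ValueError(
            f"interval end {interval.end} beyond contig "
            f"{interval.chrom} length {contig_len}"
        )
    seq = genome[interval.chrom][interval.start : interval.end].seq.upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
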