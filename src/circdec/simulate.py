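"""Synthetic rRNA-depleted RNA-seq with planted circRNA ground truth.

The simulator builds a toy genome and annotation (multi-exon genes with
GT..AG motifs planted at every splice site), plants exonic circles with
known per-condition PBI, and emits every downstream substrate the
pipeline consumes: FASTQ reads, STAR-style chimeric junction files, and
gapped SAM alignments — plus a per-read truth table, so detection,
counting and testing are all checkable against planted values without an
aligner.

Read composition follows the rRNA-depleted library model: by default 5%
of reads originate from circular junctions, 91.5% from linear mRNA, 2%
from introns, 1% from intergenic regions, and 0.5% are sequencing-error
reads (unmappable random sequence).

Junction reads are planted so that the PBI estimator is the exact
binomial MLE of the planted truth: at a circle with true circular
fraction p, each junction-informative read is circular with probability
q = p / (2 - p) — a linear molecule presents two countable flanking
junctions where the circle presents one — and linear otherwise, split
evenly between the two flanking junctions. Background linear-mRNA reads
are sampled from transcript bodies rejecting windows that cross a
planted circle's flanking junctions, so flanking counts come only from
the planted allocation and recovery oracles are exact.

An aligner is emulated, not run: a circular read whose shorter chimeric
segment is below ``chim_min_segment`` is emitted as unmapped instead of
chimeric (shorter reads therefore lose proportionally more circular
evidence, which is what makes sensitivity grow with read length).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    build_splice_index,
    reverse_complement,
    write_gtf,
    write_refflat,
)
from .backsplice import ChimericRecord
from .linear import LinearJunctionEvent

__all__ = [
    "SimulationConfig",
    "CircleTruth",
    "PlannedRead",
    "SamplePlan",
    "Simulation",
    "default_pbi_truth",
    "sensitivity_sweep",
]

DEFAULT_COMPOSITION = {
    "circular": 0.05,
    "linear": 0.915,
    "intron": 0.02,
    "intergenic": 0.01,
    "error": 0.005,
}


@dataclass
class SimulationConfig:
    """Shape of the toy reference and the sequencing experiment."""

    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    read_length: int = 100
    n_reads: int = 100_000
    n_genes: int = 40
    exons_per_gene: int = 5
    exon_length: int = 300
    intron_length: int = 400
    intergenic_length: int = 1500
    genes_per_chrom: int = 20
    n_circles: int = 20
    n_replicates: int = 1
    chim_min_segment: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.composition) != set(DEFAULT_COMPOSITION):
            raise ValueError(
                f"composition must have keys {sorted(DEFAULT_COMPOSITION)}"
            )
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2 (reads must straddle junctions)")
        if self.read_length > self.exon_length:
            raise ValueError("exon_length must be >= read_length")
        if self.read_length > self.intron_length:
            raise ValueError("intron_length must be >= read_length")
        if self.exons_per_gene < 3:
            raise ValueError("need >= 3 exons per gene (circles require flanking exons)")
        if self.n_circles > self.n_genes:
            raise ValueError("at most one circle per gene")


@dataclass(frozen=True)
class CircleTruth:
    """One planted circle with its per-condition true PBI."""

    circle_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic 5' boundary (first circle exon start)
    end: int  # genomic 3' boundary (last circle exon end, exclusive)
    up_donor: int  # end of upstream (genomic-left) flanking exon
    down_acceptor: int  # start of downstream (genomic-right) flanking exon
    pbi: dict[str, float]  # condition -> true circular fraction

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def delta_pbi(self) -> float:
        conds = sorted(self.pbi)
        return self.pbi[conds[0]] - self.pbi[conds[1]]

    @property
    def is_true_dec(self) -> bool:
        return abs(self.delta_pbi) >= 0.05


@dataclass(frozen=True)
class PlannedRead:
    """One simulated read with enough placement detail to emit sequence,
    SAM and (for back-splice reads) chimeric records.

    ``kind``: bsj | up | down | body | intron | intergenic | error.
    ``blocks`` are genomic aligned blocks in reference order; for bsj
    reads the two chimeric segments in *read* order. ``offset`` is the
    read-prefix length on the first block (left anchor for linear
    junction reads, crossing offset for bsj reads).
    """

    read_id: str
    kind: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    offset: int
    circle_index: int = -1

    @property
    def origin(self) -> str:
        if self.kind == "bsj":
            return "circular"
        if self.kind in ("up", "down", "body"):
            return "linear"
        return self.kind


@dataclass
class SamplePlan:
    """All planned reads of one sample (one condition, one replicate)."""

    sample: str
    condition: str
    replicate: int
    read_length: int
    reads: list[PlannedRead]

    def origin_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.origin] = out.get(r.origin, 0) + 1
        return out

    def expected_counts(
        self, circle_index: int, chim_min_segment: int, min_anchor: int
    ) -> tuple[int, int, int]:
        """Planted (CJC, UJC, DJC) recoverable by a consumer of the emitted
        alignments at the given aligner/anchor stringency."""
        rl = self.read_length
        cjc = ujc = djc = 0
        for r in self.reads:
            if r.circle_index != circle_index:
                continue
            short = min(r.offset, rl - r.offset)
            if r.kind == "bsj" and short >= chim_min_segment:
                cjc += 1
            elif r.kind == "up" and short >= min_anchor:
                ujc += 1
            elif r.kind == "down" and short >= min_anchor:
                djc += 1
        return cjc, ujc, djc


def default_pbi_truth(
    n_circles: int,
    rng: np.random.Generator,
    conditions: tuple[str, str] = ("c1", "c2"),
    frac_dec: float = 0.5,
    delta: float = 0.3,
    pbi_range: tuple[float, float] = (0.15, 0.55),
) -> list[dict[str, float]]:
    """Per-circle true PBIs: a ``frac_dec`` fraction of circles differ by
    ``delta`` between conditions (alternating direction), the rest are
    equal in both. PBIs stay well inside (0, 1) so every circle leaves
    linear evidence at realistic depths."""
    lo, hi = pbi_range
    out = []
    for i in range(n_circles):
        p_low = float(rng.uniform(lo, hi))
        if i < round(frac_dec * n_circles):
            p_high = min(0.95, p_low + delta)
            pair = (p_high, p_low) if i % 2 == 0 else (p_low, p_high)
        else:
            pair = (p_low, p_low)
        out.append({conditions[0]: pair[0], conditions[1]: pair[1]})
    return out


class Simulation:
    """Deterministic toy reference + planted circles + per-sample read plans.

    All randomness derives from ``config.seed``; identical configs produce
    byte-identical reference and read files.
    """

    conditions = ("c1", "c2")

    def __init__(
        self,
        config: SimulationConfig,
        pbi_truth: list[dict[str, float]] | None = None,
    ) -> None:
        self.config = config
        rng = np.random.default_rng([config.seed, 0xC1DEC])
        self._build_reference(rng)
        if pbi_truth is None:
            pbi_truth = default_pbi_truth(config.n_circles, rng, self.conditions)
        if len(pbi_truth) != config.n_circles:
            raise ValueError("pbi_truth length must equal n_circles")
        self._plant_circles(rng, pbi_truth)
        self.index = build_splice_index(self.genes)

    # ------------------------------------------------------------------ #
    # reference construction
    # ------------------------------------------------------------------ #

    def _build_reference(self, rng: np.random.Generator) -> None:
        cfg = self.config
        gene_span = (
            cfg.exons_per_gene * cfg.exon_length
            + (cfg.exons_per_gene - 1) * cfg.intron_length
        )
        self.genes: list[GeneModel] = []
        self.chrom_seqs: dict[str, np.ndarray] = {}
        bases = np.frombuffer(b"ACGT", dtype="S1")
        n_chroms = -(-cfg.n_genes // cfg.genes_per_chrom)
        gi = 0
        for ci in range(n_chroms):
            chrom = f"chr{ci + 1}"
            genes_here = min(cfg.genes_per_chrom, cfg.n_genes - gi)
            chrom_len = cfg.intergenic_length + genes_here * (
                gene_span + cfg.intergenic_length
            )
            seq = bases[rng.integers(0, 4, size=chrom_len)].copy()
            pos = cfg.intergenic_length
            for _ in range(genes_here):
                strand = "+" if gi % 2 == 0 else "-"
                exons = []
                x = pos
                for _e in range(cfg.exons_per_gene):
                    exons.append(GenomicInterval(chrom, x, x + cfg.exon_length, strand))
                    x += cfg.exon_length + cfg.intron_length
                for a, b in zip(exons, exons[1:]):
                    i0, i1 = a.end, b.start
                    if strand == "+":
                        seq[i0], seq[i0 + 1] = b"G", b"T"
                        seq[i1 - 2], seq[i1 - 1] = b"A", b"G"
                    else:
                        seq[i0], seq[i0 + 1] = b"C", b"T"
                        seq[i1 - 2], seq[i1 - 1] = b"A", b"C"
                gene_id = f"gene{gi:04d}"
                self.genes.append(
                    GeneModel(gene_id, [TranscriptModel(f"{gene_id}.t1", exons)])
                )
                pos += gene_span + cfg.intergenic_length
                gi += 1
            self.chrom_seqs[chrom] = seq
        self.chrom_lengths = {c: len(s) for c, s in self.chrom_seqs.items()}

    def _plant_circles(
        self, rng: np.random.Generator, pbi_truth: list[dict[str, float]]
    ) -> None:
        cfg = self.config
        gene_ids = rng.permutation(len(self.genes))[: cfg.n_circles]
        self.circles: list[CircleTruth] = []
        for idx, (g, pbi) in enumerate(zip(sorted(gene_ids), pbi_truth)):
            gene = self.genes[g]
            exons = gene.transcripts[0].exons
            i = int(rng.integers(1, len(exons) - 1))
            j = int(rng.integers(i, len(exons) - 1))
            self.circles.append(
                CircleTruth(
                    circle_id=f"circ{idx:03d}",
                    gene_id=gene.gene_id,
                    chrom=gene.span.chrom,
                    strand=gene.span.strand,
                    start=exons[i].start,
                    end=exons[j].end,
                    up_donor=exons[i - 1].end,
                    down_acceptor=exons[j + 1].start,
                    pbi=dict(pbi),
                )
            )

    def genome_sequence(self, chrom: str, start: int, end: int) -> str:
        return self.chrom_seqs[chrom][start:end].tobytes().decode()

    def write_reference(self, outdir) -> dict[str, Path]:
        """Emit FASTA + GTF + refFlat (+ truth table); returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "refflat": outdir / "annotation.refflat",
            "truth": outdir / "circle_truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom in sorted(self.chrom_seqs):
                fh.write(f">{chrom}\n")
                s = self.chrom_seqs[chrom].tobytes().decode()
                for i in range(0, len(s), 60):
                    fh.write(s[i : i + 60] + "\n")
        write_gtf(self.genes, paths["gtf"])
        write_refflat(self.genes, paths["refflat"])
        with open(paths["truth"], "w") as fh:
            conds = self.conditions
            fh.write(
                "circle_id\tgene_id\tchrom\tstart\tend\tstrand\t"
                f"pbi_{conds[0]}\tpbi_{conds[1]}\ttrue_delta_pbi\tis_true_dec\n"
            )
            for c in self.circles:
                fh.write(
                    f"{c.circle_id}\t{c.gene_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                    f"{c.strand}\t{c.pbi[conds[0]]:.4f}\t{c.pbi[conds[1]]:.4f}\t"
                    f"{c.delta_pbi:.4f}\t{c.is_true_dec}\n"
                )
        return paths

    # ------------------------------------------------------------------ #
    # read planting
    # ------------------------------------------------------------------ #

    def sample_plan(
        self,
        condition: str,
        replicate: int = 1,
        n_reads: int | None = None,
        read_length: int | None = None,
        junction_only: bool = False,
    ) -> SamplePlan:
        """Plan all reads of one sample.

        With ``junction_only`` only junction-informative reads (circular +
        flanking linear) are materialised; background/intron/intergenic/
        error reads are skipped. Their absence changes no junction count,
        so this is the fast path for power studies.
        """
        cfg = self.config
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        n_reads = cfg.n_reads if n_reads is None else n_reads
        read_length = cfg.read_length if read_length is None else read_length
        if read_length > cfg.exon_length or read_length < 2:
            raise ValueError("read_length must be in [2, exon_length]")
        cond_idx = self.conditions.index(condition)
        rng = np.random.default_rng([cfg.seed, 7, cond_idx, replicate])
        sample = f"{condition}r{replicate}"
        reads: list[PlannedRead] = []
        serial = 0

        def rid(kind: str) -> str:
            nonlocal serial
            serial += 1
            return f"{sample}:{kind}:{serial}"

        f_circ = cfg.composition["circular"]
        k = max(1, len(self.circles))
        n_flank_total = 0
        for ci, circle in enumerate(self.circles):
            p = circle.pbi[condition]
            q = p / (2.0 - p)
            if q <= 0:
                continue
            n_junction = max(1, round(n_reads * f_circ / (k * q)))
            n_circ = int(rng.binomial(n_junction, q))
            n_lin = n_junction - n_circ
            n_up = int(rng.binomial(n_lin, 0.5))
            n_down = n_lin - n_up
            n_flank_total += n_lin
            offsets = rng.integers(1, read_length, size=n_circ + n_lin)
            oi = 0
            for _ in range(n_circ):
                o = int(offsets[oi]); oi += 1
                reads.append(self._plan_bsj(rid("bsj"), circle, o, read_length, ci))
            for _ in range(n_up):
                o = int(offsets[oi]); oi += 1
                reads.append(
                    self._plan_flank(rid("up"), circle, "up", o, read_length, ci)
                )
            for _ in range(n_down):
                o = int(offsets[oi]); oi += 1
                reads.append(
                    self._plan_flank(rid("down"), circle, "down", o, read_length, ci)
                )

        if not junction_only:
            n_circ_total = sum(1 for r in reads if r.kind == "bsj")
            rest = n_reads - n_circ_total
            probs = np.array(
                [
                    cfg.composition["linear"],
                    cfg.composition["intron"],
                    cfg.composition["intergenic"],
                    cfg.composition["error"],
                ]
            )
            n_lin_tot, n_int, n_ig, n_err = rng.multinomial(rest, probs / probs.sum())
            n_body = n_lin_tot - n_flank_total
            if n_body < 0:
                raise ValueError(
                    "planted flanking reads exceed the linear-mRNA budget; "
                    "raise n_reads or the linear composition fraction"
                )
            for _ in range(n_body):
                reads.append(self._plan_body(rid("body"), rng, read_length))
            for _ in range(n_int):
                reads.append(self._plan_intron(rid("intron"), rng, read_length))
            for _ in range(n_ig):
                reads.append(self._plan_intergenic(rid("ig"), rng, read_length))
            for _ in range(n_err):
                reads.append(
                    PlannedRead(rid("err"), "error", "*", "+", (), 0)
                )
        return SamplePlan(sample, condition, replicate, read_length, reads)

    def _plan_bsj(
        self, read_id: str, circle: CircleTruth, offset: int, rl: int, ci: int
    ) -> PlannedRead:
        s, e = circle.start, circle.end
        if circle.strand == "+":
            blocks = ((e - offset, e), (s, s + rl - offset))
        else:
            blocks = ((s, s + offset), (e - (rl - offset), e))
        return PlannedRead(read_id, "bsj", circle.chrom, circle.strand, blocks, offset, ci)

    def _plan_flank(
        self, read_id: str, circle: CircleTruth, kind: str, offset: int, rl: int, ci: int
    ) -> PlannedRead:
        if kind == "up":
            d, a = circle.up_donor, circle.start
        else:
            d, a = circle.end, circle.down_acceptor
        blocks = ((d - offset, d), (a, a + rl - offset))
        return PlannedRead(read_id, kind, circle.chrom, circle.strand, blocks, offset, ci)

    def _circle_for_gene(self, gene_id: str) -> CircleTruth | None:
        for c in self.circles:
            if c.gene_id == gene_id:
                return c
        return None

    def _plan_body(
        self, read_id: str, rng: np.random.Generator, rl: int
    ) -> PlannedRead:
        """Linear-mRNA background read: a transcript window not crossing the
        planted circle's flanking junctions of its gene."""
        while True:
            gene = self.genes[int(rng.integers(0, len(self.genes)))]
            tx = gene.transcripts[0]
            tx_len = sum(len(e) for e in tx.exons)
            t = int(rng.integers(0, tx_len - rl + 1))
            blocks = self._tx_window_blocks(tx, t, rl)
            circle = self._circle_for_gene(gene.gene_id)
            if circle is not None and self._crosses_flank(blocks, circle):
                continue
            offset = blocks[0][1] - blocks[0][0]
            return PlannedRead(read_id, "body", gene.span.chrom, gene.span.strand,
                               tuple(blocks), offset)

    @staticmethod
    def _tx_window_blocks(
        tx: TranscriptModel, t: int, rl: int
    ) -> list[tuple[int, int]]:
        blocks = []
        remaining, offset = rl, t
        for ex in tx.exons:
            elen = len(ex)
            if offset >= elen:
                offset -= elen
                continue
            take = min(remaining, elen - offset)
            blocks.append((ex.start + offset, ex.start + offset + take))
            remaining -= take
            offset = 0
            if remaining == 0:
                break
        return blocks

    @staticmethod
    def _crosses_flank(blocks: list[tuple[int, int]], circle: CircleTruth) -> bool:
        for left, right in zip(blocks, blocks[1:]):
            if left[1] == circle.up_donor and right[0] == circle.start:
                return True
            if left[1] == circle.end and right[0] == circle.down_acceptor:
                return True
        return False

    def _plan_intron(
        self, read_id: str, rng: np.random.Generator, rl: int
    ) -> PlannedRead:
        gene = self.genes[int(rng.integers(0, len(self.genes)))]
        introns = gene.transcripts[0].introns
        intron = introns[int(rng.integers(0, len(introns)))]
        start = intron.start + int(rng.integers(0, len(intron) - rl + 1))
        return PlannedRead(
            read_id, "intron", gene.span.chrom, gene.span.strand,
            ((start, start + rl),), rl,
        )

    def _plan_intergenic(
        self, read_id: str, rng: np.random.Generator, rl: int
    ) -> PlannedRead:
        chroms = sorted(self.chrom_lengths)
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, self.chrom_lengths[chrom] - rl + 1))
            if not self.index.genes_overlapping(chrom, start, start + rl):
                return PlannedRead(
                    read_id, "intergenic", chrom, "+", ((start, start + rl),), rl
                )

    # ------------------------------------------------------------------ #
    # emission
    # ------------------------------------------------------------------ #

    def read_sequence(self, read: PlannedRead, rng: np.random.Generator) -> str:
        if read.kind == "error":
            return "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=self.config.read_length)
            )
        seq = "".join(self.genome_sequence(read.chrom, s, e) for s, e in read.blocks)
        if read.kind == "bsj":
            if read.strand == "-":
                # blocks are in read order; each is transcribed from '-'
                a, b = read.blocks
                seq = reverse_complement(
                    self.genome_sequence(read.chrom, *a)
                ) + reverse_complement(self.genome_sequence(read.chrom, *b))
        elif read.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def write_fastq(self, plan: SamplePlan, path) -> None:
        rng = np.random.default_rng([self.config.seed, 11, hash(plan.sample) % 2**31])
        with open(path, "w") as fh:
            for read in plan.reads:
                seq = self.read_sequence(read, rng)
                fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_chimeric(self, plan: SamplePlan, path) -> None:
        """STAR-style 14-column chimeric junction file for the sample's
        back-splice reads passing the emulated aligner's segment minimum."""
        rl = plan.read_length
        cmin = self.config.chim_min_segment
        with open(path, "w") as fh:
            fh.write("# chimeric junction fixture (STAR Chimeric.out.junction dialect)\n")
            for read in plan.reads:
                if read.kind != "bsj":
                    continue
                o = read.offset
                if min(o, rl - o) < cmin:
                    continue
                circle = self.circles[read.circle_index]
                s, e, chrom, strand = circle.start, circle.end, circle.chrom, circle.strand
                if strand == "+":
                    seg1_start, seg1_cigar = e - o + 1, f"{o}M{rl - o}S"
                    seg2_start, seg2_cigar = s + 1, f"{o}S{rl - o}M"
                    don, acc = e + 1, s
                else:
                    seg1_start, seg1_cigar = s + 1, f"{rl - o}S{o}M"
                    seg2_start, seg2_cigar = e - (rl - o) + 1, f"{rl - o}M{o}S"
                    don, acc = s, e + 1
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            chrom, don, strand, chrom, acc, strand, 1, 0, 0,
                            read.read_id, seg1_start, seg1_cigar,
                            seg2_start, seg2_cigar,
                        )
                    )
                    + "\n"
                )

    def write_sam(self, plan: SamplePlan, path, with_sequence: bool = True) -> None:
        """Linear alignments (gapped where reads cross splice junctions) in
        plain-text SAM; error reads and aligner-dropped back-splice reads
        are emitted unmapped."""
        rl = plan.read_length
        cmin = self.config.chim_min_segment
        rng = np.random.default_rng([self.config.seed, 13, hash(plan.sample) % 2**31])
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom in sorted(self.chrom_lengths):
                fh.write(f"@SQ\tSN:{chrom}\tLN:{self.chrom_lengths[chrom]}\n")
            for read in plan.reads:
                seq = self.read_sequence(read, rng) if with_sequence else "*"
                qual = "I" * len(seq) if seq != "*" else "*"
                if read.kind == "error" or (
                    read.kind == "bsj" and min(read.offset, rl - read.offset) < cmin
                ):
                    fh.write(f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                    continue
                if read.kind == "bsj":
                    # represented in the chimeric file; keep the linear SAM
                    # clean by emitting the read unmapped here
                    fh.write(f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                    continue
                flag = 16 if read.strand == "-" and read.kind != "intergenic" else 0
                pos = read.blocks[0][0] + 1
                cigar = ""
                prev_end = None
                for bs, be in read.blocks:
                    if prev_end is not None:
                        cigar += f"{bs - prev_end}N"
                    cigar += f"{be - bs}M"
                    prev_end = be
                if flag == 16 and seq != "*":
                    seq = reverse_complement(seq)
                fh.write(
                    f"{read.read_id}\t{flag}\t{read.chrom}\t{pos}\t255\t{cigar}\t"
                    f"*\t0\t0\t{seq}\t{qual}\n"
                )

    def write_sample(self, plan: SamplePlan, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": outdir / f"{plan.sample}.fastq",
            "chimeric": outdir / f"{plan.sample}.chimeric.junction",
            "sam": outdir / f"{plan.sample}.sam",
        }
        self.write_fastq(plan, paths["fastq"])
        self.write_chimeric(plan, paths["chimeric"])
        self.write_sam(plan, paths["sam"])
        return paths

    # ------------------------------------------------------------------ #
    # in-memory fast path
    # ------------------------------------------------------------------ #

    def chimeric_records(self, plan: SamplePlan) -> list[ChimericRecord]:
        """Chimeric records the emulated aligner would report, built
        directly from the plan (no file round-trip)."""
        rl = plan.read_length
        cmin = self.config.chim_min_segment
        out = []
        for read in plan.reads:
            if read.kind != "bsj":
                continue
            o = read.offset
            if min(o, rl - o) < cmin:
                continue
            circle = self.circles[read.circle_index]
            s, e = circle.start, circle.end
            if circle.strand == "+":
                seg_a = GenomicInterval(circle.chrom, e - o, e, "+")
                seg_b = GenomicInterval(circle.chrom, s, s + rl - o, "+")
            else:
                seg_a = GenomicInterval(circle.chrom, s, s + o, "-")
                seg_b = GenomicInterval(circle.chrom, e - (rl - o), e, "-")
            out.append(
                ChimericRecord(
                    read_id=read.read_id,
                    chrom_a=circle.chrom,
                    chrom_b=circle.chrom,
                    strand_a=circle.strand,
                    strand_b=circle.strand,
                    seg_a=seg_a,
                    seg_b=seg_b,
                    read_offset_a=0,
                    read_offset_b=o,
                )
            )
        return out

    def linear_events(
        self, plan: SamplePlan, min_anchor: int = 6
    ) -> list[LinearJunctionEvent]:
        """Linear junction events a gapped-alignment consumer would extract
        from this sample at the given anchor stringency."""
        out = []
        for read in plan.reads:
            if read.kind not in ("up", "down", "body"):
                continue
            blocks = read.blocks
            for (ls, le), (rs, re) in zip(blocks, blocks[1:]):
                left, right = le - ls, re - rs
                if left >= min_anchor and right >= min_anchor:
                    out.append(
                        LinearJunctionEvent(
                            read.read_id, read.chrom, read.strand, le, rs, left, right
                        )
                    )
        return out


def sensitivity_sweep(
    depths: list[int],
    read_lengths: list[int],
    n_repeats: int = 10,
    config: SimulationConfig | None = None,
    min_cjc: int = 2,
    min_anchor: int = 6,
    seed: int = 0,
):
    """True-positive rate of DEC calling over a depth x read-length grid.

    For each cell and repeat, a fresh simulation (new reference and truth)
    is run through detection, counting and testing; TPR is the fraction of
    truly differential circles (|true dPBI| >= 0.05) called as DECs.
    Returns a tidy DataFrame (depth, read_length, repeat, tpr) — zero
    depth yields TPR 0 by convention.
    """
    import pandas as pd

    from .pipeline import analyse_samples

    base = config or SimulationConfig()
    rows = []
    for depth in depths:
        for rl in read_lengths:
            for rep in range(n_repeats):
                if depth == 0:
                    rows.append(
                        {"depth": 0, "read_length": rl, "repeat": rep, "tpr": 0.0}
                    )
                    continue
                cfg = dataclasses.replace(
                    base, n_reads=depth, read_length=rl,
                    seed=(seed * 1_000_003 + rep) % 2**31,
                )
                sim = Simulation(cfg)
                samples = {
                    cond: [
                        (
                            sim.chimeric_records(plan),
                            sim.linear_events(plan, min_anchor),
                        )
                        for plan in [
                            sim.sample_plan(cond, r + 1, junction_only=True)
                            for r in range(cfg.n_replicates)
                        ]
                    ]
                    for cond in sim.conditions
                }
                records = analyse_samples(
                    sim.index, samples[sim.conditions[0]], samples[sim.conditions[1]],
                    min_cjc=min_cjc,
                )
                called = {
                    r.junction.key for r in records if r.is_dec
                }
                truth = {c.key for c in sim.circles if c.is_true_dec}
                tpr = len(called & truth) / len(truth) if truth else float("nan")
                rows.append(
                    {"depth": depth, "read_length": rl, "repeat": rep, "tpr": tpr}
                )
    return pd.DataFrame(rows)
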