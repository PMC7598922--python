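# Methods

## Problem and model

Back-splicing joins a downstream splice donor to an upstream splice
acceptor, producing a covalently closed circular RNA (circRNA). In an
rRNA-depleted RNA-seq library, a read crossing the back-splice junction
aligns as two segments of the same gene in reverse order relative to
transcription; reads crossing the circle's two *flanking* linear
junctions (upstream flanking exon → first circle exon; last circle exon
→ downstream flanking exon) measure the linear isoform at the same
locus. circdec quantifies a circRNA's expression *relative to its linear
host* as the Percent-Backspliced-In:

    PBI = CJC / (CJC + LJC/2) = 2·CJC / (2·CJC + LJC)

where CJC is the circular junction count and LJC = UJC + DJC the
combined flanking linear junction count. The factor 2 reflects junction
opportunity: one linear molecule traversing the locus presents two
countable flanking junctions, while one circular molecule presents a
single back-splice junction. Under a binomial read-sampling model in
which each junction-informative read is circular with probability
q = p/(2 − p) (p the true circular molecule fraction), PBI is the
maximum-likelihood estimate of p. Because the circular and linear
junctions have identical mappable length, no length normalisation
beyond this factor is needed.

Differential expression between two conditions is tested per circRNA
with a two-sided Fisher's exact test on

    [[2·CJC₁, LJC₁],
     [2·CJC₂, LJC₂]]

— the CJC doubling keeps the table on the same junction-opportunity
scale as the PBI denominator. p-values are adjusted with
Benjamini–Hochberg across all tested circRNAs, and a circRNA is called
a DEC (differentially expressed circRNA) when |ΔPBI| ≥ 5% (inclusive)
and FDR < 5% (strict). Replicates are pooled by summing junction counts
per condition before estimation and testing; no replicate-level
dispersion model is fitted.

## Detection and counting rules

* A chimeric record is a back-splice candidate iff both segments share
  chromosome and strand, lie within the span of one common gene on that
  strand (or within `max_span`, default 100 kb, when fully
  unannotated), and occur in reverse transcriptional order. Candidates
  are aggregated by (chrom, acceptor, donor, strand) with read-id
  deduplication, so a paired-end fragment counts once; a read
  supporting two distinct junctions is discarded as ambiguous.
* Called boundaries are snapped to annotated exon boundaries within
  `tol` (default 2 bp), requiring both boundaries to match one common
  gene; the nearest-site assignment (minimum total shift) wins.
* Circles are typed `exonic` (both boundaries are exon boundaries of
  one transcript), `intronic` (anything else inside a gene, including
  junctions wholly within one intron), or `intergenic` (no same-strand
  gene overlap).
* Linear junction events come from `N` CIGAR operations of primary,
  non-duplicate alignments with MAPQ ≥ 20 (or the 255 unique-mapping
  convention), both anchors ≥ `min_anchor` (default 6 bp). For a circle
  [s, e): UJC counts distinct reads splicing into s from upstream
  (donor < s), DJC distinct reads splicing out of e downstream
  (acceptor > e). Orientation is genomic; on the '−' strand the labels
  swap transcriptional roles but LJC, PBI and the test are unaffected.
  Event strand is ignored by default (unstranded libraries); a
  stranded mode enforces matching.
* Detection itself is permissive (CJC ≥ 1); the `min_cjc` filter
  (default 2) is applied at reporting time against the *pooled* CJC of
  each condition, keeping a circle if either condition reaches the
  threshold. All kept circles are tested in both conditions,
  contributing zero counts where unobserved. Circles with CJC = LJC = 0
  in a condition have undefined PBI there, are reported as NA and are
  excluded from the BH family (so untestable records do not inflate the
  correction denominator).

## Fisher's exact test: numerics

The two-sided p is the probability-mass rule: the sum of hypergeometric
probabilities of all tables with the observed margins whose probability
does not exceed the observed table's. For table totals up to 10 000 the
implementation enumerates in exact integer arithmetic (binomial-weight
comparison, so ties are decided exactly rather than by float rounding),
with an LRU cache per margin triple; larger tables fall back to scipy's
floating-point implementation, which agrees to ~1e-15 on the sizes
where both run. The exact path makes the test reproducible to the last
bit and fast for junction-count-scale data.

## The simulator

The simulator is first-class code: it generates the study conditions
every pipeline stage is verified against.

* **Toy reference.** `n_genes` genes (default 40) of
  `exons_per_gene` = 5 exons × 300 bp separated by 400 bp introns, laid
  out on chromosomes of 20 genes with 1.5 kb intergenic gaps,
  alternating strands; GT..AG dinucleotides are planted at every splice
  site in transcription orientation. Annotation is emitted as both GTF
  and refFlat from the same in-memory model.
* **Read composition** (defaults): 5% circular-junction reads, 91.5%
  linear mRNA, 2% intron, 1% intergenic, 0.5% error reads (uniform
  random sequence standing in for unmappable errors). Counts are drawn
  multinomially, so realised fractions converge binomially to these
  targets.
* **Planting rule.** Each of `n_circles` circles (a contiguous run of
  internal exons of one gene, so both flanking exons exist) has a true
  per-condition PBI p. Its junction-read total is sized so circular
  reads take an equal share of the circular budget, and each junction
  read is independently circular with q = p/(2 − p), linear otherwise
  (split 50/50 between the two flanking junctions). This makes the PBI
  estimator the exact binomial MLE on the fixture. Default truth: half
  the circles differ by ΔPBI = 0.3 (alternating direction), half are
  null; base PBIs are uniform on [0.15, 0.55], keeping every circle's
  linear-read demand within the linear budget.
* **Aligner emulation.** No aligner runs. Back-splice reads are emitted
  directly as STAR-style `Chimeric.out.junction` lines and linear reads
  as gapped SAM records, with the junction-crossing offset uniform over
  the read. A back-splice read whose shorter segment is below
  `chim_min_segment` (default 10 bp, mirroring STAR's chimeric segment
  minimum) is emitted unmapped instead — this is what makes sensitivity
  grow with read length, since short reads lose proportionally more
  circular evidence. Linear-side anchor loss is applied downstream by
  the `min_anchor` extraction filter. Background linear reads are
  sampled from transcript bodies *rejecting* windows that cross a
  planted circle's flanking junctions, so flanking counts come only
  from the planted allocation and count-recovery oracles are exact.
* **Determinism.** All randomness derives from the config seed via
  per-sample seed sequences; identical configs give byte-identical
  FASTA/GTF/refFlat/FASTQ/SAM/chimeric output.

What the simulator does **not** model: base-call quality profiles and
per-base errors on mapped reads, GC and fragment-length bias, repeat-
and paralog-induced multimapping, rRNA carryover, alternative isoforms
per gene, and intron lariats. Passing tests therefore demonstrate the
correctness of the junction accounting and statistics under ideal
alignment, not robustness to alignment artefacts on real genomes.

A consequence of the aligner emulation worth noting: because the
chimeric segment minimum (10 bp) is stricter than the linear anchor
minimum (6 bp), surviving junction reads are slightly depleted of
circular evidence, so PBI estimates carry a small negative bias
(~2% absolute at p = 0.5, read length 100) relative to planted truth —
exactly as real chimeric alignment does relative to linear alignment.
Recovery tests account for this with the thinned circular fraction.

## Scaled study sizes

Power studies use a toy transcriptome (~40–50 genes, ~0.5 Mb) with
depths of 10k–500k reads and read lengths 50–150 bp, preserving the
reads-per-junction ratios of a full-genome experiment at roughly 1/1000
scale. The sensitivity sweep runs the in-memory fast path (only
junction-informative reads are materialised; background reads change no
junction count), 10 repeats per grid cell with a fresh reference and
truth each repeat.

## Degenerate inputs and tie-breaks

* `compute_pbi(0, 0)` → undefined (NA), never 0 or 1.
* All-zero Fisher tables → undefined p, excluded from BH.
* Snapping prefers the smallest total coordinate shift; among equally
  good gene assignments the lexicographically smallest gene id wins.
* BH uses a stable mergesort so equal p-values keep input order, making
  results permutation-invariant.
* Junction sets, result rows and manifests are canonically sorted, so
  outputs are byte-identical across reruns and insensitive to input
  record order.

## Known limitations

* The `{exonic, intronic, intergenic}` type vocabulary is a design
  choice; finer classes (e.g. exon–intron circles) are not separated.
* Uniqueness of mapping is approximated by MAPQ thresholding; aligners
  with non-standard MAPQ conventions need `min_mapq` adjusted.
* Chimeric input is the STAR junction-file dialect only; SA-tagged
  supplementary alignments in SAM/BAM are not parsed.
* Pooling replicates discards between-replicate dispersion; with many
  replicates a beta-binomial model would be better calibrated, but is
  out of scope here.
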