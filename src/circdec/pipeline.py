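"""End-to-end orchestration: detect -> snap -> count -> pool -> test -> report.

``analyse_samples`` is the in-memory core shared by the command-line
pipeline and the simulation sweep; ``run_pipeline`` wraps it with file
parsing, reporting, and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .annotation import SpliceSiteIndex, build_splice_index, parse_gtf, parse_refflat
from .backsplice import (
    BackspliceJunction,
    ChimericRecord,
    call_backsplices,
    classify_circ_type,
    parse_chimeric_file,
    snap_to_annotation,
)
from .diffexp import (
    DECRecord,
    build_dec_records,
    call_decs,
    pool_replicates,
    run_differential,
    write_results,
)
from .linear import (
    JunctionCountSet,
    LinearJunctionEvent,
    count_flanking_junctions,
    extract_linear_junctions,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyse_samples", "load_annotation"]

#: one sample's parsed inputs: chimeric records + linear junction events
SampleData = tuple[list[ChimericRecord], list[LinearJunctionEvent]]


@dataclass
class RunConfig:
    """Configuration of one two-condition run.

    Each condition lists >= 1 replicate, each replicate a pair of
    pre-aligned inputs: a STAR-style chimeric junction file and a SAM/BAM
    of linear alignments.
    """

    condition1: list[dict[str, str]]  # [{"chimeric": path, "alignments": path}, ...]
    condition2: list[dict[str, str]]
    annotation: str
    annotation_format: str = "auto"  # gtf | refflat | auto (by extension)
    genome: str | None = None
    outdir: str = "circdec_out"
    min_cjc: int = 2
    dpbi_cut: float = 0.05
    fdr_cut: float = 0.05
    min_anchor: int = 6
    min_mapq: int = 20
    tol: int = 2
    max_span: int = 100_000
    stranded: bool = False

    def validate(self) -> None:
        if not self.condition1 or not self.condition2:
            raise ValueError("each condition needs at least one replicate")
        if self.min_cjc < 1:
            raise ValueError("min_cjc must be >= 1")
        for name, val in (("dpbi_cut", self.dpbi_cut), ("fdr_cut", self.fdr_cut)):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_anchor < 1 or self.tol < 0 or self.max_span < 0:
            raise ValueError("min_anchor >= 1, tol >= 0, max_span >= 0 required")


def load_annotation(path: str, fmt: str = "auto"):
    if fmt == "auto":
        lowered = str(path).lower()
        fmt = "gtf" if lowered.endswith((".gtf", ".gtf.gz")) else "refflat"
    if fmt == "gtf":
        return parse_gtf(path)
    if fmt == "refflat":
        return parse_refflat(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _detect_sample(
    records: list[ChimericRecord],
    index: SpliceSiteIndex,
    tol: int,
    max_span: int,
) -> dict[tuple, BackspliceJunction]:
    """Per-sample junction calls, snapped to annotation, keyed by locus.

    Detection runs permissively (min CJC 1); the reporting filter is
    applied later on condition-pooled counts.
    """
    called = call_backsplices(records, index, min_cjc=1, max_span=max_span)
    snapped: dict[tuple, BackspliceJunction] = {}
    for j in called:
        sj = snap_to_annotation(j, index, tol=tol)
        if sj.key in snapped:
            snapped[sj.key].supporting_reads |= sj.supporting_reads
        else:
            snapped[sj.key] = sj
    return snapped


def analyse_samples(
    index: SpliceSiteIndex,
    condition1: list[SampleData],
    condition2: list[SampleData],
    min_cjc: int = 2,
    dpbi_cut: float = 0.05,
    fdr_cut: float = 0.05,
    tol: int = 2,
    max_span: int = 100_000,
    stranded: bool = False,
) -> list[DECRecord]:
    """Run detection, counting, pooling and differential testing on parsed
    per-replicate inputs; returns finalized records (DEC flags set).

    CircRNAs are kept when either condition's pooled CJC reaches
    ``min_cjc``; every kept circRNA is counted and tested in both
    conditions, contributing zeros where it was not observed.
    """
    conditions = (condition1, condition2)
    per_sample_junctions: list[list[dict[tuple, BackspliceJunction]]] = [
        [_detect_sample(chim, index, tol, max_span) for chim, _ in cond]
        for cond in conditions
    ]
    # union of snapped junction loci across all samples
    union: dict[tuple, BackspliceJunction] = {}
    for cond in per_sample_junctions:
        for sample in cond:
            for key, j in sample.items():
                if key not in union:
                    union[key] = BackspliceJunction(
                        j.chrom, j.acceptor, j.donor, j.strand, gene_id=j.gene_id
                    )
                elif union[key].gene_id == "NA" and j.gene_id != "NA":
                    union[key].gene_id = j.gene_id
    junctions = [union[k] for k in sorted(union)]
    for j in junctions:
        j.circ_type = classify_circ_type(j, index)

    # per-replicate counts at every union locus
    pooled: list[dict[tuple, JunctionCountSet]] = []
    for cond_idx, cond in enumerate(conditions):
        replicate_counts: list[dict[tuple, JunctionCountSet]] = []
        for rep_idx, (_chim, events) in enumerate(cond):
            sample_j = per_sample_junctions[cond_idx][rep_idx]
            with_support = [
                BackspliceJunction(
                    j.chrom, j.acceptor, j.donor, j.strand,
                    supporting_reads=set(
                        sample_j[j.key].supporting_reads if j.key in sample_j else ()
                    ),
                )
                for j in junctions
            ]
            replicate_counts.append(
                count_flanking_junctions(events, with_support, stranded=stranded)
            )
        pooled.append(
            {
                key: pool_replicates([rc[key] for rc in replicate_counts])
                for key in union
            }
        )

    # reporting filter: observed at min_cjc in at least one condition
    kept = [
        j
        for j in junctions
        if max(pooled[0][j.key].cjc, pooled[1][j.key].cjc) >= min_cjc
    ]
    records = build_dec_records(kept, pooled[0], pooled[1])
    run_differential(records)
    call_decs(records, dpbi_cut=dpbi_cut, fdr_cut=fdr_cut)
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from files; writes the results table, a
    run summary, and a manifest into ``config.outdir``.

    Returns the manifest dictionary. Outputs are deterministic for
    identical inputs and configuration.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "annotation"
    try:
        genes = load_annotation(config.annotation, config.annotation_format)
        index = build_splice_index(genes)
        stage = "input parsing"
        parsed: list[list[SampleData]] = []
        for cond in (config.condition1, config.condition2):
            cond_data = []
            for rep in cond:
                chim = parse_chimeric_file(rep["chimeric"])
                events = extract_linear_junctions(
                    rep["alignments"],
                    min_anchor=config.min_anchor,
                    min_mapq=config.min_mapq,
                )
                cond_data.append((chim, events))
            parsed.append(cond_data)
        stage = "analysis"
        records = analyse_samples(
            index,
            parsed[0],
            parsed[1],
            min_cjc=config.min_cjc,
            dpbi_cut=config.dpbi_cut,
            fdr_cut=config.fdr_cut,
            tol=config.tol,
            max_span=config.max_span,
            stranded=config.stranded,
        )
        stage = "reporting"
        results_path = outdir / "circrnas.tsv"
        write_results(records, results_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    n_tested = sum(1 for r in records if r.fdr is not None)
    n_dec = sum(1 for r in records if r.is_dec)
    summary = {
        "n_circrnas": len(records),
        "n_tested": n_tested,
        "n_dec": n_dec,
    }
    cfg_dict = asdict(config)
    manifest = {
        "tool": "circdec",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stage_counts": summary,
        "results": str(results_path),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info(
        "pipeline complete: %d circRNAs, %d tested, %d DECs",
        len(records), n_tested, n_dec,
    )
    return manifest
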