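"""PBI estimation and differential circRNA testing.

Expression of a circRNA relative to its host's linear isoform is the
Percent-Backspliced-In,

    PBI = CJC / (CJC + LJC/2) = 2*CJC / (2*CJC + LJC),

the binomial maximum-likelihood estimate of the circular fraction given
that a linear molecule presents two countable flanking junctions per
circle boundary pair while the circle presents one. Each circRNA is
tested between two conditions with a two-sided Fisher's exact test on
the 2x2 table

    [[2*CJC_1, LJC_1],
     [2*CJC_2, LJC_2]]

(the CJC doubling mirrors the PBI normalisation), p-values are adjusted
with Benjamini-Hochberg across all tested circRNAs, and a circRNA is a
DEC (differentially expressed circRNA) when |dPBI| >= 5% and FDR < 5%.

The exact test sums hypergeometric table probabilities not exceeding the
observed table's (the probability-mass rule), in exact integer
arithmetic with a per-margin cache; tables too large for that are
delegated to scipy's floating-point implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .backsplice import BackspliceJunction
from .linear import JunctionCountSet

__all__ = [
    "PBIEstimate",
    "DECRecord",
    "compute_pbi",
    "pool_replicates",
    "fisher_test",
    "fisher_exact_pvalue",
    "bh_fdr",
    "build_dec_records",
    "run_differential",
    "call_decs",
    "write_results",
    "read_results",
]

#: table totals above this use scipy's float implementation instead of
#: exact integer enumeration (exact-path cost grows with the support size)
_EXACT_TOTAL_LIMIT = 10_000


@dataclass(frozen=True)
class PBIEstimate:
    """PBI with the pooled counts it was computed from; pbi is None when
    no informative read was observed (CJC = LJC = 0)."""

    pbi: float | None
    cjc: int
    ljc: int


def compute_pbi(cjc: int, ljc: int) -> PBIEstimate:
    """MLE of the circular fraction: 2*CJC / (2*CJC + LJC).

    Undefined (None) when both counts are zero; such circRNAs are
    excluded from testing and reported as NA.
    """
    if cjc < 0 or ljc < 0:
        raise ValueError("junction counts must be >= 0")
    if cjc == 0 and ljc == 0:
        return PBIEstimate(None, 0, 0)
    return PBIEstimate(2 * cjc / (2 * cjc + ljc), cjc, ljc)


def pool_replicates(counts: Sequence[JunctionCountSet]) -> JunctionCountSet:
    """Element-wise sum of junction counts across replicates of one
    condition (LJC is recomputed as UJC + DJC)."""
    if not counts:
        raise ValueError("need at least one replicate")
    return JunctionCountSet(
        cjc=sum(c.cjc for c in counts),
        ujc=sum(c.ujc for c in counts),
        djc=sum(c.djc for c in counts),
    )


@lru_cache(maxsize=200_000)
def _hypergeom_weights(r1: int, r2: int, c1: int) -> tuple[int, tuple[int, ...]]:
    """Integer table weights C(r1,k)*C(r2,c1-k) over the support of k,
    returned as (k_min, weights); their sum is C(r1+r2, c1)."""
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    return k_min, tuple(
        comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)
    )


def fisher_exact_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the raw table [[a, b], [c, d]] by
    exact integer enumeration: sum the hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (integer weights, so ties are exact)."""
    r1, r2, c1 = a + b, c + d, a + c
    k_min, weights = _hypergeom_weights(r1, r2, c1)
    observed = weights[a - k_min]
    num = sum(w for w in weights if w <= observed)
    return min(1.0, num / comb(r1 + r2, c1))


def fisher_test(cjc1: int, ljc1: int, cjc2: int, ljc2: int) -> float | None:
    """Two-sided Fisher's exact p for the table [[2*cjc1, ljc1],
    [2*cjc2, ljc2]]; None (untestable) when all four cells are zero."""
    if min(cjc1, ljc1, cjc2, ljc2) < 0:
        raise ValueError("junction counts must be >= 0")
    a, b, c, d = 2 * cjc1, ljc1, 2 * cjc2, ljc2
    if a + b + c + d == 0:
        return None
    if a + b + c + d <= _EXACT_TOTAL_LIMIT:
        return fisher_exact_pvalue(a, b, c, d)
    from scipy.stats import fisher_exact

    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending sort, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class DECRecord:
    """Per-circRNA differential-expression result."""

    junction: BackspliceJunction
    counts_1: JunctionCountSet
    counts_2: JunctionCountSet
    pbi_1: PBIEstimate = field(init=False)
    pbi_2: PBIEstimate = field(init=False)
    delta_pbi: float | None = field(init=False)
    p_value: float | None = None
    fdr: float | None = None
    is_dec: bool = False

    def __post_init__(self) -> None:
        self.pbi_1 = compute_pbi(self.counts_1.cjc, self.counts_1.ljc)
        self.pbi_2 = compute_pbi(self.counts_2.cjc, self.counts_2.ljc)
        if self.pbi_1.pbi is None or self.pbi_2.pbi is None:
            self.delta_pbi = None
        else:
            self.delta_pbi = self.pbi_1.pbi - self.pbi_2.pbi


def build_dec_records(
    junctions: list[BackspliceJunction],
    counts_1: dict[tuple, JunctionCountSet],
    counts_2: dict[tuple, JunctionCountSet],
) -> list[DECRecord]:
    """Assemble one record per junction from per-condition pooled counts
    (missing keys contribute zero counts)."""
    zero = JunctionCountSet()
    return [
        DECRecord(j, counts_1.get(j.key, zero), counts_2.get(j.key, zero))
        for j in junctions
    ]


def run_differential(records: list[DECRecord]) -> list[DECRecord]:
    """Fill p-values and BH FDR in place.

    The BH family comprises only testable records — those with a defined
    p (not an all-zero table) and defined PBIs in both conditions — so
    untestable circRNAs do not inflate the correction denominator.
    """
    for rec in records:
        rec.p_value = fisher_test(
            rec.counts_1.cjc, rec.counts_1.ljc, rec.counts_2.cjc, rec.counts_2.ljc
        )
    tested = [
        r for r in records if r.p_value is not None and r.delta_pbi is not None
    ]
    if tested:
        fdrs = bh_fdr([r.p_value for r in tested])
        for rec, q in zip(tested, fdrs):
            rec.fdr = float(q)
    return records


def call_decs(
    records: list[DECRecord],
    dpbi_cut: float = 0.05,
    fdr_cut: float = 0.05,
) -> list[DECRecord]:
    """Flag DECs: |dPBI| >= dpbi_cut and FDR < fdr_cut. Records with
    undefined PBI, p, or FDR are never DECs."""
    for rec in records:
        rec.is_dec = (
            rec.delta_pbi is not None
            and rec.fdr is not None
            and abs(rec.delta_pbi) >= dpbi_cut
            and rec.fdr < fdr_cut
        )
    return records


_COLUMNS = [
    "chrom", "start", "end", "strand", "gene_id", "circ_type",
    "CJC_s1", "LJC_s1", "CJC_s2", "LJC_s2",
    "PBI_s1", "PBI_s2", "deltaPBI", "p_value", "FDR", "is_DEC",
]


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.6g}"


def write_results(records: list[DECRecord], path) -> None:
    """Write the tab-delimited per-circRNA report, sorted by FDR then
    |dPBI| descending; undefined values serialised as NA."""

    def sort_key(rec: DECRecord):
        fdr = rec.fdr if rec.fdr is not None else 2.0
        dpbi = abs(rec.delta_pbi) if rec.delta_pbi is not None else -1.0
        return (fdr, -dpbi, rec.junction.key)

    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for rec in sorted(records, key=sort_key):
            j = rec.junction
            fh.write(
                "\t".join(
                    [
                        j.chrom, str(j.acceptor), str(j.donor), j.strand,
                        j.gene_id, j.circ_type,
                        str(rec.counts_1.cjc), str(rec.counts_1.ljc),
                        str(rec.counts_2.cjc), str(rec.counts_2.ljc),
                        _fmt(rec.pbi_1.pbi), _fmt(rec.pbi_2.pbi),
                        _fmt(rec.delta_pbi), _fmt(rec.p_value), _fmt(rec.fdr),
                        str(rec.is_dec),
                    ]
                )
                + "\n"
            )


def read_results(path) -> pd.DataFrame:
    """Read a results table back into a DataFrame (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
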