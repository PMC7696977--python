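"""DEG thresholding, gene-set overlap statistics, correlation, enhancer
candidates and qPCR fold change.

Differential expression model fitting happens upstream (the negative
binomial machinery of DESeq2-style tools); this module consumes the
resulting tables and applies the downstream statistics: Benjamini-Hochberg
FDR control, the adjusted-p/effect-size DEG filter, chi-square and Fisher
gene-set overlap tests over an explicit universe, Spearman correlation,
LTR-neighborhood enhancer-candidate calling, and the comparative-CT
(2^-ddCT) qPCR quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from terk.intervals import GeneModel, TELocus
from terk.motifs import chi2_2x2


@dataclass
class DERecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float | None = None
    mean_expr: float = 0.0


def read_de_table(path: str) -> list[DERecord]:
    """Read a DE TSV with columns gene_id, log2fc, pvalue[, padj[, mean_expr]]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        padj = getattr(row, "padj", None)
        if padj is not None and (isinstance(padj, float) and math.isnan(padj)):
            padj = None
        records.append(
            DERecord(
                str(row.gene_id),
                float(row.log2fc),
                float(row.pvalue),
                None if padj is None else float(padj),
                float(getattr(row, "mean_expr", 0.0)),
            )
        )
    return records


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_filter(
    records: Sequence[DERecord], alpha: float = 0.05, min_abs_lfc: float = 1.0
) -> tuple[list[DERecord], list[DERecord]]:
    """Split records into (up, down) DEG lists.

    Kept iff padj < alpha and |log2fc| >= min_abs_lfc (inclusive effect-size
    boundary).  Missing padj values are computed by BH over the whole
    table's raw p-values.
    """
    if any(r.padj is None for r in records):
        padj = bh_adjust([r.pvalue for r in records])
        records = [
            DERecord(r.gene_id, r.log2fc, r.pvalue, float(q), r.mean_expr)
            for r, q in zip(records, padj)
        ]
    up = [r for r in records if r.padj < alpha and r.log2fc >= min_abs_lfc]
    down = [r for r in records if r.padj < alpha and r.log2fc <= -min_abs_lfc]
    return up, down


@dataclass
class OverlapTestResult:
    table: np.ndarray  # [[in A & B, in A only], [in B only, in neither]]
    method: str
    statistic: float
    p: float


def set_overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str], method: str = "chi2"
) -> OverlapTestResult:
    """Test association of two gene sets over an explicit universe.

    The 2x2 table partitions the universe by membership in A and B; the test
    is a 1-df chi-square without continuity correction or a two-sided Fisher
    exact test.  The universe must be supplied: the expected overlap depends
    entirely on it and there is no safe default.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a = set(set_a) & universe
    b = set(set_b) & universe
    both = len(a & b)
    table = np.array(
        [
            [both, len(a) - both],
            [len(b) - both, len(universe) - len(a) - len(b) + both],
        ]
    )
    if method == "fisher":
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        return OverlapTestResult(table, "fisher-two-sided", float(stat), float(p))
    if method == "chi2":
        if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
            return OverlapTestResult(table, "chi-square", 0.0, 1.0)
        chi2, p = chi2_2x2(table)
        return OverlapTestResult(table, "chi-square", chi2, p)
    raise ValueError("method must be 'chi2' or 'fisher'")


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with asymptotic-t p-value.

    Mid-ranks are used for ties.  A constant vector leaves the correlation
    undefined: (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EnhancerCandidate:
    gene_id: str
    te_locus_id: str
    distance_bp: int
    reciprocal_response: bool = True
    upregulated_with_treatment: bool = True
    tf_bound: bool = True


def enhancer_candidates(
    genes: Sequence[GeneModel],
    te_loci: Sequence[TELocus],
    bound_locus_ids: Iterable[str],
    de_treatment: Sequence[DERecord],
    de_states: Sequence[DERecord],
    neighborhood_bp: int = 10000,
    target_family: str | None = None,
    reciprocal_sign: str = "down",
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> list[EnhancerCandidate]:
    """Genes plausibly driven by a nearby TF-bound LTR enhancer.

    A gene qualifies when (i) it responds reciprocally across invasion
    states — significant in ``de_states`` with the sign given by
    ``reciprocal_sign``; (ii) it is upregulated with treatment per the DEG
    filter on ``de_treatment``; and (iii) a locus of ``target_family`` whose
    id is in ``bound_locus_ids`` lies within ``neighborhood_bp`` of the
    gene's TSS (edge-to-TSS distance, boundary inclusive).
    """
    bound = set(bound_locus_ids)
    up_t, _ = deg_filter(de_treatment, alpha, min_abs_lfc)
    up_s, down_s = deg_filter(de_states, alpha, min_abs_lfc)
    reciprocal = {r.gene_id for r in (down_s if reciprocal_sign == "down" else up_s)}
    upregulated = {r.gene_id for r in up_t}
    candidate_loci = [
        l
        for l in te_loci
        if l.locus_id in bound and (target_family is None or l.family == target_family)
    ]
    out = []
    for gene in genes:
        if gene.gene_id not in reciprocal or gene.gene_id not in upregulated:
            continue
        best: tuple[int, str] | None = None
        for locus in candidate_loci:
            d = locus.interval.distance_to_position(gene.tss.chrom, gene.tss_position)
            if d <= neighborhood_bp and (best is None or (d, locus.locus_id) < best):
                best = (int(d), locus.locus_id)
        if best is not None:
            out.append(EnhancerCandidate(gene.gene_id, best[1], best[0]))
    out.sort(key=lambda c: c.gene_id)
    return out


def write_candidates(candidates: Sequence[EnhancerCandidate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tte_locus_id\tdistance_bp\n")
        for c in candidates:
            fh.write(f"{c.gene_id}\t{c.te_locus_id}\t{c.distance_bp}\n")


@dataclass
class QPCRMeasurement:
    """Replicate CT values for a target and a reference gene in one sample."""

    sample: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.target_ct or not self.reference_ct:
            raise ValueError("need at least one CT replicate for target and reference")
        if any(ct <= 0 for ct in self.target_ct + self.reference_ct):
            raise ValueError("CT values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_ct) - np.mean(self.reference_ct))


def ddct_fold_change(case: QPCRMeasurement, control: QPCRMeasurement) -> float:
    """Comparative-CT fold change 2^-(dCT_case - dCT_control)."""
    return float(2.0 ** -(case.delta_ct - control.delta_ct))
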