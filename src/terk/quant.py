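"""TE expression quantification from read alignments.

Two complementary quantifiers:

* **family level** — a multi-mapping read is counted only when every one of
  its reported alignments falls within loci of one single repeat family
  ("exclusive-family" rule); each read then contributes exactly one count to
  that family.  Counts are scaled to CPM (counts per million total
  genome-mappable reads) and expressed as log2(CPM + 1).
* **locus level** — multi-mapped reads are redistributed across their
  candidate loci by an expectation-maximization algorithm whose fixed point
  is anchored by uniquely mapped reads.

The library size (total mappable reads) is always an explicit input: it is a
property of the whole alignment run, not of the TE-overlapping subset seen
here, and is never inferred.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from terk.intervals import GenomicInterval, LocusIndex, TELocus

logger = logging.getLogger(__name__)

NO_FAMILY = None


@dataclass(frozen=True)
class AlignmentRecord:
    """One reported alignment of a read."""

    read_id: str
    interval: GenomicInterval
    hit_count: int = 1
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.hit_count < 1:
            raise ValueError("hit_count must be >= 1")


@dataclass
class FamilyCounts:
    """Per-family read counts with CPM and log2(CPM+1) normalisations."""

    counts: dict[str, float]
    total_mappable_reads: int
    cpm: dict[str, float] = field(default_factory=dict)
    log2_cpm1: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_mappable_reads <= 0:
            raise ValueError("total_mappable_reads must be positive")
        scale = 1e6 / self.total_mappable_reads
        self.cpm = {f: c * scale for f, c in self.counts.items()}
        self.log2_cpm1 = {f: math.log2(v + 1.0) for f, v in self.cpm.items()}


@dataclass
class LocusCounts:
    """Unique counts and EM totals per locus."""

    unique: dict[str, int]
    em_total: dict[str, float]
    iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)
    n_dropped: int = 0


@dataclass
class FamilyExpressionSummary:
    """Mean and population sd of log2(CPM+1) per family across samples."""

    mean: dict[str, float]
    sd: dict[str, float]


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def read_sam(path: str) -> list[AlignmentRecord]:
    """Read alignments from SAM, one record per reported alignment.

    The NH tag supplies hit_count when present; otherwise records are grouped
    by read id and the group size is used.  Unmapped reads are skipped.
    """
    records: list[AlignmentRecord] = []
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 0
            records.append(
                AlignmentRecord(aln.query_name, iv, max(int(nh), 1), aln.mapping_quality)
            )
            counts[aln.query_name] = counts.get(aln.query_name, 0) + 1
    # reads without NH: use the observed multiplicity
    fixed = []
    for rec in records:
        n = max(rec.hit_count, counts[rec.read_id])
        fixed.append(
            rec if rec.hit_count == n else AlignmentRecord(rec.read_id, rec.interval, n, rec.mapq)
        )
    return fixed


def group_by_read(alignments: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    groups: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        groups.setdefault(rec.read_id, []).append(rec)
    return groups


# ---------------------------------------------------------------------------
# family-level quantification
# ---------------------------------------------------------------------------

def families_hit(
    record: AlignmentRecord, index: LocusIndex, read_overlap_frac: float = 0.5
) -> set[str]:
    """Families whose loci this alignment overlaps by >= frac of read length."""
    min_bp = read_overlap_frac * record.interval.length
    out = set()
    for locus in index.overlapping(record.interval):
        if record.interval.overlap_bp(locus.interval) >= min_bp:
            out.add(locus.family)
    return out


def assign_read_family(
    records_of_one_read: Sequence[AlignmentRecord],
    index: LocusIndex,
    read_overlap_frac: float = 0.5,
) -> str | None:
    """Family assignment under the exclusive-family rule.

    Returns the family iff every alignment of the read hits loci of one
    single family (and no other); returns ``None`` when any alignment falls
    outside all TE loci or when two families are hit.
    """
    read_ids = {r.read_id for r in records_of_one_read}
    if len(read_ids) != 1:
        raise ValueError(f"records of multiple reads passed: {sorted(read_ids)}")
    union: set[str] = set()
    for rec in records_of_one_read:
        fams = families_hit(rec, index, read_overlap_frac)
        if not fams:
            return NO_FAMILY
        union |= fams
        if len(union) > 1:
            return NO_FAMILY
    return next(iter(union)) if len(union) == 1 else NO_FAMILY


def family_counts(
    alignments: Iterable[AlignmentRecord],
    te_loci: Sequence[TELocus] | LocusIndex,
    total_mappable_reads: int,
    read_overlap_frac: float = 0.5,
) -> FamilyCounts:
    """Count one alignment per exclusively-assigned read, per family."""
    if total_mappable_reads <= 0:
        raise ValueError("total_mappable_reads must be positive")
    index = te_loci if isinstance(te_loci, LocusIndex) else LocusIndex(te_loci)
    counts: dict[str, float] = {locus.family: 0.0 for locus in index.loci}
    for records in group_by_read(alignments).values():
        fam = assign_read_family(records, index, read_overlap_frac)
        if fam is not NO_FAMILY:
            counts[fam] = counts.get(fam, 0.0) + 1.0
    return FamilyCounts(counts, total_mappable_reads)


def summarize_family_expression(samples: Sequence[FamilyCounts]) -> FamilyExpressionSummary:
    """Per-family mean and population sd of log2(CPM+1) across samples."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to summarize")
    families = sorted({f for s in samples for f in s.log2_cpm1})
    mean, sd = {}, {}
    for fam in families:
        vals = np.array([s.log2_cpm1.get(fam, 0.0) for s in samples])
        mean[fam] = float(vals.mean())
        sd[fam] = float(vals.std())  # population sd
    return FamilyExpressionSummary(mean, sd)


# ---------------------------------------------------------------------------
# locus-level EM quantification
# ---------------------------------------------------------------------------

def em_locus_quant(
    alignments: Iterable[AlignmentRecord],
    loci: Sequence[TELocus],
    tol: float = 1e-8,
    max_iter: int = 1000,
    read_overlap_frac: float = 0.5,
) -> LocusCounts:
    """Redistribute multi-mapped reads over loci by EM on unique evidence.

    Each read r has a candidate locus set L(r): the loci any of its
    alignments overlap by >= ``read_overlap_frac`` of the read length.
    Reads with empty L(r) are dropped (counted).  Reads with |L(r)| = 1 are
    unique evidence.  Ambiguous reads are fractionally assigned with
    responsibility theta_l / sum_{k in L(r)} theta_k; the M-step sets
    theta_l proportional to unique[l] plus the fractional assignments.
    theta starts uniform so loci without unique reads are not zeroed at
    initialisation.  ``em_total[l] = theta_l * (number of assigned reads)``.
    """
    index = LocusIndex(loci)
    locus_ids = [l.locus_id for l in loci]
    pos = {lid: i for i, lid in enumerate(locus_ids)}
    n = len(locus_ids)

    unique = np.zeros(n)
    ambiguous: dict[tuple[int, ...], int] = {}
    n_dropped = 0
    for records in group_by_read(alignments).values():
        cand: set[int] = set()
        for rec in records:
            min_bp = read_overlap_frac * rec.interval.length
            for locus in index.overlapping(rec.interval):
                if rec.interval.overlap_bp(locus.interval) >= min_bp:
                    cand.add(pos[locus.locus_id])
        if not cand:
            n_dropped += 1
            continue
        if len(cand) == 1:
            unique[cand.pop()] += 1
        else:
            key = tuple(sorted(cand))
            ambiguous[key] = ambiguous.get(key, 0) + 1
    if n_dropped:
        logger.info("em_locus_quant: dropped %d reads outside all loci", n_dropped)

    n_unique = float(unique.sum())
    n_multi = float(sum(ambiguous.values()))
    n_assigned = n_unique + n_multi

    if n == 0 or n_assigned == 0:
        return LocusCounts({lid: 0 for lid in locus_ids}, {lid: 0.0 for lid in locus_ids}, 0, True)

    theta = np.full(n, 1.0 / n)
    loglik: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # E-step: responsibilities for ambiguous classes; log-likelihood
        assigned = unique.copy()
        ll = float(np.sum(unique[unique > 0] * np.log(theta[unique > 0])))
        for key, count in ambiguous.items():
            idx = np.array(key)
            mass = theta[idx].sum()
            if mass > 0:
                assigned[idx] += count * theta[idx] / mass
                ll += count * math.log(mass)
            else:  # degenerate class: equal shares
                assigned[idx] += count / len(idx)
                ll += -math.inf
        loglik.append(ll)
        new_theta = assigned / n_assigned
        delta = float(np.abs(new_theta - theta).max())
        theta = new_theta
        if delta < tol:
            converged = True
            break
        if not ambiguous:
            converged = True
            break
    if not converged:
        logger.warning("em_locus_quant: no convergence after %d iterations", max_iter)

    em_total = theta * n_assigned
    return LocusCounts(
        unique={lid: int(unique[pos[lid]]) for lid in locus_ids},
        em_total={lid: float(em_total[pos[lid]]) for lid in locus_ids},
        iterations=iterations,
        converged=converged,
        log_likelihood=loglik,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_family_counts(fc: FamilyCounts, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("family\tcount\tcpm\tlog2_cpm1\n")
        for fam in sorted(fc.counts):
            fh.write(f"{fam}\t{fc.counts[fam]:g}\t{fc.cpm[fam]:.6g}\t{fc.log2_cpm1[fam]:.6g}\n")


def write_locus_counts(lc: LocusCounts, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tunique\tem_total\n")
        for lid in sorted(lc.unique):
            fh.write(f"{lid}\t{lc.unique[lid]}\t{lc.em_total[lid]:.6f}\n")
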