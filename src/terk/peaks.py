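"""Peak-to-TE assignment and per-family peak enrichment testing.

Peaks (pre-merged and blacklist-filtered upstream) are assigned to the TE
locus they overlap most, provided the overlap covers at least ``min_frac``
of the peak.  Per family, the observed number of assigned peaks is compared
with an expectation proportional either to the family's genomic span or to
its locus count, with a 1-df two-cell chi-square (no continuity correction)
and BH adjustment across families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from terk.expression import bh_adjust
from terk.intervals import GenomicInterval, LocusIndex, TELocus, overlap_fraction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakRecord:
    """A called peak; summit_offset is relative to the peak start (or None)."""

    interval: GenomicInterval
    summit_offset: int | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError("summit_offset outside peak")

    @property
    def summit(self) -> int:
        """Absolute summit position; peak midpoint (floor) when absent."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.start + self.interval.length // 2


def read_peaks(path: str) -> list[PeakRecord]:
    """Read narrowPeak (10 columns, summit offset in column 10) or BED."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            summit = None
            if len(fields) >= 10:
                off = int(fields[9])
                summit = off if off >= 0 else None
            peaks.append(PeakRecord(GenomicInterval(chrom, start, end), summit, score))
    return peaks


def write_peaks(peaks: Sequence[PeakRecord], path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            off = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t{p.score:g}\t.\t0\t-1\t-1\t{off}\n"
            )


@dataclass
class PeakAssignment:
    """Mapping of peaks to loci plus per-family tallies."""

    assignment: dict[int, str | None]  # peak index -> locus_id or None
    family_counts: dict[str, int]
    bound_loci: dict[str, set[str]]  # family -> set of bound locus_ids

    @property
    def n_assigned(self) -> int:
        return sum(1 for v in self.assignment.values() if v is not None)


def assign_peaks_to_te(
    peaks: Sequence[PeakRecord],
    te_loci: Sequence[TELocus] | LocusIndex,
    min_frac: float = 0.5,
    overlap_on: str = "peak",
) -> PeakAssignment:
    """Assign each peak to the locus maximizing overlap, at >= min_frac.

    The fraction denominator is the peak length by default (``overlap_on=
    'peak'``) or the repeat length (``'repeat'``).  Ties on overlap are
    broken by smaller locus start, then lexicographic locus_id, so output is
    independent of input order.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    index = te_loci if isinstance(te_loci, LocusIndex) else LocusIndex(te_loci)
    assignment: dict[int, str | None] = {}
    family_counts: dict[str, int] = {}
    bound: dict[str, set[str]] = {}
    for i, peak in enumerate(peaks):
        best: tuple[int, int, str] | None = None  # (-overlap, start, locus_id)
        best_locus: TELocus | None = None
        for locus in index.overlapping(peak.interval):
            ov = peak.interval.overlap_bp(locus.interval)
            key = (-ov, locus.interval.start, locus.locus_id)
            if best is None or key < best:
                best, best_locus = key, locus
        if best_locus is not None:
            if overlap_on == "peak":
                frac = overlap_fraction(peak.interval, best_locus.interval)
            else:
                frac = overlap_fraction(best_locus.interval, peak.interval)
            if frac >= min_frac:
                assignment[i] = best_locus.locus_id
                family_counts[best_locus.family] = family_counts.get(best_locus.family, 0) + 1
                bound.setdefault(best_locus.family, set()).add(best_locus.locus_id)
                continue
        assignment[i] = None
    return PeakAssignment(assignment, family_counts, bound)


def expected_family_peaks(
    n_assigned: int,
    te_loci: Sequence[TELocus],
    model: str = "span",
) -> dict[str, float]:
    """Expected assigned-peak counts per family under a genomic null.

    span model: expected proportional to the family's total bp; count model:
    proportional to its number of loci.  Zero-weight families are excluded
    (logged).
    """
    if model not in ("span", "count"):
        raise ValueError("model must be 'span' or 'count'")
    weights: dict[str, float] = {}
    for locus in te_loci:
        w = locus.length_bp if model == "span" else 1
        weights[locus.family] = weights.get(locus.family, 0.0) + w
    total = sum(weights.values())
    expected = {}
    for fam, w in weights.items():
        if w == 0:
            logger.info("expected_family_peaks: family %s has zero weight, excluded", fam)
            continue
        expected[fam] = n_assigned * w / total
    return expected


@dataclass
class EnrichmentResult:
    family: str
    observed: int
    expected: float
    chi2: float
    p: float
    padj: float = 1.0
    reported: bool = True
    low_expected: bool = False


def family_enrichment_test(
    observed: Mapping[str, int], expected: Mapping[str, float]
) -> list[EnrichmentResult]:
    """Per-family 1-df chi-square of observed vs expected peak share.

    For each family the assigned peaks are partitioned into in-family and
    out-of-family cells; chi2 = (o-e)^2/e + ((N-o)-(N-e))^2/(N-e), with p
    from the upper tail of chi-square(1).  No continuity correction.
    Families with an expected cell < 5 are flagged but still tested.
    """
    total = sum(expected.values())
    results = []
    for fam in sorted(expected):
        e = expected[fam]
        if e <= 0:
            raise ValueError(f"expected count for {fam} must be > 0")
        o = int(observed.get(fam, 0))
        out_o, out_e = total - o, total - e
        chi2 = (o - e) ** 2 / e
        if out_e > 0:
            chi2 += (out_o - out_e) ** 2 / out_e
        p = float(stats.chi2.sf(chi2, df=1))
        results.append(
            EnrichmentResult(fam, o, e, chi2, p, low_expected=min(e, out_e) < 5)
        )
    if results:
        padj = bh_adjust([r.p for r in results])
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results


def reporting_filter(
    results: Sequence[EnrichmentResult], min_peaks: int = 5
) -> list[EnrichmentResult]:
    """Mark families with at least ``min_peaks`` observed peaks as reported."""
    for r in results:
        r.reported = r.observed >= min_peaks
    return list(results)


def write_enrichment(results: Sequence[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("family\tobserved\texpected\tchi2\tp\tpadj\treported\tlow_expected\n")
        for r in results:
            fh.write(
                f"{r.family}\t{r.observed}\t{r.expected:.6g}\t{r.chi2:.6g}\t{r.p:.6g}\t"
                f"{r.padj:.6g}\t{int(r.reported)}\t{int(r.low_expected)}\n"
            )
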