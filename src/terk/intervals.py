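"""Genomic-interval data model, annotation readers and interval algebra.

Everything internal is 0-based half-open (BED convention).  GTF is read
1-based inclusive and converted at the boundary; UCSC rmsk ``genoStart`` is
treated as already 0-based.  Repeat loci close to gene models are removed
before any TE quantification so that read counts over repeats are not
confounded by overlapping genic transcription.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

_RMSK_COLS = ("genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily")


class AnnotationFormatError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_position(self, chrom: str, pos: int) -> float:
        """Distance in bp from the nearest interval base to ``pos``; 0 if inside."""
        if self.chrom != chrom:
            return float("inf")
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)


@dataclass(frozen=True)
class TELocus:
    """One repeat-annotation interval with family/class identity."""

    interval: GenomicInterval
    family: str
    class_name: str = ""
    locus_id: str = ""

    def __post_init__(self) -> None:
        if not self.locus_id:
            iv = self.interval
            object.__setattr__(self, "locus_id", f"{iv.chrom}:{iv.start}-{iv.end}:{self.family}")

    @property
    def length_bp(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS (width-1 interval at the strand-aware 5' end)."""

    gene_id: str
    tss: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    utrs: tuple[GenomicInterval, ...] = ()
    strand: str = "+"

    @property
    def tss_position(self) -> int:
        return self.tss.start


@dataclass
class AnnotationSet:
    """A bundle of repeat loci, gene models and chromosome sizes."""

    te_loci: list[TELocus] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def loci_of_family(self, family: str) -> list[TELocus]:
        return [l for l in self.te_loci if l.family == family]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.te_loci:
            seen.setdefault(l.family, None)
        return list(seen)


class LocusIndex:
    """Per-chromosome interval tree over TE loci for overlap lookups."""

    def __init__(self, loci: Iterable[TELocus]):
        self._trees: dict[str, IntervalTree] = {}
        self.loci = list(loci)
        for locus in self.loci:
            iv = locus.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, locus)

    def overlapping(self, interval: GenomicInterval) -> list[TELocus]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_repeat_annotation(path: str) -> list[TELocus]:
    """Read repeat loci from BED6 (name column = family) or UCSC rmsk TSV.

    The rmsk dialect is recognised by a header line containing ``genoName``;
    otherwise six tab-separated columns are parsed as BED6.  Coordinates in
    both dialects end up 0-based half-open; stable locus ids are assigned as
    ``chrom:start-end:family``.
    """
    loci: list[TELocus] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return loci
    header = lines[0].rstrip("\n").split("\t")
    if "genoName" in header:
        idx = {}
        for col in _RMSK_COLS:
            if col not in header:
                raise AnnotationFormatError(f"rmsk table missing column {col!r}")
            idx[col] = header.index(col)
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                chrom = fields[idx["genoName"]]
                start = int(fields[idx["genoStart"]])
                end = int(fields[idx["genoEnd"]])
                strand = fields[idx["strand"]]
                family = fields[idx["repName"]]
                class_name = fields[idx["repClass"]]
            except (IndexError, ValueError) as exc:
                raise AnnotationFormatError(f"{path}: malformed rmsk line {ln}: {exc}") from exc
            if strand == "C":  # rmsk uses C for the reverse strand
                strand = "-"
            loci.append(TELocus(GenomicInterval(chrom, start, end, strand), family, class_name))
        return loci
    # BED6
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("track", "#", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise AnnotationFormatError(f"{path}: line {ln}: expected >=4 BED columns")
        try:
            chrom, start, end, family = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 else "."
        except ValueError as exc:
            raise AnnotationFormatError(f"{path}: malformed BED line {ln}: {exc}") from exc
        loci.append(TELocus(GenomicInterval(chrom, start, end, strand), family))
    return loci


def write_bed(loci: Iterable[TELocus], path: str) -> None:
    """Write TE loci as BED6 (score column 0, name = family)."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{locus.family}\t0\t{strand}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from a GTF with exon (and optional UTR) features.

    GTF coordinates are 1-based inclusive and converted to 0-based half-open.
    The TSS is the 5'-most exon boundary on the gene's strand.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    utrs: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationFormatError(f"{path}: line {ln}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("exon", "UTR", "five_prime_utr", "three_prime_utr"):
                continue
            match = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = match.get("gene_id")
            if gene_id is None:
                raise AnnotationFormatError(f"{path}: line {ln}: missing gene_id attribute")
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            strands[gene_id] = strand
            if feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
            else:
                utrs.setdefault(gene_id, []).append(iv)
    genes = []
    for gene_id, ex in exons.items():
        ex = sorted(ex, key=lambda iv: (iv.start, iv.end))
        strand = strands[gene_id]
        if strand == "+":
            tss_pos = ex[0].start
        else:
            tss_pos = max(iv.end for iv in ex) - 1
        tss = GenomicInterval(ex[0].chrom, tss_pos, tss_pos + 1, strand)
        genes.append(
            GeneModel(gene_id, tss, tuple(ex), tuple(utrs.get(gene_id, ())), strand)
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "terk") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for i, ex in enumerate(gene.exons, start=1):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; exon_number "{i}";'
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{gene.strand}\t.\t{attrs}\n"
                )


def load_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise AnnotationFormatError(f"{path}: line {ln}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b`` (0 on different chromosomes)."""
    return a.overlap_bp(b) / a.length


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap_bp: int = 50
) -> list[GenomicInterval]:
    """Merge intervals whose gap is strictly less than ``max_gap_bp``.

    Overlapping and bookended intervals always merge; strand is ignored and
    the output carries strand '.'.  Output is sorted and disjoint with
    pairwise gaps >= ``max_gap_bp``.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end < max_gap_bp:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def filter_te_loci(
    te_loci: Sequence[TELocus],
    genes: Sequence[GeneModel],
    tss_exclusion_bp: int = 1000,
) -> list[TELocus]:
    """Remove repeat loci that overlap exons/UTRs or sit near a TSS.

    A locus is dropped when its interval overlaps (>= 1 bp) any exon or UTR
    of any gene, or when the distance from its nearest edge to any TSS is
    <= ``tss_exclusion_bp`` (inclusive boundary; overlap counts as 0).
    Survivors keep their input order.
    """
    if tss_exclusion_bp < 0:
        raise ValueError("tss_exclusion_bp must be non-negative")
    exonic: dict[str, IntervalTree] = {}
    tss_positions: dict[str, list[int]] = {}
    for gene in genes:
        for iv in list(gene.exons) + list(gene.utrs):
            exonic.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        tss_positions.setdefault(gene.tss.chrom, []).append(gene.tss_position)
    for positions in tss_positions.values():
        positions.sort()

    survivors = []
    for locus in te_loci:
        iv = locus.interval
        tree = exonic.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            continue
        positions = tss_positions.get(iv.chrom, ())
        if positions and _near_any_position(iv, positions, tss_exclusion_bp):
            continue
        survivors.append(locus)
    return survivors


def _near_any_position(iv: GenomicInterval, sorted_pos: Sequence[int], max_dist: int) -> bool:
    """True if any position in ``sorted_pos`` is within ``max_dist`` of ``iv``."""
    # a TSS t is within max_dist iff start - max_dist <= t <= end - 1 + max_dist
    lo, hi = iv.start - max_dist, iv.end - 1 + max_dist
    i = bisect_left(sorted_pos, lo)
    return i < len(sorted_pos) and sorted_pos[i] <= hi
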