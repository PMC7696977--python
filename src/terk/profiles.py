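"""Binned, strand-aware signal metaprofiles over TE loci.

Signal tracks carry bedGraph semantics: disjoint per-chromosome segments
with non-negative values.  For each locus, a window of ``flank_bp`` on each
side of its 5' anchor is split into ``bin_bp`` bins; segment mass is
distributed into bins by exact bp overlap (value x overlapping bp) and
normalised to CPM per bin by the track's library size.  For minus-strand
loci the bin order is reversed so that bin 0 is always the 5'-most upstream
bin — this is what makes profiles from loci on both strands averageable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from terk.intervals import GenomicInterval, TELocus

logger = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    """Piecewise-constant genomic signal (bedGraph semantics)."""

    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # chrom -> (starts, ends, values)
    library_size: float

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[GenomicInterval, float]], library_size: float | None = None
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in records:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        segments = {}
        mass = 0.0
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph segments on {chrom}")
            segments[chrom] = (starts, ends, values)
            mass += float(((ends - starts) * values).sum())
        if library_size is None:
            library_size = mass
        return cls(segments, float(library_size))

    @classmethod
    def read_bedgraph(cls, path: str, library_size: float | None = None) -> "SignalTrack":
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                records.append((GenomicInterval(chrom, int(start), int(end)), float(value)))
        return cls.from_records(records, library_size)

    def window_mass_per_bin(self, chrom: str, win_start: int, win_end: int, bin_bp: int) -> np.ndarray:
        """Tag mass per bin over [win_start, win_end); missing bases are 0."""
        n_bins = (win_end - win_start) // bin_bp
        out = np.zeros(n_bins)
        seg = self.segments.get(chrom)
        if seg is None:
            return out
        starts, ends, values = seg
        lo = int(np.searchsorted(ends, win_start, side="right"))
        hi = int(np.searchsorted(starts, win_end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), win_start)
            e = min(int(ends[i]), win_end)
            if s >= e or values[i] == 0.0:
                continue
            b0 = (s - win_start) // bin_bp
            b1 = (e - 1 - win_start) // bin_bp
            if b0 == b1:
                out[b0] += values[i] * (e - s)
            else:
                out[b0] += values[i] * ((win_start + (b0 + 1) * bin_bp) - s)
                out[b1] += values[i] * (e - (win_start + b1 * bin_bp))
                if b1 > b0 + 1:
                    out[b0 + 1 : b1] += values[i] * bin_bp
        return out


@dataclass
class ProfileMatrix:
    """Loci x bins matrix of per-bin CPM, plus the per-bin aggregate."""

    loci: list[str]
    n_bins: int
    bin_bp: int
    flank_bp: int
    matrix: np.ndarray
    aggregate_mode: str = "mean"
    aggregated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.recompute_aggregate()

    def recompute_aggregate(self) -> None:
        if self.matrix.shape[0] == 0:
            self.aggregated = np.zeros(self.n_bins)
        elif self.aggregate_mode == "sum":
            self.aggregated = self.matrix.sum(axis=0)
        else:
            self.aggregated = self.matrix.mean(axis=0)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            header = "\t".join(f"bin{j}" for j in range(self.n_bins))
            fh.write(f"locus_id\t{header}\n")
            for lid, row in zip(self.loci, self.matrix):
                fh.write(lid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
            fh.write("aggregate\t" + "\t".join(f"{v:.6g}" for v in self.aggregated) + "\n")


def anchor_position(locus: TELocus, anchor: str = "five-prime") -> int:
    """Anchor coordinate: strand-aware 5' boundary, or literal left boundary."""
    iv = locus.interval
    if anchor == "left" or iv.strand != "-":
        return iv.start
    return iv.end


def build_profile(
    track: SignalTrack,
    loci: Sequence[TELocus],
    flank_bp: int = 5000,
    bin_bp: int = 100,
    anchor: str = "five-prime",
    aggregate_mode: str = "mean",
) -> ProfileMatrix:
    """Binned CPM profile of ``track`` around the 5' anchor of each locus.

    Bin 0 is the 5'-most upstream bin regardless of strand; windows running
    off a chromosome contribute zeros in the missing bins, and loci on
    chromosomes absent from the track yield all-zero rows (kept, logged) so
    profiles stay comparable across tracks.
    """
    if (2 * flank_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*flank_bp")
    if track.library_size <= 0:
        raise ValueError("library_size must be positive")
    n_bins = 2 * flank_bp // bin_bp
    scale = 1e6 / track.library_size
    rows = np.zeros((len(loci), n_bins))
    n_missing = 0
    for i, locus in enumerate(loci):
        chrom = locus.interval.chrom
        if chrom not in track.segments:
            n_missing += 1
            continue
        a = anchor_position(locus, anchor)
        mass = track.window_mass_per_bin(chrom, a - flank_bp, a + flank_bp, bin_bp)
        if anchor != "left" and locus.interval.strand == "-":
            mass = mass[::-1]
        rows[i] = mass * scale
    if n_missing:
        logger.info("build_profile: %d loci on chromosomes absent from track", n_missing)
    return ProfileMatrix(
        [l.locus_id for l in loci], n_bins, bin_bp, flank_bp, rows, aggregate_mode
    )


def average_replicates(profiles: Sequence[ProfileMatrix]) -> ProfileMatrix:
    """Element-wise mean of replicate profiles over identical loci/bins."""
    first = profiles[0]
    for p in profiles[1:]:
        if p.loci != first.loci or p.n_bins != first.n_bins or p.bin_bp != first.bin_bp:
            raise ValueError("replicate profiles have mismatched loci or binning")
    mean = np.mean([p.matrix for p in profiles], axis=0)
    return ProfileMatrix(
        list(first.loci), first.n_bins, first.bin_bp, first.flank_bp, mean, first.aggregate_mode
    )


def profile_contrast(a: ProfileMatrix, b: ProfileMatrix, mode: str = "difference") -> np.ndarray:
    """Per-bin contrast of two aggregated profiles (difference or log2 ratio)."""
    if a.n_bins != b.n_bins or a.bin_bp != b.bin_bp:
        raise ValueError("profiles have mismatched binning")
    if mode == "ratio":
        return np.log2((a.aggregated + 1.0) / (b.aggregated + 1.0))
    return a.aggregated - b.aggregated
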