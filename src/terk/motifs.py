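"""E-box motif scanning and the bound-vs-unbound presence test.

The canonical E-box CA(C/T)GTG is the hexamer bound by MITF/MYC/MAX-class
basic helix-loop-helix factors.  Scanning covers both strands: CACGTG is its
own reverse complement and is reported once per position on the + strand;
CATGTG on the reverse strand appears as CACATG on the forward sequence.
Presence is binary per sequence (a locus either carries the motif or not),
and the bound/unbound association is a 2x2 chi-square without continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from terk.intervals import GenomicInterval

if TYPE_CHECKING:  # avoid a cycle with terk.peaks, which uses our chi-square
    from terk.peaks import PeakRecord

logger = logging.getLogger(__name__)

EBOX_FORWARD = ("CACGTG", "CATGTG")
# CACGTG is palindromic; the only extra reverse-strand word is revcomp(CATGTG)
EBOX_REVERSE_ONLY = ("CACATG",)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class MotifHit:
    """A 6-mer E-box match at a 0-based position on the forward sequence."""

    sequence_id: str
    position: int
    strand: str
    matched: str


def summit_windows(
    peaks: Sequence["PeakRecord"], flank_bp: int = 25
) -> list[GenomicInterval]:
    """Summit-centered windows of 2*flank+1 bp (summit base included).

    Peaks without a recorded summit use the peak midpoint.  Windows running
    past position 0 are clamped (logged).
    """
    windows = []
    n_clamped = 0
    for peak in peaks:
        s = peak.summit
        start = s - flank_bp
        if start < 0:
            n_clamped += 1
            start = 0
        windows.append(GenomicInterval(peak.interval.chrom, start, s + flank_bp + 1))
    if n_clamped:
        logger.info("summit_windows: clamped %d windows at chromosome start", n_clamped)
    return windows


def scan_ebox(record: SequenceRecord) -> list[MotifHit]:
    """All E-box occurrences on either strand, by forward-strand position.

    The palindromic CACGTG is reported once per position with strand '+'.
    N never matches.
    """
    seq = record.sequence
    hits = []
    for pos in range(len(seq) - 5):
        word = seq[pos : pos + 6]
        if word in EBOX_FORWARD:
            hits.append(MotifHit(record.id, pos, "+", word))
        elif word in EBOX_REVERSE_ONLY:
            hits.append(MotifHit(record.id, pos, "-", reverse_complement(word)))
    return hits


def has_ebox(record: SequenceRecord) -> bool:
    seq = record.sequence
    return any(w in seq for w in EBOX_FORWARD + EBOX_REVERSE_ONLY)


@dataclass
class MotifPresenceTable:
    """2x2 table (bound, unbound) x (with motif, without motif) + chi-square."""

    table: np.ndarray  # rows: bound, unbound; cols: with, without
    chi2: float
    p: float

    @property
    def bound_with(self) -> int:
        return int(self.table[0, 0])

    @property
    def n_bound(self) -> int:
        return int(self.table[0].sum())

    @property
    def unbound_with(self) -> int:
        return int(self.table[1, 0])

    @property
    def n_unbound(self) -> int:
        return int(self.table[1].sum())


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if table.sum() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def motif_presence_test(
    bound: Sequence[SequenceRecord], unbound: Sequence[SequenceRecord]
) -> MotifPresenceTable:
    """Chi-square test of E-box presence in bound vs unbound sequences.

    Presence is binary per sequence: at least one hit anywhere, either
    strand.
    """
    if not bound or not unbound:
        raise ValueError("both bound and unbound groups must be non-empty")
    bw = sum(has_ebox(r) for r in bound)
    uw = sum(has_ebox(r) for r in unbound)
    table = np.array([[bw, len(bound) - bw], [uw, len(unbound) - uw]])
    if 0 in table.sum(axis=0):  # no variation in presence: nothing to test
        return MotifPresenceTable(table, 0.0, 1.0)
    chi2, p = chi2_2x2(table)
    return MotifPresenceTable(table, chi2, p)


def fetch_sequences(
    fasta_path: str, intervals: Sequence[GenomicInterval], ids: Sequence[str] | None = None
) -> list[SequenceRecord]:
    """Extract interval sequences from an indexed FASTA (0-based half-open)."""
    from pyfaidx import Fasta

    fasta = Fasta(fasta_path)
    out = []
    for i, iv in enumerate(intervals):
        name = ids[i] if ids is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        seq = str(fasta[iv.chrom][iv.start : iv.end])
        out.append(SequenceRecord(name, seq))
    return out


def write_hits_bed(hits: Sequence[MotifHit], path: str) -> None:
    """Hits as BED6; sequence ids of the form chrom:start-end map to genome."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.position}\t{h.position + 6}\t{h.matched}\t0\t{h.strand}\n")
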