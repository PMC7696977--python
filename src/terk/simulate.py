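"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their parameters and a seed (one
`numpy.random.default_rng` per call, no global state), and write the exact
text dialects the readers consume (BED6, GTF, SAM, bedGraph, narrowPeak,
FASTA, TSV) so I/O is exercised end to end.  Each generator plants a known
truth — family abundances, locus proportions, an enriched family, motif
presence probabilities, true DEGs, a profile bump — recorded in a
:class:`TruthBundle` for parameter-recovery and calibration tests.

Defaults emulate the regime of a TE-centric melanoma regulatory study: a
small multi-chromosome genome carrying several repeat families, one of them
an LTR5_Hs-like family of solo/proviral LTR loci; ~50k reads of 100 bp with
40% multi-mappers; signal tracks with peak-shaped enrichment at LTR
anchors; peak sets with one 3x-enriched family; and DE tables with 10%
planted true positives at |log2FC| = 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from terk.expression import DERecord
from terk.intervals import AnnotationSet, GeneModel, GenomicInterval, TELocus
from terk.peaks import PeakRecord
from terk.profiles import SignalTrack
from terk.quant import AlignmentRecord

LTR_FAMILY = "LTR5_Hs"


@dataclass
class TruthBundle:
    """Planted parameters behind one synthetic dataset."""

    seed: int
    family_proportions: dict[str, float] = field(default_factory=dict)
    locus_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched_family: str = LTR_FAMILY
    enrichment_fold: float = 3.0
    motif_presence_probs: tuple[float, float] = (0.5, 0.1)  # (bound p1, unbound p0)
    bound_locus_ids: list[str] = field(default_factory=list)
    profile_bump_height: float = 5.0
    profile_bump_sd: float = 150.0
    profile_bump_offset: int = 0
    multimap_cross_family_prob: float = 0.1
    true_deg_ids: list[str] = field(default_factory=list)
    planted_lfc: float = 2.0
    true_candidate_gene_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _place_nonoverlapping(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom_names: Sequence[str],
    chrom_len: int,
    length: int,
    margin: int = 0,
) -> tuple[str, int] | None:
    """Sample a (chrom, start) uniformly over every feasible placement.

    Feasible means the new ``[start, start+length)`` stays ``margin`` bp away
    from every occupied interval and inside the chromosome.  Enumerating the
    free gaps makes placement exact: it fails only when no gap can hold the
    interval at all.
    """
    ranges: list[tuple[str, int, int]] = []  # (chrom, first start, n starts)
    total = 0
    for chrom in chrom_names:
        blocked = sorted(
            (max(0, s - margin), min(chrom_len, e + margin))
            for s, e in occupied.get(chrom, ())
        )
        merged: list[list[int]] = []
        for s, e in blocked:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        prev = 0
        for s, e in merged + [[chrom_len, chrom_len]]:
            n_starts = (s - length) - prev + 1
            if n_starts > 0:
                ranges.append((chrom, prev, n_starts))
                total += n_starts
            prev = max(prev, e)
    if total == 0:
        return None
    pick = int(rng.integers(total))
    for chrom, first, n_starts in ranges:
        if pick < n_starts:
            start = first + pick
            occupied.setdefault(chrom, []).append((start, start + length))
            return chrom, start
        pick -= n_starts
    raise AssertionError("unreachable")


def make_annotation(
    seed: int,
    n_chroms: int = 3,
    chrom_len: int = 1_000_000,
    families: int = 4,
    loci_per_family: int = 50,
    n_genes: int = 100,
    locus_len_range: tuple[int, int] = (300, 1000),
) -> tuple[AnnotationSet, TruthBundle]:
    """Non-overlapping TE loci and gene models on a small synthetic genome.

    One family is labeled LTR5_Hs; family abundance proportions are fixed to
    the descending simplex (k, k-1, ..., 1)/sum so that ranking-recovery
    properties are well separated; locus proportions within a family follow
    a seeded Dirichlet(5) draw.  Gene models keep a >= 1.1 kb clearance from
    TE loci so the TSS/exon exclusion filter does not silently remove
    planted loci.  Half of the LTR5_Hs loci are designated TF-bound
    (relevant for sequence simulation and enhancer screening).
    """
    if min(n_chroms, chrom_len, families, loci_per_family, n_genes) <= 0:
        raise ValueError("all annotation parameters must be positive")
    # coarse feasibility guard: mean locus length plus mean gene footprint
    # (~3 exons of ~350 bp, ~2 introns of ~1.1 kb, 1.1 kb clearance per side)
    requested_bp = families * loci_per_family * sum(locus_len_range) // 2 + n_genes * 5_500
    if requested_bp > 0.8 * n_chroms * chrom_len:
        raise ValueError("infeasible packing: requested bp exceeds genome capacity")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    family_names = [LTR_FAMILY] + [f"TEfam{i + 1}" for i in range(1, families)]

    # genes first (few, large), then loci packed into the remaining gaps with
    # a 1.1 kb clearance from any gene so the TSS/exon filter keeps all loci
    gene_occ: dict[str, list[tuple[int, int]]] = {}
    genes: list[GeneModel] = []
    for g in range(n_genes):
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(200, 501, size=n_exons)
        intron_lens = rng.integers(200, 2001, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        placed = _place_nonoverlapping(rng, gene_occ, chrom_names, chrom_len, span)
        if placed is None:
            raise ValueError("infeasible packing: could not place gene")
        chrom, start = placed
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
            pos += int(exon_lens[i]) + (int(intron_lens[i]) if i < n_exons - 1 else 0)
        tss_pos = start if strand == "+" else pos - 1
        tss = GenomicInterval(chrom, tss_pos, tss_pos + 1, strand)
        genes.append(GeneModel(f"gene{g + 1}", tss, tuple(exons), (), strand))

    occupied: dict[str, list[tuple[int, int]]] = {
        chrom: [(max(0, s - 1100), min(chrom_len, e + 1100)) for s, e in spans]
        for chrom, spans in gene_occ.items()
    }
    te_loci: list[TELocus] = []
    for fam in family_names:
        for _ in range(loci_per_family):
            length = int(rng.integers(locus_len_range[0], locus_len_range[1] + 1))
            placed = _place_nonoverlapping(rng, occupied, chrom_names, chrom_len, length)
            if placed is None:
                raise ValueError("infeasible packing: could not place locus")
            chrom, start = placed
            strand = "+" if rng.random() < 0.5 else "-"
            te_loci.append(
                TELocus(GenomicInterval(chrom, start, start + length, strand), fam, "LTR")
            )

    annotation = AnnotationSet(te_loci, genes, {c: chrom_len for c in chrom_names})

    k = families
    fam_props = np.arange(k, 0, -1, dtype=float)
    fam_props /= fam_props.sum()
    truth = TruthBundle(seed=seed)
    truth.family_proportions = {f: float(p) for f, p in zip(family_names, fam_props)}
    for fam in family_names:
        ids = [l.locus_id for l in te_loci if l.family == fam]
        props = rng.dirichlet(np.full(len(ids), 5.0))
        truth.locus_proportions[fam] = {i: float(p) for i, p in zip(ids, props)}
    ltr_ids = [l.locus_id for l in te_loci if l.family == LTR_FAMILY]
    n_bound = len(ltr_ids) // 2
    truth.bound_locus_ids = sorted(
        rng.choice(ltr_ids, size=n_bound, replace=False).tolist()
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def simulate_alignments(
    annotation: AnnotationSet,
    truth: TruthBundle,
    n_reads: int = 50_000,
    read_len: int = 100,
    multimap_rate: float = 0.4,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Reads drawn from planted family/locus abundances, with multi-mappers.

    Each read originates in a family per ``truth.family_proportions`` and a
    locus per the within-family proportions, fully inside the locus.  With
    probability ``multimap_rate`` it is additionally reported at k-1 extra
    positions (k in 2..4) drawn uniformly over loci of the same family, or
    of a random other family with probability
    ``truth.multimap_cross_family_prob``.  Secondary loci are uniform over
    loci (not abundance-weighted) so the reported-position ambiguity is
    independent of the read's true origin — the regime EM redistribution
    assumes.
    """
    if not (0 <= multimap_rate <= 1):
        raise ValueError("multimap_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {l.locus_id: l for l in annotation.te_loci}
    families = list(truth.family_proportions)
    fam_p = np.array([truth.family_proportions[f] for f in families])
    fam_loci: list[list[TELocus]] = [
        [by_id[lid] for lid in truth.locus_proportions[f]] for f in families
    ]
    fam_locus_p = [
        np.array(list(truth.locus_proportions[f].values())) for f in families
    ]

    # bulk randomness: origin family/locus, multimap structure
    fam_idx = rng.choice(len(families), size=n_reads, p=fam_p)
    prim_locus = np.zeros(n_reads, dtype=np.int64)
    for fi in range(len(families)):
        mask = fam_idx == fi
        if mask.any():
            prim_locus[mask] = rng.choice(
                len(fam_loci[fi]), size=int(mask.sum()), p=fam_locus_p[fi]
            )
    n_extra = np.where(
        rng.random(n_reads) < multimap_rate, rng.integers(1, 4, size=n_reads), 0
    )
    total_extra = int(n_extra.sum())
    cross = rng.random(total_extra) < (
        truth.multimap_cross_family_prob if len(families) > 1 else 0.0
    )
    other_pick = rng.integers(0, max(len(families) - 1, 1), size=total_extra)
    locus_u = rng.random(total_extra)
    pos_u = rng.random(n_reads + total_extra)

    def place(locus: TELocus, u: float) -> GenomicInterval:
        iv = locus.interval
        if iv.length >= read_len:
            s = iv.start + int(u * (iv.length - read_len + 1))
        else:
            s = max(0, iv.start + (iv.length - read_len) // 2)
        return GenomicInterval(iv.chrom, s, s + read_len, "+")

    records: list[AlignmentRecord] = []
    e = 0  # extra-alignment cursor
    u = 0  # position-randomness cursor
    for r in range(n_reads):
        fi = int(fam_idx[r])
        intervals = [place(fam_loci[fi][int(prim_locus[r])], pos_u[u])]
        u += 1
        for _ in range(int(n_extra[r])):
            if cross[e]:
                f2 = int(other_pick[e])
                if f2 >= fi:
                    f2 += 1
            else:
                f2 = fi
            loci2 = fam_loci[f2]
            intervals.append(place(loci2[int(locus_u[e] * len(loci2))], pos_u[u]))
            e += 1
            u += 1
        hit_count = len(intervals)
        read_id = f"read{r + 1}"
        for iv in intervals:
            records.append(
                AlignmentRecord(read_id, iv, hit_count, 255 if hit_count == 1 else 1)
            )
    return records


def write_sam(
    records: Sequence[AlignmentRecord], chrom_sizes: dict[str, int], path: str
) -> None:
    """Write alignment records as headered SAM with NH tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for rec in records:
            iv = rec.interval
            flag = 16 if iv.strand == "-" else 0
            cigar = f"{iv.length}M"
            fh.write(
                f"{rec.read_id}\t{flag}\t{iv.chrom}\t{iv.start + 1}\t{rec.mapq}\t"
                f"{cigar}\t*\t0\t0\t*\t*\tNH:i:{rec.hit_count}\n"
            )


# ---------------------------------------------------------------------------
# signal track
# ---------------------------------------------------------------------------

def simulate_track(
    annotation: AnnotationSet,
    truth: TruthBundle,
    library_size: float = 1e6,
    noise_sd: float = 0.5,
    background: float = 1.0,
    segment_bp: int = 25,
    seed: int = 0,
) -> SignalTrack:
    """Flat noisy background plus Gaussian bumps at enriched-family anchors.

    The track is piecewise constant on a ``segment_bp`` grid; each segment's
    value is a non-negative-clamped Normal(background, noise_sd) draw plus,
    within 4 sd of an enriched-family locus 5' anchor, the planted Gaussian
    bump of height ``truth.profile_bump_height`` and sd
    ``truth.profile_bump_sd`` evaluated at the segment midpoint.
    """
    rng = np.random.default_rng(seed)
    h, sd = truth.profile_bump_height, truth.profile_bump_sd
    anchors: dict[str, list[int]] = {}
    for locus in annotation.te_loci:
        if locus.family != truth.enriched_family:
            continue
        iv = locus.interval
        a = iv.start if iv.strand != "-" else iv.end
        anchors.setdefault(iv.chrom, []).append(a + truth.profile_bump_offset)
    records = []
    for chrom, size in annotation.chrom_sizes.items():
        n_seg = size // segment_bp
        starts = np.arange(n_seg) * segment_bp
        mids = starts + segment_bp / 2.0
        values = rng.normal(background, noise_sd, size=n_seg) if noise_sd > 0 else np.full(
            n_seg, float(background)
        )
        if h > 0:
            for a in anchors.get(chrom, ()):
                lo = max(0, int((a - 4 * sd) // segment_bp))
                hi = min(n_seg, int((a + 4 * sd) // segment_bp) + 1)
                values[lo:hi] += h * np.exp(-((mids[lo:hi] - a) ** 2) / (2 * sd**2))
        values = np.clip(values, 0.0, None)
        for i in range(n_seg):
            records.append(
                (GenomicInterval(chrom, int(starts[i]), int(starts[i]) + segment_bp), float(values[i]))
            )
    return SignalTrack.from_records(records, library_size)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.segments):
            starts, ends, values = track.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    annotation: AnnotationSet,
    truth: TruthBundle,
    n_peaks: int = 400,
    peak_len_range: tuple[int, int] = (150, 400),
    seed: int = 0,
) -> list[PeakRecord]:
    """Peaks placed over TE bp, the enriched family's rate scaled by fold.

    A locus is drawn with probability proportional to its length times
    ``truth.enrichment_fold`` for the enriched family (fold 1 = uniform over
    TE bp); the peak sits fully inside the locus when it fits, with its
    summit at the peak center.
    """
    rng = np.random.default_rng(seed)
    loci = annotation.te_loci
    weights = np.array(
        [
            l.length_bp * (truth.enrichment_fold if l.family == truth.enriched_family else 1.0)
            for l in loci
        ],
        dtype=float,
    )
    weights /= weights.sum()
    peaks = []
    for _ in range(n_peaks):
        locus = loci[rng.choice(len(loci), p=weights)]
        iv = locus.interval
        plen = int(rng.integers(peak_len_range[0], peak_len_range[1] + 1))
        if plen >= iv.length:
            start, end = iv.start, iv.end
        else:
            start = int(rng.integers(iv.start, iv.end - plen + 1))
            end = start + plen
        peaks.append(PeakRecord(GenomicInterval(iv.chrom, start, end), (end - start) // 2))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def simulate_sequences(
    annotation: AnnotationSet, truth: TruthBundle, seed: int = 0
) -> dict[str, str]:
    """I.i.d. uniform-nucleotide chromosomes with planted E-boxes.

    At the center of each enriched-family locus an E-box word (CACGTG or
    CATGTG, equal odds) is written with probability p1 for TF-bound loci and
    p0 for unbound ones, per ``truth.motif_presence_probs``.
    """
    rng = np.random.default_rng(seed)
    p1, p0 = truth.motif_presence_probs
    chroms = {}
    for chrom, size in annotation.chrom_sizes.items():
        arr = rng.integers(0, 4, size=size)
        chroms[chrom] = np.frombuffer(b"ACGT", dtype="S1")[arr]
    bound = set(truth.bound_locus_ids)
    for locus in annotation.te_loci:
        if locus.family != truth.enriched_family:
            continue
        p = p1 if locus.locus_id in bound else p0
        if rng.random() < p:
            word = ("CACGTG", "CATGTG")[int(rng.integers(2))]
            iv = locus.interval
            center = iv.start + iv.length // 2 - 3
            chroms[iv.chrom][center : center + 6] = np.frombuffer(word.encode(), dtype="S1")
    return {c: arr.tobytes().decode() for c, arr in chroms.items()}


def write_fasta(chroms: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chroms):
            fh.write(f">{chrom}\n")
            seq = chroms[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def simulate_de_table(
    n_genes: int = 1000,
    n_true: int = 100,
    lfc: float = 2.0,
    seed: int = 0,
) -> tuple[list[DERecord], TruthBundle]:
    """DE table with planted true positives.

    Null genes draw p ~ Uniform(0,1) and log2FC ~ Normal(0, 0.2); true genes
    draw p from a Beta(0.01, 1) alternative (sharply concentrated near 0)
    and log2FC = +-``lfc`` with random sign.
    """
    if n_true > n_genes:
        raise ValueError("n_true cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    truth = TruthBundle(seed=seed, planted_lfc=lfc)
    records = []
    true_idx = set(rng.choice(n_genes, size=n_true, replace=False).tolist())
    for i in range(n_genes):
        gene_id = f"gene{i + 1}"
        if i in true_idx:
            p = float(rng.beta(0.01, 1.0))
            fc = lfc if rng.random() < 0.5 else -lfc
            truth.true_deg_ids.append(gene_id)
        else:
            p = float(rng.uniform())
            fc = float(rng.normal(0.0, 0.2))
        records.append(DERecord(gene_id, fc, min(p, 1.0)))
    return records, truth


def write_de_table(records: Sequence[DERecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.8g}\n")


# ---------------------------------------------------------------------------
# integration fixture
# ---------------------------------------------------------------------------

def make_integration_fixture(
    seed: int,
    n_candidates: int = 3,
    neighborhood_bp: int = 10_000,
    **annotation_kwargs,
) -> tuple[AnnotationSet, list[DERecord], list[DERecord], set[str], TruthBundle]:
    """Annotation + DE tables + bound loci with planted enhancer candidates.

    ``n_candidates`` genes that have an LTR5_Hs locus within the TSS
    neighborhood are given a fully qualifying signature (significantly down
    across invasion states, significantly up with treatment, nearest locus
    TF-bound).  Decoy genes satisfying only two of the three criteria are
    planted alongside; all remaining genes carry null statistics.
    """
    annotation, truth = make_annotation(seed, **annotation_kwargs)
    rng = np.random.default_rng(seed + 1)
    ltr = annotation.loci_of_family(LTR_FAMILY)

    nearest: dict[str, tuple[float, str]] = {}
    for gene in annotation.genes:
        best = (float("inf"), "")
        for locus in ltr:
            d = locus.interval.distance_to_position(gene.tss.chrom, gene.tss_position)
            if d < best[0]:
                best = (d, locus.locus_id)
        nearest[gene.gene_id] = best
    eligible = [g for g in annotation.genes if nearest[g.gene_id][0] <= neighborhood_bp]
    if len(eligible) < n_candidates + 3:
        raise ValueError("not enough genes with an LTR5_Hs in the TSS neighborhood")
    picked = rng.choice(len(eligible), size=n_candidates + 2, replace=False)
    planted = [eligible[i] for i in picked[:n_candidates]]
    decoys = [eligible[i] for i in picked[n_candidates:]]

    bound = {nearest[g.gene_id][1] for g in planted}

    def neighborhood_loci(gene: GeneModel) -> set[str]:
        return {
            l.locus_id
            for l in ltr
            if l.interval.distance_to_position(gene.tss.chrom, gene.tss_position)
            <= neighborhood_bp
        }

    # a third decoy qualifies on DE but its whole TSS neighborhood must stay
    # unbound, so pick one whose neighborhood does not touch planted loci
    used = {g.gene_id for g in planted} | {g.gene_id for g in decoys}
    decoy_unbound = None
    blocked: set[str] = set()
    for gene in eligible:
        if gene.gene_id in used:
            continue
        hood = neighborhood_loci(gene)
        if not hood & bound:
            decoy_unbound, blocked = gene, hood
            break
    if decoy_unbound is None:
        raise ValueError("could not place an unbound-neighborhood decoy gene")
    extra = [l.locus_id for l in ltr if l.locus_id not in bound | blocked]
    bound |= set(rng.choice(extra, size=len(extra) // 4, replace=False).tolist())
    bound -= blocked

    sig_p, null_lfc_sd = 1e-6, 0.2

    def null_record(gene_id: str) -> tuple[float, float]:
        return float(rng.normal(0.0, null_lfc_sd)), float(rng.uniform(0.2, 1.0))

    de_states, de_treatment = [], []
    planted_ids = {g.gene_id for g in planted}
    for gene in annotation.genes:
        gid = gene.gene_id
        if gid in planted_ids:
            s_lfc, s_p = -2.0, sig_p
            t_lfc, t_p = 2.0, sig_p
        elif gid == decoys[0].gene_id:  # up with treatment, not reciprocal
            s_lfc, s_p = null_record(gid)
            t_lfc, t_p = 2.0, sig_p
        elif gid == decoys[1].gene_id:  # reciprocal, not up with treatment
            s_lfc, s_p = -2.0, sig_p
            t_lfc, t_p = null_record(gid)
        elif gid == decoy_unbound.gene_id:  # qualifying DE, unbound neighborhood
            s_lfc, s_p = -2.0, sig_p
            t_lfc, t_p = 2.0, sig_p
        else:
            s_lfc, s_p = null_record(gid)
            t_lfc, t_p = null_record(gid)
        de_states.append(DERecord(gid, s_lfc, s_p))
        de_treatment.append(DERecord(gid, t_lfc, t_p))

    truth.bound_locus_ids = sorted(bound)
    truth.true_candidate_gene_ids = sorted(planted_ids)
    return annotation, de_treatment, de_states, bound, truth
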