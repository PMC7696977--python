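# Methods

`terk` implements the computational core of a transposable-element (TE)
centric regulatory genomics analysis of the kind used to study HERV-K /
LTR5_Hs activity in melanoma: quantifying TE expression in the presence of
multi-mapping reads, profiling TF/chromatin signal around LTR loci, testing
which repeat families attract TF peaks, asking whether TF-bound loci carry
the E-box motif, and screening LTR neighborhoods for enhancer-candidate
genes. This note records the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic data do and do not show.

## Coordinates and locus filtering

All internal coordinates are 0-based half-open (BED convention). GTF input
is 1-based inclusive and converted at the reader; UCSC rmsk `genoStart` is
treated as already 0-based; the rmsk `C` strand symbol maps to `-`.

Before any quantification, repeat loci are removed when they overlap
(≥ 1 bp) a genic exon or UTR, or when their nearest edge is within
`tss_exclusion_bp` (default 1000) of any annotated TSS. The 1 kb boundary
is **inclusive** — "within 1 kb" has no open/closed reading that is clearly
right, so the inclusive convention was chosen and is pinned by a boundary
test. The TSS of a gene is the 5′-most exon boundary on its strand.

Peak merging fuses intervals whose gap is **strictly less than**
`max_gap_bp` (default 50), the literal reading of a "distance less than 50
base pairs" rule; overlapping and bookended intervals always merge.

Overlap fractions are computed relative to the **query (peak)** length,
matching the default fraction semantics of `intersectBed -f`. Because the
convention genuinely matters and tools differ, `--overlap-on
{peak,repeat}` exposes the alternative.

## Family-level quantification (exclusive-family rule)

A multi-mapping read is informative at family resolution when all of its
reported alignments land in one repeat family. Concretely, an alignment
"hits" a family when it overlaps a locus of that family by at least
`read_overlap_frac` (default 0.5) of the read length; a read is assigned to
family *f* iff every alignment hits at least one locus and the union of
families hit across all alignments is exactly {*f*}. Each assigned read
contributes **one** count regardless of its number of alignments. Counts
are scaled to CPM against an explicitly supplied library size — the total
reads mappable anywhere on the genome, which cannot be inferred from the
TE-overlapping subset and is therefore a required input — and expressed as
log2(CPM + 1). MAPQ is ignored here by design: multi-mappers carry low MAPQ
by construction and are precisely the reads this rule rescues.

## Locus-level quantification (EM)

Within a family, loci are too similar for unique assignment, so
multi-mapped reads are redistributed by expectation-maximization. Read *r*
has candidate locus set L(r) (loci any alignment overlaps at ≥ the read
overlap fraction; reads with empty L(r) are dropped and counted). With
locus abundances θ (a probability vector over loci):

* E-step: read *r* is fractionally assigned to locus *l* ∈ L(r) with
  responsibility θ_l / Σ_{k∈L(r)} θ_k;
* M-step: θ_l ∝ unique(l) + fractional assignments to *l*;
* iterate until max |Δθ| < `tol` (default 1e-8) or `max_iter` (1000);
  `em_total(l) = θ_l × (assigned reads)`.

θ is initialized **uniform**, not proportional to unique counts, so loci
without unique evidence are not zeroed at the start; unique evidence still
dominates the fixed point. A read whose candidate loci all carry θ = 0
receives equal fractional shares. Loci are deliberately not
length-normalized inside the EM — the outputs are counts, matching the CPM
reporting convention, not per-kb densities. The observed-data
log-likelihood Σ_r log Σ_{l∈L(r)} θ_l is recorded each iteration and tested
to be non-decreasing. For two loci with unique counts u_A, u_B and m shared
reads the fixed point is analytic, em_total(A) = u_A (u_A+u_B+m)/(u_A+u_B),
and the implementation is tested against it to 1e-6.

## Signal metaprofiles

Signal tracks carry bedGraph semantics (disjoint piecewise-constant
segments) plus a library size. For each locus the anchor is the
**strand-aware 5′ boundary** (interval start for `+`, interval end for
`-`); a ±`flank_bp` window (default 5000) is divided into `bin_bp` bins
(default 100) and segment mass is distributed into bins by exact bp overlap
(value × overlapping bp) rather than by segment midpoints — exact and
resolution-independent. Bins of minus-strand loci are reversed so bin 0 is
always the 5′-most upstream bin, which is what makes rows averageable
across strands; a `--anchor left` flag preserves the literal
left-boundary alternative. Per-bin mass is normalized to CPM by the track
library size. Windows truncated at chromosome edges contribute zeros in the
missing bins, and loci on chromosomes absent from a track yield all-zero
rows (kept and logged) so aggregated profiles remain comparable across
tracks. The aggregate is the per-bin **mean** over loci (a sum mode is
available); replicate profiles are averaged element-wise before contrasts,
and a contrast is the difference of aggregated vectors (log2-ratio mode
optional).

## Peak–family enrichment

Merged peaks are assigned to the TE locus they overlap most, provided the
overlap covers ≥ `min_frac` (default 0.5, inclusive) of the peak; ties are
broken by smaller locus start then lexicographic locus id, making
assignment independent of input order. The expected per-family peak share
is proportional either to the family's **genomic span** (total bp) or to
its **locus count** — the right null is genuinely ambiguous, so the model
is a required argument rather than a default. Per family, a 1-df two-cell
chi-square (in-family vs out-of-family, no Yates correction) compares
observed and expected among **assigned** peaks (unassigned peaks are
excluded from the denominator; an all-peaks mode is a flag), with BH
adjustment across families and a `low_expected` flag when an expected cell
is below 5 (the result is still computed). Families are marked reported
when they carry at least `min_peaks` (default 5, inclusive) observed peaks.

A practical caveat verified on synthetic data: when peaks are dense
relative to locus capacity, the <50 bp merge step collapses multiple peaks
per locus and saturates per-family counts toward the number of occupied
loci, attenuating rate differences. Enrichment power statements therefore
assume peak sets that are sparse at the locus scale (as MACS2 output over a
genome is); the calibration and power simulations run on unmerged peaks.

## E-box motif analysis

The scanner matches the canonical E-box CA(C/T)GTG literally on both
strands: CACGTG (its own reverse complement) is reported once per position
on the + strand; CATGTG on the reverse strand appears as CACATG on the
forward sequence; N never matches. PWM scoring and de novo discovery are
out of scope — the biological question is presence of the canonical
hexamer. Summit windows are summit ± 25 bp (51 bp including the summit
base); absent summits fall back to the peak midpoint (floor); windows are
clamped at position 0. Presence is **binary per sequence** (loci are
counted "with" or "without" the motif; hit counts are emitted for
diagnostics), and bound-vs-unbound association is a 2×2 Pearson chi-square
without continuity correction. Both summit windows and whole-locus
sequences are accepted as input, since either convention is defensible.

## Downstream statistics

* **BH adjustment**: standard step-up (implemented via statsmodels
  `fdr_bh`), validated against an independent hand-written step-up oracle.
* **DEG filter**: kept iff padj < α (default 0.05, strict) and |log2FC| ≥ 1
  (**inclusive**, a flag exposes the strict reading); partitioned by sign.
* **Set overlap**: 2×2 chi-square (no correction) or two-sided Fisher exact
  over an **explicitly supplied universe** — there is no safe default
  universe, so omitting it is a hard error.
* **Spearman correlation**: mid-rank Pearson with the asymptotic-t p-value;
  constant input yields NaN with no exception.
* **Enhancer candidates**: a gene qualifies iff (i) it is significantly DE
  across invasion states with the configured reciprocal sign, (ii) it is
  significantly up with treatment, and (iii) a TF-bound locus of the target
  family lies within `neighborhood_bp` (default 10 000, edge-to-TSS,
  inclusive) of its TSS. The reported locus is the nearest qualifying one.
* **qPCR**: replicate CTs are averaged first; ΔCT = CT_target −
  CT_reference per sample; fold change = 2^−ΔΔCT.

## Synthetic data

The generators produce every input dialect the readers consume (BED6, GTF,
SAM with NH tags, bedGraph, narrowPeak, FASTA, TSV) from a single seeded
`numpy` Generator per call, with the planted parameters recorded in a
`TruthBundle`. Defaults emulate the study regime: a 3-chromosome genome,
4 repeat families × 50 loci of 300–1000 bp (one family labeled LTR5_Hs),
100 gene models, 50 000 reads of 100 bp with a 40% multi-mapping rate,
tracks with Gaussian bumps (height 5, sd 150 bp) at enriched-family
anchors over unit background with noise sd = height/10, 400 peaks with a
3× rate for the enriched family, motif presence probabilities 0.5 (bound)
vs 0.1 (unbound), and DE tables of 1000 genes with 100 true positives at
|log2FC| = 2 (alternative p ~ Beta(0.01, 1)).

Design choices inside the generators:

* Family proportions default to the fixed descending simplex
  (k, k−1, …, 1)/Σ rather than a random draw, so ranking-recovery
  properties are well separated at the stated read depth; within-family
  locus proportions are a seeded Dirichlet(5) draw.
* Placement of genes and loci is exact: free gaps are enumerated and a
  position is drawn uniformly over all feasible placements, so generation
  fails only when packing is truly infeasible. Genes are placed first and
  loci keep a 1.1 kb clearance from them, so the TSS/exon filter passes
  every planted locus through to quantification.
* Secondary alignments of multi-mapped reads are placed in loci drawn
  **uniformly** (same family, or a random other family with probability
  0.1), not abundance-weighted. This makes the reported-position ambiguity
  independent of the read's true origin, which is the regime in which the
  EM estimator is consistent; with abundance-weighted secondaries the EM
  target and the planted proportions differ by design, not by bug.
* The track is piecewise constant on a 25 bp grid with the bump evaluated
  at segment midpoints; at sd = 150 bp the midpoint-rule error of the bump
  mass is ≈ 0.5%, tested against the closed-form Gaussian integral at 1%.

What the synthetic data do **not** model: sequencing error, fragment-length
and GC bias, paired-end structure, mappability variation, copy-number
differences, and correlated biological replicates. Passing tests therefore
demonstrate the correctness and calibration of the computations, not
robustness to those real-data artifacts.

## Problem sizes used in tests and the acceptance script

Oracle-agreement checks run exhaustively (1000 reads against an all-pairs
assignment oracle; 100 random 10 kb sequences against a brute-force 6-mer
oracle; 50 random tables against hypergeometric enumeration). Simulation
studies use 200 replicates for null calibration of the enrichment test
(~800 family-level p-values), 100 replicates each for enrichment power and
DEG false-discovery control, and the stated 10-locus/50 000-read regime for
EM recovery. End-to-end family-ranking recovery is checked across 10
independent seeds at 50 000 reads. Full-workflow determinism is verified by
running `terk run` twice with one config and comparing output SHA-256
checksums.

## Known limitations

* The EM quantifier models alignments at the locus level (a candidate set
  per read); it does not model positional bias within loci or fragment
  length, and it reports counts, not TPM.
* The per-family chi-square treats families independently; counts across
  families are multinomially coupled, which slightly tightens the null
  beyond nominal in small annotations (verified acceptable by the
  calibration simulation).
* Literal E-box matching does not capture degenerate or flanking-context
  binding preferences.
* The enhancer-candidate caller is a screen, not a validation: it encodes
  three necessary criteria and inherits the DEG filter's thresholds.
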