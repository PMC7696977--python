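"""Interval algebra, annotation readers and repeat-locus filtering."""

import numpy as np
import pytest

from terk.intervals import (
    AnnotationFormatError,
    GenomicInterval,
    TELocus,
    filter_te_loci,
    load_gene_models,
    load_repeat_annotation,
    merge_intervals,
    overlap_fraction,
    write_bed,
)
from terk.simulate import make_annotation

from conftest import random_intervals


class TestGenomicInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "x")

    def test_overlap_fraction_examples(self):
        a = GenomicInterval("chr1", 0, 200)
        b = GenomicInterval("chr1", 100, 400)
        assert overlap_fraction(a, b) == 0.5
        assert overlap_fraction(GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)) == 0
        inner = GenomicInterval("chr1", 150, 250)
        assert overlap_fraction(inner, b) == 1.0
        assert overlap_fraction(a, GenomicInterval("chr2", 0, 200)) == 0

    def test_overlap_bp_symmetric_identity(self):
        rng = np.random.default_rng(0)
        for a, b in zip(random_intervals(rng, 50), random_intervals(rng, 50)):
            assert overlap_fraction(a, b) * a.length == pytest.approx(
                overlap_fraction(b, a) * b.length
            )


class TestRepeatReader:
    def test_bed6_line(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t1068\tLTR5_Hs\t0\t+\n")
        (locus,) = load_repeat_annotation(str(p))
        assert locus.family == "LTR5_Hs"
        assert locus.length_bp == 968
        assert locus.interval.strand == "+"
        assert locus.locus_id == "chr1:100-1068:LTR5_Hs"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert load_repeat_annotation(str(p)) == []

    def test_rmsk_fixture_matches_hand_parse(self, tmp_path):
        header = "\t".join(
            ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]
        )
        rows = [
            "chr1\t1000\t1950\t+\tLTR5_Hs\tLTR\tERVK",
            "chr1\t5000\t5400\tC\tAluY\tSINE\tAlu",
            "chr2\t300\t900\t-\tL1HS\tLINE\tL1",
        ]
        p = tmp_path / "rmsk.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        loci = load_repeat_annotation(str(p))
        # hand parse of the same three rows
        expected = [
            ("chr1", 1000, 1950, "+", "LTR5_Hs", "LTR"),
            ("chr1", 5000, 5400, "-", "AluY", "SINE"),  # rmsk C strand = minus
            ("chr2", 300, 900, "-", "L1HS", "LINE"),
        ]
        assert [
            (l.interval.chrom, l.interval.start, l.interval.end, l.interval.strand,
             l.family, l.class_name)
            for l in loci
        ] == expected

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\tA\n" + "chr1\tnope\t300\tB\n")
        with pytest.raises(AnnotationFormatError, match="line 2"):
            load_repeat_annotation(str(p))

    def test_bed_round_trip(self, tmp_path):
        ann, _ = make_annotation(5, n_chroms=2, chrom_len=100_000, loci_per_family=10, n_genes=5)
        p = tmp_path / "loci.bed"
        write_bed(ann.te_loci, str(p))
        reloaded = load_repeat_annotation(str(p))
        assert [(l.locus_id, l.interval) for l in reloaded] == [
            (l.locus_id, l.interval) for l in ann.te_loci
        ]


class TestGeneReader:
    GTF = (
        'chr1\tsrc\texon\t1000\t1200\t.\t{s}\t.\tgene_id "g1"; transcript_id "g1.t";\n'
        'chr1\tsrc\texon\t1500\t1800\t.\t{s}\t.\tgene_id "g1"; transcript_id "g1.t";\n'
    )

    def test_plus_strand_tss(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(self.GTF.format(s="+"))
        (gene,) = load_gene_models(str(p))
        assert gene.tss_position == 999  # GTF 1-based 1000 -> 0-based 999
        assert gene.exons[0].start == 999 and gene.exons[0].end == 1200

    def test_minus_strand_tss(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(self.GTF.format(s="-"))
        (gene,) = load_gene_models(str(p))
        assert gene.tss_position == 1799  # 0-based last base of the 3'-most exon

    def test_missing_gene_id_errors(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\texon\t10\t20\t.\t+\t.\ttranscript_id "t";\n')
        with pytest.raises(AnnotationFormatError, match="gene_id"):
            load_gene_models(str(p))

    def test_multi_gene_fixture_matches_hand_parse(self, tmp_path):
        lines = []
        expected = {}
        for i, (start, strand) in enumerate([(11, "+"), (501, "-"), (901, "+"), (2001, "-"), (5001, "+")]):
            gid = f"g{i}"
            lines.append(
                f'chr1\tsrc\texon\t{start}\t{start + 99}\t.\t{strand}\t.\tgene_id "{gid}";\n'
            )
            lines.append(
                f'chr1\tsrc\texon\t{start + 200}\t{start + 299}\t.\t{strand}\t.\tgene_id "{gid}";\n'
            )
            expected[gid] = start - 1 if strand == "+" else start + 299 - 1
        p = tmp_path / "five.gtf"
        p.write_text("".join(lines))
        genes = load_gene_models(str(p))
        assert {g.gene_id: g.tss_position for g in genes} == expected


class TestMergeIntervals:
    def test_gap_boundary(self):
        a, b = GenomicInterval("c", 100, 200), GenomicInterval("c", 249, 300)
        assert merge_intervals([a, b]) == [GenomicInterval("c", 100, 300)]
        c = GenomicInterval("c", 250, 300)  # gap exactly 50: stays separate
        assert len(merge_intervals([a, c])) == 2

    def test_empty(self):
        assert merge_intervals([]) == []

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        intervals = random_intervals(rng, 500)
        got = merge_intervals(intervals, 50)

        # O(n^2) oracle: repeatedly fuse any mergeable pair
        pool = [[iv.chrom, iv.start, iv.end] for iv in intervals]
        changed = True
        while changed:
            changed = False
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    a, b = pool[i], pool[j]
                    if a[0] == b[0] and max(a[1], b[1]) - min(a[2], b[2]) < 50:
                        a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                        pool.pop(j)
                        changed = True
                        break
                if changed:
                    break
        oracle = sorted((c, s, e) for c, s, e in pool)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == oracle

    def test_idempotent_and_gap_invariant(self):
        rng = np.random.default_rng(2)
        merged = merge_intervals(random_intervals(rng, 300), 50)
        assert merge_intervals(merged, 50) == merged
        by_chrom = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end >= 50


class TestFilterTeLoci:
    @staticmethod
    def _gene(chrom, exon_spans, strand="+", gid="g"):
        from terk.intervals import GeneModel

        exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans)
        tss_pos = exons[0].start if strand == "+" else exons[-1].end - 1
        return GeneModel(gid, GenomicInterval(chrom, tss_pos, tss_pos + 1, strand), exons, (), strand)

    def test_exonic_locus_removed(self):
        locus = TELocus(GenomicInterval("c", 1100, 1150), "A")
        gene = self._gene("c", [(1000, 1200)])
        assert filter_te_loci([locus], [gene]) == []

    def test_tss_boundary_inclusive(self):
        gene = self._gene("c", [(10_000, 10_200)])  # TSS at 10_000
        at_1000 = TELocus(GenomicInterval("c", 8500, 9001), "A")  # edge 9000, distance 1000
        at_1001 = TELocus(GenomicInterval("c", 8500, 9000), "A")  # edge 8999, distance 1001
        assert filter_te_loci([at_1000], [gene]) == []
        assert filter_te_loci([at_1001], [gene]) == [at_1001]

    def test_negative_exclusion_rejected(self):
        with pytest.raises(ValueError):
            filter_te_loci([], [], tss_exclusion_bp=-1)

    def test_matches_brute_force_oracle_and_order(self):
        rng = np.random.default_rng(3)
        loci = []
        for i in range(200):
            start = int(rng.integers(0, 80_000))
            loci.append(
                TELocus(GenomicInterval(str(rng.choice(["chr1", "chr2"])), start,
                                        start + int(rng.integers(50, 800))), "F", locus_id=f"L{i}")
            )
        genes = []
        for i in range(20):
            start = int(rng.integers(0, 80_000))
            genes.append(
                self._gene(str(rng.choice(["chr1", "chr2"])),
                           [(start, start + 300), (start + 800, start + 1100)],
                           strand=str(rng.choice(["+", "-"])), gid=f"g{i}")
            )
        got = filter_te_loci(loci, genes, 1000)

        def oracle_keep(locus):
            iv = locus.interval
            for gene in genes:
                for ex in gene.exons:
                    if iv.chrom == ex.chrom and iv.start < ex.end and ex.start < iv.end:
                        return False
                t = gene.tss_position
                if iv.chrom == gene.tss.chrom:
                    d = 0 if iv.start <= t < iv.end else min(abs(iv.start - t), abs(t - (iv.end - 1)))
                    if d <= 1000:
                        return False
            return True

        oracle = [l for l in loci if oracle_keep(l)]
        assert [l.locus_id for l in got] == [l.locus_id for l in oracle]

        # survivor SET invariant under permutation of inputs
        perm = list(rng.permutation(len(loci)))
        got_perm = filter_te_loci([loci[i] for i in perm], genes[::-1], 1000)
        assert {l.locus_id for l in got_perm} == {l.locus_id for l in got}
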