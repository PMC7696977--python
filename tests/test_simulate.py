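"""Determinism and planted-truth fidelity of the synthetic generators."""

import math

import numpy as np
import pytest

from terk.motifs import SequenceRecord, has_ebox
from terk.quant import family_counts, group_by_read
from terk.simulate import (
    make_annotation,
    make_integration_fixture,
    simulate_alignments,
    simulate_de_table,
    simulate_peaks,
    simulate_sequences,
    simulate_track,
)


class TestMakeAnnotation:
    def test_deterministic_per_seed(self):
        a1, t1 = make_annotation(5, n_chroms=2, chrom_len=100_000, loci_per_family=10, n_genes=10)
        a2, t2 = make_annotation(5, n_chroms=2, chrom_len=100_000, loci_per_family=10, n_genes=10)
        assert [l.locus_id for l in a1.te_loci] == [l.locus_id for l in a2.te_loci]
        assert t1.locus_proportions == t2.locus_proportions
        assert [g.tss_position for g in a1.genes] == [g.tss_position for g in a2.genes]

    def test_locus_count_and_single_family(self):
        ann, _ = make_annotation(6, n_chroms=2, chrom_len=150_000, families=3,
                                 loci_per_family=12, n_genes=5)
        assert len(ann.te_loci) == 36
        ann1, _ = make_annotation(6, n_chroms=1, chrom_len=100_000, families=1,
                                  loci_per_family=8, n_genes=3)
        assert {l.family for l in ann1.te_loci} == {"LTR5_Hs"}

    def test_loci_disjoint_and_inside_chromosomes(self):
        ann, _ = make_annotation(7, n_chroms=2, chrom_len=120_000, loci_per_family=15, n_genes=10)
        by_chrom = {}
        for l in ann.te_loci:
            iv = l.interval
            assert 0 <= iv.start < iv.end <= ann.chrom_sizes[iv.chrom]
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            make_annotation(1, n_chroms=1, chrom_len=5_000, families=4,
                            loci_per_family=50, n_genes=100)

    def test_proportions_normalized(self):
        _, truth = make_annotation(8, n_chroms=2, chrom_len=100_000, loci_per_family=10, n_genes=5)
        assert sum(truth.family_proportions.values()) == pytest.approx(1.0)
        for props in truth.locus_proportions.values():
            assert sum(props.values()) == pytest.approx(1.0)


class TestSimulateAlignments:
    def test_multimap_rate_zero_all_unique(self, small_annotation):
        ann, truth = small_annotation
        recs = simulate_alignments(ann, truth, n_reads=500, multimap_rate=0.0, seed=1)
        assert all(r.hit_count == 1 for r in recs)
        assert len(recs) == 500

    def test_same_seed_identical_stream(self, small_annotation):
        ann, truth = small_annotation
        a = simulate_alignments(ann, truth, n_reads=300, seed=2)
        b = simulate_alignments(ann, truth, n_reads=300, seed=2)
        assert a == b
        c = simulate_alignments(ann, truth, n_reads=300, seed=3)
        assert a != c

    def test_hit_count_consistency(self, small_annotation):
        ann, truth = small_annotation
        recs = simulate_alignments(ann, truth, n_reads=400, seed=4)
        for records in group_by_read(recs).values():
            counts = {r.hit_count for r in records}
            assert len(counts) == 1
            assert len(records) == counts.pop()

    def test_unique_read_family_shares_within_multinomial_band(self, small_annotation):
        ann, truth = small_annotation
        n = 50_000
        recs = simulate_alignments(ann, truth, n_reads=n, multimap_rate=0.0, seed=5)
        fc = family_counts(recs, ann.te_loci, n)
        for fam, p in truth.family_proportions.items():
            sd = math.sqrt(n * p * (1 - p))
            assert abs(fc.counts[fam] - n * p) < 3 * sd


class TestSimulateTrack:
    def _ann(self):
        return make_annotation(9, n_chroms=2, chrom_len=80_000, families=2,
                               loci_per_family=10, n_genes=4)

    def test_zero_bump_and_noise_is_flat(self):
        ann, truth = self._ann()
        truth.profile_bump_height = 0.0
        track = simulate_track(ann, truth, noise_sd=0.0, background=2.0, seed=1)
        for starts, ends, values in track.segments.values():
            assert np.allclose(values, 2.0)

    def test_deterministic(self):
        ann, truth = self._ann()
        t1 = simulate_track(ann, truth, seed=2)
        t2 = simulate_track(ann, truth, seed=2)
        for chrom in t1.segments:
            np.testing.assert_array_equal(t1.segments[chrom][2], t2.segments[chrom][2])

    def test_bump_mass_matches_gaussian_integral(self):
        ann, truth = self._ann()
        truth.profile_bump_height, truth.profile_bump_sd = 4.0, 150.0
        track = simulate_track(ann, truth, noise_sd=0.0, background=0.0, seed=3)
        total = sum(
            float(((ends - starts) * values).sum())
            for starts, ends, values in track.segments.values()
        )
        n_anchors = len(ann.loci_of_family(truth.enriched_family))
        expected = n_anchors * 4.0 * 150.0 * math.sqrt(2 * math.pi)
        assert total == pytest.approx(expected, rel=0.01)


class TestSimulatePeaks:
    def test_deterministic_and_inside_te(self):
        ann, truth = make_annotation(10, n_chroms=2, chrom_len=100_000,
                                     loci_per_family=10, n_genes=4)
        p1 = simulate_peaks(ann, truth, 100, seed=1)
        p2 = simulate_peaks(ann, truth, 100, seed=1)
        assert p1 == p2
        starts = {(l.interval.chrom, l.interval.start, l.interval.end) for l in ann.te_loci}
        for p in p1:
            assert any(
                c == p.interval.chrom and s <= p.interval.start and p.interval.end <= e
                for c, s, e in starts
            )

    def test_fold_one_is_uniform_over_te_bp(self):
        ann, truth = make_annotation(11, n_chroms=2, chrom_len=150_000, families=2,
                                     loci_per_family=20, n_genes=4)
        truth.enrichment_fold = 1.0
        peaks = simulate_peaks(ann, truth, 4000, seed=2)
        spans = {}
        counts = {}
        by_key = {}
        for l in ann.te_loci:
            spans[l.family] = spans.get(l.family, 0) + l.length_bp
            by_key[(l.interval.chrom, l.interval.start, l.interval.end)] = l.family
        for p in peaks:
            fam = next(f for (c, s, e), f in by_key.items()
                       if c == p.interval.chrom and s <= p.interval.start and p.interval.end <= e)
            counts[fam] = counts.get(fam, 0) + 1
        total_span = sum(spans.values())
        for fam, c in counts.items():
            expect = 4000 * spans[fam] / total_span
            assert abs(c - expect) < 4 * math.sqrt(expect)


class TestSimulateSequences:
    def test_planted_presence_extremes(self):
        ann, truth = make_annotation(12, n_chroms=2, chrom_len=80_000, families=2,
                                     loci_per_family=12, n_genes=4)
        truth.motif_presence_probs = (1.0, 0.0)
        chroms = simulate_sequences(ann, truth, seed=4)
        bound = set(truth.bound_locus_ids)
        for locus in ann.loci_of_family("LTR5_Hs"):
            iv = locus.interval
            seq = chroms[iv.chrom][iv.start : iv.end]
            if locus.locus_id in bound:
                assert has_ebox(SequenceRecord(locus.locus_id, seq))

    def test_deterministic(self):
        ann, truth = make_annotation(13, n_chroms=1, chrom_len=60_000, families=1,
                                     loci_per_family=5, n_genes=2)
        assert simulate_sequences(ann, truth, seed=5) == simulate_sequences(ann, truth, seed=5)

    def test_background_motif_rate_near_closed_form(self):
        ann, truth = make_annotation(14, n_chroms=2, chrom_len=100_000, families=1,
                                     loci_per_family=4, n_genes=2)
        truth.motif_presence_probs = (0.0, 0.0)
        chroms = simulate_sequences(ann, truth, seed=6)
        n_hits = sum(
            len([1 for i in range(len(seq) - 5)
                 if seq[i:i + 6] in ("CACGTG", "CATGTG", "CACATG")])
            for seq in chroms.values()
        )
        n_positions = sum(len(s) - 5 for s in chroms.values())
        rate = 3 / 4**6  # three distinct forward words of the strand-pair classes
        expect = n_positions * rate
        assert abs(n_hits - expect) < 4 * math.sqrt(expect)


class TestSimulateDeTable:
    def test_deterministic_and_counts(self):
        r1, t1 = simulate_de_table(seed=7)
        r2, t2 = simulate_de_table(seed=7)
        assert [(a.gene_id, a.pvalue, a.log2fc) for a in r1] == [
            (b.gene_id, b.pvalue, b.log2fc) for b in r2
        ]
        assert len(t1.true_deg_ids) == 100 and len(r1) == 1000

    def test_null_table_controls_type_one(self):
        from terk.expression import deg_filter

        discoveries = 0
        for seed in range(50):
            records, _ = simulate_de_table(n_genes=400, n_true=0, seed=seed)
            up, down = deg_filter(records)
            discoveries += len(up) + len(down)
        assert discoveries <= 3  # ~0 expected under BH at alpha 0.05

    def test_planted_genes_rank_first_by_p(self):
        records, truth = simulate_de_table(n_genes=1000, n_true=100, seed=8)
        order = sorted(records, key=lambda r: r.pvalue)
        top = {r.gene_id for r in order[:100]}
        assert len(top & set(truth.true_deg_ids)) >= 80


class TestEndToEndRecovery:
    def test_family_ranking_recovered_across_seeds(self, small_annotation):
        ann, truth = small_annotation
        true_order = sorted(truth.family_proportions,
                            key=truth.family_proportions.get, reverse=True)
        hits = 0
        for seed in range(10):
            recs = simulate_alignments(ann, truth, n_reads=50_000, seed=100 + seed)
            fc = family_counts(recs, ann.te_loci, 50_000)
            order = sorted(fc.counts, key=fc.counts.get, reverse=True)
            hits += order == true_order
        assert hits == 10


class TestIntegrationFixture:
    def test_deterministic_and_consistent(self):
        kw = dict(n_chroms=3, chrom_len=200_000, families=3, loci_per_family=25, n_genes=50)
        a = make_integration_fixture(3, **kw)
        b = make_integration_fixture(3, **kw)
        assert a[4].true_candidate_gene_ids == b[4].true_candidate_gene_ids
        assert a[3] == b[3]
        ann, de_t, de_s, bound, truth = a
        assert len(truth.true_candidate_gene_ids) == 3
        assert bound <= {l.locus_id for l in ann.loci_of_family("LTR5_Hs")}
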