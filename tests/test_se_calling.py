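import numpy as np
import pandas as pd
import pytest

from secircuit.core import GeneSignature, TSSTable
from secircuit.se_calling import (
    SuperEnhancerCaller,
    build_te_control_signature,
    exclude_promoter_peaks,
    hockey_stick_cutoff,
    map_genes,
    quantify_signal,
    rank_and_classify,
    stitch_peaks,
)
from conftest import make_peak, random_peaks
from oracles import count_below_line_cutoff, transitive_merge


def tss_table(entries):
    frame = pd.DataFrame(
        [(g, c, t, s) for g, c, t, s in entries],
        columns=["gene", "chrom", "tss", "strand"],
    ).set_index("gene")
    return TSSTable(frame)


class TestPromoterExclusion:
    TSS = [("G1", "chr1", 100_000, "+")]

    def test_midpoint_inside_window_removed(self):
        peaks = [make_peak("chr1", 99_000, 101_000)]  # midpoint exactly at TSS
        assert exclude_promoter_peaks(peaks, tss_table(self.TSS)) == []

    def test_midpoint_outside_window_kept(self):
        peaks = [make_peak("chr1", 104_000, 105_000)]  # midpoint 104500, 4.5 kb away
        assert len(exclude_promoter_peaks(peaks, tss_table(self.TSS))) == 1

    def test_boundary_is_inclusive(self):
        inside = [make_peak("chr1", 102_000, 103_000)]   # midpoint 102500 == +2.5 kb
        outside = [make_peak("chr1", 102_001, 103_001)]  # midpoint 102501
        assert exclude_promoter_peaks(inside, tss_table(self.TSS)) == []
        assert len(exclude_promoter_peaks(outside, tss_table(self.TSS))) == 1

    def test_matches_all_pairs_brute_force(self, rng):
        entries = [
            (f"G{i}", "chr1", int(rng.integers(0, 500_000)), "+") for i in range(20)
        ]
        tss = tss_table(entries)
        peaks = random_peaks(rng, 100, genome=500_000, chroms=("chr1",))
        got = exclude_promoter_peaks(peaks, tss, flank=2_500)
        expected = [
            p for p in peaks
            if all(abs(p.interval.midpoint - t) > 2_500 for _, _, t, _ in entries)
        ]
        assert got == expected

    def test_empty_tss_rejected(self):
        empty = TSSTable(pd.DataFrame(columns=["chrom", "tss", "strand"]))
        with pytest.raises(ValueError):
            exclude_promoter_peaks([make_peak("chr1", 0, 100)], empty)


class TestStitching:
    def test_gap_within_distance_merges(self):
        merged = stitch_peaks([make_peak("chr1", 0, 1_000), make_peak("chr1", 5_000, 6_000)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 6_000)
        assert merged[0].num_constituents == 2

    def test_exact_stitch_distance_is_inclusive(self):
        at = stitch_peaks([make_peak("chr1", 0, 100), make_peak("chr1", 12_600, 12_700)])
        beyond = stitch_peaks([make_peak("chr1", 0, 100), make_peak("chr1", 12_601, 12_701)])
        assert len(at) == 1
        assert len(beyond) == 2

    def test_different_chromosomes_never_merge(self):
        merged = stitch_peaks([make_peak("chr1", 0, 100), make_peak("chr2", 50, 150)])
        assert len(merged) == 2

    def test_idempotent_and_order_invariant(self, rng):
        peaks = random_peaks(rng, 50)
        a = stitch_peaks(peaks)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        b = stitch_peaks(shuffled)
        key = lambda es: [(e.interval.chrom, e.interval.start, e.interval.end) for e in es]
        assert key(a) == key(b)
        restitched = stitch_peaks(
            [p for e in a for p in e.constituents], stitch_distance=12_500
        )
        assert key(restitched) == key(a)

    def test_matches_transitive_merge_oracle(self, rng):
        for _ in range(60):
            peaks = random_peaks(rng, int(rng.integers(2, 40)), genome=300_000)
            gap = int(rng.integers(0, 20_000))
            got = [
                (e.interval.chrom, e.interval.start, e.interval.end)
                for e in stitch_peaks(peaks, stitch_distance=gap)
            ]
            expected = transitive_merge(
                [(p.interval.chrom, p.interval.start, p.interval.end) for p in peaks],
                gap,
            )
            assert sorted(got) == expected


class TestSignal:
    def test_background_subtracted_times_length(self):
        e = stitch_peaks([make_peak("chr1", 0, 1_000, density=2.0, input_density=0.5)])[0]
        assert quantify_signal(e) == pytest.approx(1_500.0)

    def test_input_above_sample_clamps_to_zero(self):
        e = stitch_peaks([make_peak("chr1", 0, 1_000, density=0.2, input_density=0.9)])[0]
        assert quantify_signal(e) == 0.0

    def test_additive_over_constituents(self):
        e = stitch_peaks([
            make_peak("chr1", 0, 1_000, density=2.0, input_density=0.5),
            make_peak("chr1", 2_000, 2_500, density=1.0),
        ])[0]
        assert quantify_signal(e) == pytest.approx(1_500.0 + 500.0)


class TestHockeyStick:
    def test_flat_curve_has_zero_super(self):
        cutoff, rank = hockey_stick_cutoff([3.0] * 10)
        assert cutoff == 3.0 and rank == 10

    def test_single_outlier_is_the_only_super(self):
        signals = list(range(1, 10)) + [200]
        cutoff, rank = hockey_stick_cutoff(signals)
        assert cutoff == count_below_line_cutoff(signals)[0]
        assert sum(s > cutoff for s in signals) == 1

    def test_scale_invariance(self, rng):
        signals = rng.exponential(5.0, size=400)
        _, rank = hockey_stick_cutoff(signals)
        for factor in (0.001, 7.3, 1e6):
            assert hockey_stick_cutoff(signals * factor)[1] == rank

    def test_matches_count_below_line_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 300))
            signals = rng.exponential(1.0, size=n) ** rng.uniform(0.5, 3.0)
            assert hockey_stick_cutoff(signals) == count_below_line_cutoff(signals)

    def test_too_few_signals_rejected(self):
        with pytest.raises(ValueError):
            hockey_stick_cutoff([1.0])


class TestGeneMapping:
    def _classified(self, enhancer_specs):
        enhancers = []
        for start, end, density, is_super in enhancer_specs:
            e = stitch_peaks([make_peak("chr1", start, end, density=density)])[0]
            e.is_super = is_super
            enhancers.append(e)
        return enhancers

    def test_tss_inside_interval_assigned(self):
        enh = self._classified([(100_000, 110_000, 5.0, True)])
        tss = tss_table([("IN", "chr1", 105_000, "+")])
        _, se_genes, _ = map_genes(enh, tss)
        assert se_genes == {"IN"}

    def test_window_convention(self):
        enh = self._classified([(100_000, 110_000, 5.0, True)])
        tss = tss_table([
            ("NEAR", "chr1", 110_000 - 1 + 49_999, "+"),
            ("FAR", "chr1", 110_000 - 1 + 50_001, "+"),
        ])
        _, se_genes, _ = map_genes(enh, tss, window=50_000)
        assert se_genes == {"NEAR"}

    def test_overlap_mode_requires_tss_inside(self):
        enh = self._classified([(100_000, 110_000, 5.0, True)])
        tss = tss_table([("OUT", "chr1", 112_000, "+"), ("IN", "chr1", 101_000, "+")])
        _, se_genes, _ = map_genes(enh, tss, assignment="overlap")
        assert se_genes == {"IN"}

    def test_te_ranking_excludes_se_genes_and_sorts_ascending(self):
        enh = self._classified([
            (0, 1_000, 9.0, True),         # SE near SHARED
            (100_000, 101_000, 1.0, False),  # weak TE near A
            (300_000, 301_000, 3.0, False),  # stronger TE near B and SHARED
        ])
        tss = tss_table([
            ("SHARED", "chr1", 500, "+"),
            ("A", "chr1", 100_500, "+"),
            ("B", "chr1", 300_500, "+"),
        ])
        _, se_genes, te_ranked = map_genes(enh, tss, window=50_000)
        assert se_genes == {"SHARED"}
        assert te_ranked == [("A", 1_000.0), ("B", 3_000.0)]

    def test_matches_all_pairs_distance_oracle(self, rng):
        peaks = random_peaks(rng, 40, genome=2_000_000, chroms=("chr1",))
        enhancers = stitch_peaks(peaks)
        rank_and_classify(enhancers)
        entries = [
            (f"G{i}", "chr1", int(rng.integers(0, 2_000_000)), "+") for i in range(60)
        ]
        per_enh, se_genes, _ = map_genes(enhancers, tss_table(entries), window=50_000)
        for e, genes in zip(enhancers, per_enh):
            expected = {
                g for g, _, t, _ in entries
                if e.interval.start - 50_000 <= t <= e.interval.end - 1 + 50_000
            }
            assert set(genes) == expected


class TestTEControl:
    def test_bottom_k_by_signal(self):
        te = [("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 4.0)]
        sig = build_te_control_signature({"X", "Y"}, te)
        assert sig.genes == {"A", "B"}

    def test_short_te_list_returns_all_with_warning(self, caplog):
        sig = build_te_control_signature({"X", "Y", "Z"}, [("A", 1.0)])
        assert sig.genes == {"A"}
        assert any("TE genes" in r.message for r in caplog.records)


class TestCallerEstimator:
    def test_sklearn_param_interface(self):
        caller = SuperEnhancerCaller(stitch_distance=10_000)
        assert caller.get_params()["stitch_distance"] == 10_000
        caller.set_params(gene_window=25_000)
        assert caller.gene_window == 25_000

    def test_input_order_does_not_change_result(self, study, rng):
        peaks = list(study.chipseq["LINE2"])
        caller = SuperEnhancerCaller()
        a = caller.fit(peaks, tss_table=study.annotation)
        se_a, cutoff_a = set(a.se_genes_), a.cutoff_signal_
        rng.shuffle(peaks)
        b = SuperEnhancerCaller().fit(peaks, tss_table=study.annotation)
        assert set(b.se_genes_) == se_a
        assert b.cutoff_signal_ == cutoff_a

    def test_ranks_are_permutation_and_classes_partition(self, study):
        caller = SuperEnhancerCaller().fit(
            study.chipseq["LINE1"], tss_table=study.annotation
        )
        ranks = sorted(e.rank for e in caller.enhancers_)
        assert ranks == list(range(1, len(caller.enhancers_) + 1))
        n_se = sum(e.is_super for e in caller.enhancers_)
        assert 0 <= n_se <= len(caller.enhancers_)
        for e in caller.enhancers_:
            assert e.is_super == (e.signal > caller.cutoff_signal_)

    def test_te_control_disjoint_from_se_genes(self, study):
        caller = SuperEnhancerCaller().fit(
            study.chipseq["LINE1"], tss_table=study.annotation
        )
        control = caller.te_control_signature()
        assert control.genes.isdisjoint(caller.se_genes_)
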