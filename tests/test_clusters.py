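"""Clustering, proximity statistics, and the binomial placement null."""

import math

import numpy as np
import pytest
from scipy import stats

from nucrnai.calls import RegionCall
from nucrnai.clusters import (
    annotate_clusters,
    binomial_proximity_null,
    binomial_proximity_pvalue,
    cluster_calls,
    proximity_curve,
    proximity_fraction,
    _hit_start_span,
)
from nucrnai.genome import Bin, GenomeModel, GenomicInterval


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def calls_at(intervals):
    return [
        RegionCall(Bin(x, i), "GRTS", 3.0, {"polII_S2": 5.0})
        for i, x in enumerate(intervals)
    ]


class TestClustering:
    def test_hand_enumerated_clusters(self):
        res = cluster_calls(
            calls_at([iv("chrI", 0, 1000), iv("chrI", 2000, 3000), iv("chrI", 20000, 21000)]),
            max_gap=5000,
        )
        assert res.n_clusters == 2
        assert res.n_loci_in_multi == 2
        assert res.clustered_fraction == pytest.approx(2 / 3)

    def test_single_locus_is_unclustered_singleton(self):
        res = cluster_calls(calls_at([iv("chrI", 0, 1000)]))
        assert res.n_clusters == 1
        assert res.clustered_fraction == 0.0

    def test_member_bookkeeping_conserves_loci(self):
        rng = np.random.default_rng(3)
        ivs = [
            iv("chrI", s, s + 1000)
            for s in sorted(set(rng.integers(0, 500, 40) * 1000))
        ]
        res = cluster_calls(calls_at(ivs), max_gap=5000)
        assert sum(c.n_members for c in res.clusters) == len(ivs)

    def test_large_cluster_counting(self):
        ivs = [iv("chrI", i * 1000, (i + 1) * 1000) for i in range(12)]
        ivs += [iv("chrII", 0, 1000)]
        res = cluster_calls(calls_at(ivs), max_gap=5000, large_threshold_bp=10000)
        assert res.n_large == 1


class TestProximityFraction:
    def test_overlap_counting_at_cutoff_zero(self):
        q = [iv("chrI", i * 10_000, i * 10_000 + 1000) for i in range(4)]
        ref = [iv("chrI", 500, 700)]
        assert proximity_fraction(q, ref, 0) == pytest.approx(0.25)

    def test_infinite_cutoff_on_shared_chromosome(self):
        q = [iv("chrI", 0, 1000), iv("chrI", 900_000, 901_000)]
        ref = [iv("chrI", 500_000, 501_000)]
        assert proximity_fraction(q, ref, math.inf) == 1.0

    def test_empty_query_rejected_empty_reference_warns(self):
        with pytest.raises(ValueError, match="empty query"):
            proximity_fraction([], [iv("chrI", 0, 10)], 0)
        with pytest.warns(UserWarning):
            assert proximity_fraction([iv("chrI", 0, 10)], [], 0) == 0.0

    def test_non_decreasing_in_cutoff(self):
        rng = np.random.default_rng(5)
        q = [iv("chrI", int(s), int(s) + 1000) for s in rng.integers(0, 400_000, 30)]
        ref = [iv("chrI", int(s), int(s) + 1000) for s in rng.integers(0, 400_000, 10)]
        fracs = [proximity_fraction(q, ref, c) for c in range(0, 50_000, 2_000)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestBinomialNull:
    def brute_force_p_hit(self, genome, ref, cutoff, w):
        """Oracle: enumerate every valid start and test the distance rule."""
        hits = valid = 0
        for name, length in genome.chromosomes:
            starts = np.arange(0, length - w + 1)
            valid += len(starts)
            d = np.full(len(starts), np.inf)
            for r in ref:
                if r.chrom != name:
                    continue
                gap = np.maximum(0, np.maximum(r.start - (starts + w), starts - r.end))
                d = np.minimum(d, gap)
            hits += int(np.sum(d <= cutoff))
        return hits, valid

    def test_exact_span_matches_enumeration(self):
        genome = GenomeModel([("chrI", 1_000_000)])
        ref = [iv("chrI", 200_000, 210_000)]
        got = _hit_start_span(ref, genome, 0, 1000)
        assert got == self.brute_force_p_hit(genome, ref, 0, 1000)
        # 10-kb reference, 1-kb query: starts a-w-0 .. b+0 inclusive
        assert got[0] == 10_000 + 1000 + 1
        assert got[1] == 1_000_000 - 999

    def test_exact_span_with_cutoff_and_overlapping_refs(self):
        genome = GenomeModel([("chrI", 100_000), ("chrII", 50_000)])
        ref = [
            iv("chrI", 10_000, 12_000),
            iv("chrI", 11_000, 15_000),
            iv("chrI", 16_000, 16_500),
            iv("chrII", 0, 2_000),
        ]
        for cutoff in (0, 500, 5_000):
            assert _hit_start_span(ref, genome, cutoff, 1000) == (
                self.brute_force_p_hit(genome, ref, cutoff, 1000)
            )

    def test_min_fraction_from_exact_binomial_tail(self):
        genome = GenomeModel([("chrI", 1_000_000)])
        # reference sized so that p_hit ~ 0.1; then force the textbook case
        null = binomial_proximity_null(
            10, [iv("chrI", 400_000, 498_901)], genome, 0, alpha=0.05
        )
        assert null.p_hit == pytest.approx(0.1, abs=1e-3)
        # with p=0.1, n=10: P(X>=4)=0.0128 <= 0.05 < P(X>=3)=0.0702
        assert stats.binom.sf(3, 10, 0.1) == pytest.approx(0.0128, abs=1e-4)
        assert stats.binom.sf(2, 10, 0.1) == pytest.approx(0.0702, abs=1e-4)
        assert null.min_count_to_reject == 4
        assert null.min_fraction_to_reject == pytest.approx(0.4)

    def test_exact_tail_matches_monte_carlo(self):
        rng = np.random.default_rng(17)
        genome = GenomeModel([("chrI", 120_000)])
        ref = [iv("chrI", 30_000, 33_000), iv("chrI", 80_000, 81_000)]
        cutoff, w, n_mc = 2_000, 1000, 100_000
        hits, valid = _hit_start_span(ref, genome, cutoff, w)
        p = hits / valid
        starts = rng.integers(0, valid, n_mc)
        d = np.full(n_mc, np.inf)
        for r in ref:
            gap = np.maximum(0, np.maximum(r.start - (starts + w), starts - r.end))
            d = np.minimum(d, gap)
        p_mc = np.mean(d <= cutoff)
        se = math.sqrt(p * (1 - p) / n_mc)
        assert abs(p_mc - p) <= 3 * se

    def test_rejection_rate_calibrated_under_uniform_placement(self):
        rng = np.random.default_rng(23)
        genome = GenomeModel([("chrI", 200_000)])
        ref = [iv("chrI", 50_000, 60_000), iv("chrI", 150_000, 152_000)]
        alpha, n_query, w = 0.05, 30, 1000
        null = binomial_proximity_null(n_query, ref, genome, 1_000, alpha, w)
        hits, valid = _hit_start_span(ref, genome, 1_000, w)
        rejections = 0
        trials = 400
        for _ in range(trials):
            starts = rng.integers(0, valid, n_query)
            d = np.full(n_query, np.inf)
            for r in ref:
                gap = np.maximum(0, np.maximum(r.start - (starts + w), starts - r.end))
                d = np.minimum(d, gap)
            if np.mean(d <= 1_000) >= null.min_fraction_to_reject:
                rejections += 1
        rate = rejections / trials
        # discrete threshold is conservative: rate <= alpha (+3 SE slack)
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / trials)

    def test_clustered_query_rejects(self):
        genome = GenomeModel([("chrI", 1_000_000)])
        ref = [iv("chrI", 500_000, 510_000)]
        query = [iv("chrI", 510_000 + i * 2000, 511_000 + i * 2000) for i in range(20)]
        null = binomial_proximity_null(len(query), ref, genome, 50_000, 1e-6)
        obs = proximity_fraction(query, ref, 50_000)
        assert obs >= null.min_fraction_to_reject
        assert binomial_proximity_pvalue(20, 20, null.p_hit) < 1e-6

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            binomial_proximity_null(
                10, [iv("chrI", 0, 10)], GenomeModel([("chrI", 10_000)]), 0, 1.5
            )


class TestProximityCurve:
    def test_curve_shapes_and_monotonicity(self):
        rng = np.random.default_rng(9)
        genome = GenomeModel([("chrI", 500_000)])
        ref = [iv("chrI", int(s) * 1000, int(s) * 1000 + 1000)
               for s in rng.choice(499, 12, replace=False)]
        query = [iv("chrI", int(s) * 1000, int(s) * 1000 + 1000)
                 for s in rng.choice(499, 25, replace=False)]
        curve = proximity_curve(
            query, ref, genome, cutoffs=list(range(0, 20_001, 1000)), alpha=1e-3
        )
        assert len(curve.cutoffs) == 21
        assert np.all(np.diff(curve.observed_fraction) >= 0)
        assert np.all(curve.null_threshold_fraction > 0)


class TestAnnotation:
    def test_overlap_recorded_with_bp(self):
        cl = cluster_calls(calls_at([iv("chrI", 1000, 2000)])).clusters
        feats = [(iv("chrI", 1500, 2500), "LTR_retrotransposon", "Cer9")]
        out = annotate_clusters(cl, feats)
        assert out[0].annotations[0].feature_class == "LTR_retrotransposon"
        assert out[0].annotations[0].overlap_bp == 500

    def test_no_features_leaves_empty_annotations(self):
        cl = cluster_calls(calls_at([iv("chrI", 0, 1000)])).clusters
        assert annotate_clusters(cl, [])[0].annotations == []

    def test_sorted_by_length_for_top_n(self):
        cl = cluster_calls(
            calls_at([iv("chrI", 0, 1000), iv("chrI", 10_000, 11_000),
                      iv("chrI", 12_000, 13_000)]),
            max_gap=5000,
        ).clusters
        out = annotate_clusters(cl, [])
        assert out[0].interval.width >= out[-1].interval.width
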