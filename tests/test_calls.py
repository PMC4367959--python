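"""Fold-change computation and tiered region calling."""

import numpy as np
import pytest

from nucrnai.calls import (
    FoldChangeTable,
    call_desilenced,
    call_grh,
    call_grts,
    call_polII_decreased,
    fold_change,
    fold_change_values,
    summarize_calls,
)
from nucrnai.genome import GenomeBins, GenomeModel, GenomicInterval
from nucrnai.tracks import POLII_ASSAYS, BinnedTrack


@pytest.fixture
def gb():
    return GenomeBins(GenomeModel([("chrI", 10_000), ("chrX", 4_000)]))


def track(gb, values, assay="polII_S2", genotype="wildtype", depth=1.0):
    return BinnedTrack(
        library_id=f"{assay}_{genotype}",
        genotype=genotype,
        assay=assay,
        values=np.asarray(values, dtype=float),
        bins=gb,
        depth_factor=depth,
    )


class TestFoldChange:
    def test_pseudocounted_ratio(self):
        assert fold_change_values([30.0], [10.0], 1.0)[0] == pytest.approx(31 / 11)

    def test_equal_tracks_give_unity(self, gb):
        v = np.arange(14, dtype=float)
        assert np.allclose(fold_change_values(v, v, 0.7), 1.0)

    def test_empty_bins_are_neutral(self):
        assert fold_change_values([0.0], [0.0], 0.5)[0] == 1.0

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fold_change_values(np.ones(3), np.ones(4), 1.0)

    def test_monotone_in_both_arguments(self):
        base = fold_change_values([10.0], [10.0], 1.0)[0]
        assert fold_change_values([12.0], [10.0], 1.0)[0] > base
        assert fold_change_values([10.0], [12.0], 1.0)[0] < base

    def test_track_interface_uses_depth_epsilon(self, gb):
        m = track(gb, np.full(14, 4.0), genotype="mutant", depth=2.0)
        w = track(gb, np.full(14, 2.0), depth=1.0)
        fc = fold_change(m, w)  # epsilon = max depth factor = 2
        assert fc[0] == pytest.approx(6 / 4)


def polii_fc(gb, triples_at_zero):
    """FC vectors that are 1 everywhere except bin 0."""
    out = {}
    for assay, v in zip(POLII_ASSAYS, triples_at_zero):
        vec = np.ones(gb.n_bins)
        vec[0] = v
        out[assay] = vec
    return out


class TestGrts:
    def test_all_assays_rule(self, gb):
        calls = call_grts(polii_fc(gb, (5.0, 4.0, 9.0)), gb, cutoff=3.0)
        assert len(calls) == 1
        assert calls[0].tier == 3.0
        assert calls[0].bin.index == 0

    def test_one_weak_assay_demotes_tier(self, gb):
        fc = polii_fc(gb, (5.0, 2.9, 9.0))
        assert call_grts(fc, gb, cutoff=3.0) == []
        calls2 = call_grts(fc, gb, cutoff=2.0)
        assert len(calls2) == 1 and calls2[0].tier == 2.0

    def test_requires_three_assay_pairs(self, gb):
        with pytest.raises(ValueError, match="three Pol II"):
            call_grts({"polII_S2": np.ones(gb.n_bins)}, gb)

    def test_tier_nesting(self, gb):
        rng = np.random.default_rng(1)
        fc = {a: np.exp(rng.normal(0, 1, gb.n_bins)) for a in POLII_ASSAYS}
        sets = {
            c: {x.bin.index for x in call_grts(fc, gb, cutoff=c)}
            for c in (1.5, 2.0, 3.0)
        }
        assert sets[3.0] <= sets[2.0] <= sets[1.5]

    def test_identical_tracks_yield_no_calls(self, gb):
        fc = {a: np.ones(gb.n_bins) for a in POLII_ASSAYS}
        assert call_grts(fc, gb, cutoff=1.5) == []

    def test_min_signal_filters_low_coverage(self, gb):
        fc = polii_fc(gb, (5.0, 5.0, 5.0))
        weak = {a: np.full(gb.n_bins, 2.0) for a in POLII_ASSAYS}
        assert (
            call_grts(fc, gb, cutoff=3.0, mutant_signal=weak, min_signal=5.0) == []
        )

    def test_decreased_calls_use_inverted_ratio(self, gb):
        fc = polii_fc(gb, (0.2, 0.25, 0.1))
        calls = call_polII_decreased(fc, gb, cutoff=3.0)
        assert [c.bin.index for c in calls] == [0]
        assert calls[0].call_type == "POLII_DECREASED"


class TestGrh:
    def test_threefold_reduction_called(self, gb):
        fc = np.ones(gb.n_bins)
        fc[2] = (12 + 1) / (3 + 1)  # wt 12 vs mutant 3 at eps 1 -> 3.25
        res = call_grh({"hrde-1": fc}, gb, cutoff=3.0)
        assert [c.bin.index for c in res.calls] == [2]

    def test_every_mutant_must_agree(self, gb):
        a = np.ones(gb.n_bins)
        b = np.ones(gb.n_bins)
        a[0], b[0] = 3.5, 2.0
        assert call_grh({"A": a, "B": b}, gb, cutoff=3.0).calls == []

    def test_empty_mutant_set_rejected(self, gb):
        with pytest.raises(ValueError, match="empty mutant set"):
            call_grh({}, gb)

    def test_retained_fraction_against_reference_regions(self):
        # 358 reference 1-kb regions; H3K9me3 dependence on the extra mutant
        # planted in 215 of them -> retained fraction 215/358 (60%)
        gb = GenomeBins(GenomeModel([("chrI", 800_000)]))
        fc = np.ones(gb.n_bins)
        refs = [GenomicInterval("chrI", i * 2000, i * 2000 + 1000) for i in range(358)]
        for i in range(215):
            fc[gb.bin_index("chrI", refs[i].start)] = 5.0
        res = call_grh({"hrde-1": fc}, gb, cutoff=3.0, reference_regions=refs)
        assert res.retained_fraction == pytest.approx(215 / 358)
        assert round(100 * res.retained_fraction) == 60


class TestDesilenced:
    def test_fraction_counting(self, gb):
        fc = np.ones(gb.n_bins)
        regions = [GenomicInterval("chrI", i * 1000, (i + 1) * 1000) for i in range(10)]
        fc[:8] = 4.0
        fc[8:10] = 1.0
        res = call_desilenced(fc, gb, regions, cutoff=3.0)
        assert res.fraction == pytest.approx(0.8)
        assert all(c.call_type == "HRDE1_TARGET" for c in res.calls)

    def test_cutoff_one_with_all_fc_at_least_one(self, gb):
        fc = np.full(gb.n_bins, 1.0)
        regions = [GenomicInterval("chrI", 0, 1000)]
        assert call_desilenced(fc, gb, regions, cutoff=1.0).fraction == 1.0

    def test_empty_base_regions_rejected(self, gb):
        with pytest.raises(ValueError, match="empty"):
            call_desilenced(np.ones(gb.n_bins), gb, [])

    def test_recovers_planted_desilenced_fraction(self, sim_default):
        from nucrnai.calls import default_epsilon
        from nucrnai.tracks import bin_signal

        res = sim_default
        gb = res.bins
        mut = bin_signal(res.library("mRNA", "mutant"), gb, "per_million",
                         assay="mRNA", genotype="mutant")
        wt = bin_signal(res.library("mRNA", "wildtype"), gb, "per_million",
                        assay="mRNA", genotype="wildtype")
        fc = fold_change(mut, wt)
        regions = [r.interval for r in res.truth.grts_regions()]
        truth_frac = np.mean([r.desilenced for r in res.truth.grts_regions()])
        got = call_desilenced(fc, gb, regions, cutoff=3.0).fraction
        # binomial sampling error at n = len(regions)
        se = np.sqrt(truth_frac * (1 - truth_frac) / len(regions))
        assert abs(got - truth_frac) <= 3 * se + 1e-9


class TestSummaries:
    def _calls(self, gb, idx_fc, call_type="GRTS"):
        from nucrnai.calls import RegionCall

        bins = gb.bins
        return [
            RegionCall(bins[i], call_type, 3.0, {"polII_S2": v})
            for i, v in idx_fc
        ]

    def test_median_fold_change(self, gb):
        calls = self._calls(gb, [(0, 2.0), (1, 4.0), (2, 6.0)])
        s = summarize_calls(calls, gb.genome)
        assert s.median_fc["polII_S2"] == 4.0

    def test_autosome_only_calls_have_zero_sex_fraction(self, gb):
        calls = self._calls(gb, [(0, 3.0), (5, 3.0)])
        s = summarize_calls(calls, gb.genome)
        assert s.sex_chromosome_fraction == 0.0
        assert s.per_chromosome["chrX"] == 0

    def test_sex_chromosome_fraction_matches_tabulation(self):
        # 215 loci with 3 on chrX -> 1.4%
        gb = GenomeBins(GenomeModel([("chrI", 500_000), ("chrX", 100_000)]))
        idx_fc = [(i, 5.0) for i in range(212)]
        x_off = gb.offsets["chrX"]
        idx_fc += [(x_off + i, 5.0) for i in range(3)]
        s = summarize_calls(self._calls(gb, idx_fc, "GRH"), gb.genome)
        assert s.n_calls == 215
        assert 100 * s.sex_chromosome_fraction == pytest.approx(1.4, abs=0.05)

    def test_empty_call_set_gives_zero_summary(self, gb):
        s = summarize_calls([], gb.genome)
        assert s.n_calls == 0
        assert s.median_fc == {}
        assert s.sex_chromosome_fraction == 0.0

    def test_fc_table_medians_indexed_at_call_bins(self, gb):
        vec = np.ones(gb.n_bins)
        vec[:3] = [2.0, 4.0, 6.0]
        table = FoldChangeTable(gb, {"polII_S5": vec}, epsilon=1.0)
        calls = self._calls(gb, [(0, 0.0), (1, 0.0), (2, 0.0)])
        s = summarize_calls(calls, gb.genome, fc_table=table)
        assert s.median_fc["polII_S5"] == 4.0
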