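"""The synthetic-data generator: determinism, analytic means, recovery."""

import numpy as np
import pytest

from nucrnai.calls import call_grts, fold_change
from nucrnai.simulate import (
    SimulationConfig,
    expected_bin_mean,
    mean_vector,
    plan,
    simulate,
)
from nucrnai.tracks import POLII_ASSAYS, bin_signal

SMALL_CHROMS = (("chrI", 400_000), ("chrII", 400_000), ("chrX", 200_000))


class TestExpectedMeans:
    def test_planted_fold_multiplies_background(self):
        cfg = SimulationConfig(
            seed=1, chromosome_lengths=SMALL_CHROMS,
            n_grts_regions=4, n_grh_regions=5, n_overlap_regions=2,
            grts_polII_fold=5.0, background_reads_per_bin=20.0,
        )
        truth = plan(cfg)
        gb = simulate(cfg, assays=[]).bins
        grts_bin = int(truth.bin_indices(gb, "GRTS")[0])
        assert expected_bin_mean(cfg, grts_bin, "polII_S2", "mutant") == 100.0
        assert expected_bin_mean(cfg, grts_bin, "polII_S2", "wildtype") == 20.0
        assert expected_bin_mean(cfg, grts_bin, "input", "mutant") == 20.0

    def test_h3k9me3_enriched_in_wildtype_at_grh(self):
        cfg = SimulationConfig(
            seed=1, chromosome_lengths=SMALL_CHROMS,
            n_grts_regions=4, n_grh_regions=5, n_overlap_regions=2,
        )
        gb = simulate(cfg, assays=[]).bins
        grh_bin = int(plan(cfg).bin_indices(gb, "GRH")[0])
        wt = expected_bin_mean(cfg, grh_bin, "H3K9me3", "wildtype")
        mut = expected_bin_mean(cfg, grh_bin, "H3K9me3", "mutant")
        assert wt / mut == pytest.approx(cfg.grh_h3k9_fold)

    def test_unknown_library_rejected(self):
        cfg = SimulationConfig(seed=1, chromosome_lengths=SMALL_CHROMS,
                               n_grts_regions=2, n_grh_regions=3,
                               n_overlap_regions=1)
        with pytest.raises(ValueError, match="assay"):
            expected_bin_mean(cfg, 0, "ChIRP", "mutant")

    def test_empirical_bin_mean_matches_analytic(self):
        cfg = SimulationConfig(
            seed=5, chromosome_lengths=(("chrI", 100_000), ("chrX", 50_000)),
            n_grts_regions=1, n_grh_regions=1, n_overlap_regions=1,
            repeat_block_bins=0, n_background_ltr=1,
        )
        gb = simulate(cfg, assays=[]).bins
        means = mean_vector(cfg, "polII_S5", "mutant")
        # across-bin law of large numbers within one library draw
        counts = np.zeros(gb.n_bins)
        table = simulate(cfg, assays=["polII_S5"]).library("polII_S5", "mutant")
        t = bin_signal(table, gb, "raw")
        background = means == cfg.background_reads_per_bin
        n = background.sum()
        se = np.sqrt(cfg.background_reads_per_bin / n)
        assert abs(t.values[background].mean() - cfg.background_reads_per_bin) <= 3 * se

    def test_library_total_concentrates_on_sum_of_means(self):
        cfg = SimulationConfig(
            seed=9, chromosome_lengths=SMALL_CHROMS,
            n_grts_regions=4, n_grh_regions=5, n_overlap_regions=2,
        )
        res = simulate(cfg, assays=["pre_mRNA"])
        expect = mean_vector(cfg, "pre_mRNA", "mutant").sum()
        got = res.library("pre_mRNA", "mutant").total_weight
        assert abs(got - expect) <= 3 * np.sqrt(expect)


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(
            seed=21, chromosome_lengths=SMALL_CHROMS,
            n_grts_regions=3, n_grh_regions=4, n_overlap_regions=2,
        )
        a = simulate(cfg, outdir=tmp_path / "a", assays=["smallRNA"])
        b = simulate(cfg, outdir=tmp_path / "b", assays=["smallRNA"])
        for key in ("chrom_sizes", "truth", "smallRNA_wildtype"):
            assert (a.paths[key]).read_bytes() == (b.paths[key]).read_bytes()

    def test_subset_generation_matches_full_run(self):
        cfg = SimulationConfig(
            seed=22, chromosome_lengths=SMALL_CHROMS,
            n_grts_regions=3, n_grh_regions=4, n_overlap_regions=2,
        )
        full = simulate(cfg, assays=["polII_S2", "mRNA"])
        only = simulate(cfg, assays=["mRNA"])
        assert full.library("mRNA", "mutant").df.equals(
            only.library("mRNA", "mutant").df
        )

    def test_different_seeds_differ(self):
        base = dict(chromosome_lengths=SMALL_CHROMS, n_grts_regions=3,
                    n_grh_regions=4, n_overlap_regions=2)
        a = simulate(SimulationConfig(seed=1, **base), assays=["input"])
        b = simulate(SimulationConfig(seed=2, **base), assays=["input"])
        assert not a.library("input", "wildtype").df.equals(
            b.library("input", "wildtype").df
        )


class TestPlanting:
    def test_x_chromosome_excluded_by_default(self, sim_default):
        for r in sim_default.truth.regions:
            assert r.interval.chrom != "chrX"

    def test_capacity_error(self):
        cfg = SimulationConfig(
            seed=1, chromosome_lengths=(("chrI", 30_000), ("chrX", 10_000)),
            n_grts_regions=10, n_grh_regions=10, n_overlap_regions=5,
        )
        with pytest.raises(ValueError, match="capacity"):
            plan(cfg)

    def test_ltr_planting_matches_configured_fraction(self, sim_default):
        truth = sim_default.truth
        n_grts = len(truth.grts_regions())
        n_ltr = sum(1 for r in truth.grts_regions() if r.has_ltr)
        cfg = sim_default.config
        assert n_ltr == round(cfg.ltr_in_grts_fraction * n_grts)
        assert len(truth.dna_transposons) == cfg.n_dna_transposon


class TestMultiMappers:
    def test_repeat_reads_weighted_by_copy_number(self, sim_small):
        cfg = sim_small.config
        table = sim_small.library("input", "wildtype")
        copies = sim_small.truth.repeat_copies
        mid = table.midpoints()
        chroms = table.df["chrom"].to_numpy()
        in_block = np.zeros(len(table), dtype=bool)
        for c in copies:
            in_block |= (chroms == c.chrom) & (mid >= c.start) & (mid < c.end)
        assert in_block.any()
        assert np.allclose(
            table.df["weight"].to_numpy()[in_block], 1.0 / cfg.repeat_copies
        )
        assert (table.df["hit_count"].to_numpy()[in_block] == cfg.repeat_copies).all()

    def test_summed_block_signal_counts_each_read_once(self, sim_small):
        # each multi-mapped read spreads weight 1 over the copies, so the
        # summed binned signal over all copies equals the number of reads
        table = sim_small.library("input", "wildtype")
        t = bin_signal(table, sim_small.bins, "raw")
        total_block = sum(
            t.values[r.start : r.stop].sum()
            for r in (
                sim_small.bins.bins_overlapping(c)
                for c in sim_small.truth.repeat_copies
            )
        )
        n_multi_reads = (
            table.df.loc[table.df["hit_count"] > 1, "weight"].sum()
        )
        # block bins also hold ordinary unique background reads
        assert total_block >= n_multi_reads
        assert abs(t.total - table.total_weight) < 1e-9


class TestRecovery:
    def _grts_calls(self, res, cutoff=3.0):
        gb = res.bins
        fc = {}
        sig = {}
        for a in POLII_ASSAYS:
            mut = bin_signal(res.library(a, "mutant"), gb, "per_million",
                             assay=a, genotype="mutant")
            wt = bin_signal(res.library(a, "wildtype"), gb, "per_million",
                            assay=a, genotype="wildtype")
            fc[a] = fold_change(mut, wt)
            sig[a] = mut.values / mut.depth_factor
        return call_grts(fc, gb, cutoff=cutoff, mutant_signal=sig, min_signal=5.0)

    def test_planted_bins_recovered_at_default_conditions(self, sim_default):
        calls = self._grts_calls(sim_default)
        called = {c.bin.index for c in calls}
        truth = set(sim_default.truth.bin_indices(sim_default.bins, "GRTS").tolist())
        recall = len(called & truth) / len(truth)
        precision = len(called & truth) / max(len(called), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_twelve_single_bin_regions_recovered_without_false_calls(self):
        # 12 planted 5-fold single-bin regions at 20 reads/bin: every call is
        # a planted bin, at most one planted bin may be missed, and a miss
        # can only be marginal (its consistent fold change just under the
        # cutoff, a wild-type Poisson fluctuation, not a systematic error)
        cfg = SimulationConfig(
            seed=7, n_grts_regions=12, n_grh_regions=12, n_overlap_regions=6,
            grts_len_bins=1, grts_polII_fold=5.0,
        )
        res = simulate(cfg, assays=list(POLII_ASSAYS))
        gb = res.bins
        fc, sig = {}, {}
        for a in POLII_ASSAYS:
            mut = bin_signal(res.library(a, "mutant"), gb, "per_million",
                             assay=a, genotype="mutant")
            wt = bin_signal(res.library(a, "wildtype"), gb, "per_million",
                            assay=a, genotype="wildtype")
            fc[a] = fold_change(mut, wt)
            sig[a] = mut.values / mut.depth_factor
        calls = call_grts(fc, gb, cutoff=3.0, mutant_signal=sig, min_signal=5.0)
        called = {c.bin.index for c in calls}
        truth = set(res.truth.bin_indices(res.bins, "GRTS").tolist())
        assert called <= truth  # zero false calls
        assert len(truth - called) <= 1
        min_fc = np.min([fc[a] for a in POLII_ASSAYS], axis=0)
        for i in truth - called:
            assert min_fc[i] >= 0.9 * 3.0
        assert all(c.tier == 3.0 for c in calls)

    def test_null_configuration_produces_no_tier3_calls(self):
        cfg = SimulationConfig(
            seed=19, grts_polII_fold=1.0, grh_h3k9_fold=1.0, premrna_fold=1.0,
            mrna_fold=1.0, sirna_target_fold=1.0,
        )
        res = simulate(cfg, assays=list(POLII_ASSAYS))
        calls = self._grts_calls(res)
        # genotypes are exchangeable: consistent 3-fold excursions in all
        # three antibodies are essentially impossible at 20 reads/bin
        assert len(calls) <= 1
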