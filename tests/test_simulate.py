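"""The synthetic-data generator: determinism, truth consistency, RRT power."""

import numpy as np
import pytest

from plastdiv import (SimulationConfig, classify_columns, revcomp,
                      simulate, simulate_alignment, simulate_reference,
                      simulate_rrt_replicates, snp_partition, tajima_rrt)
from plastdiv.simulate import PlantedDeletion, PlantedHotspot


SMALL = dict(lsc_length=2000, ira_length=500, ssc_length=800)


class TestSimulateReference:
    def test_quadripartite_construction(self):
        config = SimulationConfig(**SMALL, seed=1)
        seq, features = simulate_reference(config)
        assert len(seq) == 2000 + 500 + 800 + 500
        ira = seq[2000:2500]
        irb = seq[3300:3800]
        assert irb == revcomp(ira)
        assert len(features) > 0

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError, match="ssc_length"):
            SimulationConfig(lsc_length=2000, ira_length=500,
                             ssc_length=0).validate()

    def test_features_fall_inside_their_regions(self):
        config = SimulationConfig(**SMALL, seed=2)
        seq, features = simulate_reference(config)
        features.validate(len(seq))


class TestSimulateAlignment:
    def test_zero_rates_reproduce_reference(self):
        config = SimulationConfig(**SMALL, seed=3, rate=0.0, indel_rate=0.0,
                                  long_deletions=())
        seq, _ = simulate_reference(config)
        alignment, truth = simulate_alignment(seq, config)
        for taxon in alignment.taxa:
            assert alignment.row(taxon) == seq
        assert truth.n_snp_columns == 0
        assert truth.indel_columns.size == 0

    def test_fixed_seed_determinism(self):
        config = SimulationConfig(**SMALL, seed=4)
        ref1, _, aln1, t1 = simulate(config)
        ref2, _, aln2, t2 = simulate(config)
        assert ref1 == ref2
        assert np.array_equal(aln1.matrix, aln2.matrix)
        assert np.array_equal(t1.snp_columns, t2.snp_columns)
        assert t1.subset_credits == t2.subset_credits

    def test_truth_round_trip_classification_and_credits(self):
        config = SimulationConfig(**SMALL, seed=5)
        _, _, alignment, truth = simulate(config)
        records = classify_columns(alignment)
        assert [r.column for r in records if r.is_snp] \
            == truth.snp_columns.tolist()
        assert [r.column for r in records if r.is_indel] \
            == truth.indel_columns.tolist()
        table = snp_partition(records, alignment.taxa)
        assert dict(table.counts) == truth.subset_credits

    def test_ir_regions_are_quiet(self):
        config = SimulationConfig(lsc_length=20_000, ira_length=6_000,
                                  ssc_length=4_000, seed=6,
                                  indel_rate=0.0, long_deletions=())
        _, _, _, truth = simulate(config)
        n = np.zeros(config.total_length)
        n[truth.snp_columns] = 1
        spans = truth.regions
        ir_cols = np.r_[np.arange(*spans["IRa"]), np.arange(*spans["IRb"])]
        sc_cols = np.r_[np.arange(*spans["LSC"]), np.arange(*spans["SSC"])]
        ir_rate = n[ir_cols].mean()
        sc_rate = n[sc_cols].mean()
        # IR multiplier 0.1 -> roughly an order of magnitude fewer SNPs
        assert ir_rate < sc_rate / 3

    def test_hotspots_are_enriched(self):
        config = SimulationConfig(lsc_length=20_000, ira_length=2_000,
                                  ssc_length=4_000, seed=7,
                                  indel_rate=0.0, long_deletions=())
        _, _, _, truth = simulate(config)
        snps = set(truth.snp_columns.tolist())
        hot_cols = sum(h.end - h.start for h in truth.hotspots)
        hot_snps = sum(1 for h in truth.hotspots
                       for c in range(h.start, h.end) if c in snps)
        background = (len(snps) - hot_snps) / (config.total_length - hot_cols)
        assert hot_snps / hot_cols > 2 * background

    def test_planted_deletion_recorded_in_truth(self):
        dele = PlantedDeletion("taxon2", 500, 1100)
        config = SimulationConfig(**SMALL, seed=8, indel_rate=0.0,
                                  long_deletions=(dele,))
        _, _, alignment, truth = simulate(config)
        assert (500, 1100) in truth.deletions["taxon2"]
        assert set(alignment.row("taxon2")[500:1100]) == {"-"}

    def test_reference_length_mismatch_rejected(self):
        config = SimulationConfig(**SMALL, seed=9)
        with pytest.raises(ValueError, match="length"):
            simulate_alignment("ACGT" * 10, config)

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(**SMALL, rate=-1.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(
                **SMALL, hotspots=(PlantedHotspot(0, 10, -2.0),)).validate()
        with pytest.raises(ValueError):
            SimulationConfig(
                **SMALL,
                long_deletions=(PlantedDeletion("nope", 0, 10),)).validate()


class TestRRTReplicates:
    def test_zero_branch_lengths_give_zero_statistic(self):
        reps = simulate_rrt_replicates(20, length=2_000, rate_a=0.0,
                                       rate_b=0.0, outgroup_rate=0.0, seed=0)
        for aln in reps:
            res = tajima_rrt(aln, "A", "B", "outgroup")
            assert res.chi2 == 0.0

    def test_determinism(self):
        r1 = simulate_rrt_replicates(3, length=1_000, seed=12)
        r2 = simulate_rrt_replicates(3, length=1_000, seed=12)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.matrix, b.matrix)

    def test_power_at_fivefold_rate_ratio(self):
        # 5x faster lineage on 20 kb sequences: essentially always detected,
        # and the fast lineage is never the one called slower
        reps = simulate_rrt_replicates(60, length=20_000, rate_a=0.025,
                                       rate_b=0.005, outgroup_rate=0.02,
                                       seed=13)
        rejected = 0
        for aln in reps:
            res = tajima_rrt(aln, "A", "B", "outgroup")
            if res.p < 0.05:
                rejected += 1
                assert res.slower_taxon(alpha=0.05) == "B"
        assert rejected / len(reps) > 0.9
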