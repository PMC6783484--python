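"""Sliding-window profiles, hotspot merging, deletion and identity screens."""

import numpy as np
import pytest

from plastdiv import (Alignment, Feature, FeatureTable, annotate_windows,
                      classify_columns, detect_hotspots,
                      high_deletion_windows, identity_profile,
                      window_profile)
from plastdiv.simulate import PlantedDeletion, SimulationConfig, simulate
from _oracles import brute_window_counts


def _alignment_with_snps(length: int, snp_columns: set[int]) -> Alignment:
    row1 = ["A"] * length
    row2 = ["A"] * length
    for c in snp_columns:
        row2[c] = "C"
    return Alignment.from_strings([("r", "".join(row1)),
                                   ("q", "".join(row2))])


class TestWindowProfile:
    def test_spec_window_counts(self):
        aln = _alignment_with_snps(1000, {100, 300, 600})
        prof = window_profile(classify_columns(aln), 500, 250)
        assert prof.starts.tolist() == [0, 250, 500]
        assert prof.snp_counts.tolist() == [2, 2, 1]
        assert prof.midpoints.tolist() == [250.0, 500.0, 750.0]

    def test_zero_variation(self):
        aln = _alignment_with_snps(1000, set())
        prof = window_profile(classify_columns(aln), 500, 250)
        assert not prof.snp_counts.any() and not prof.indel_counts.any()

    def test_alignment_shorter_than_window(self):
        aln = _alignment_with_snps(100, set())
        with pytest.raises(ValueError, match="smaller"):
            window_profile(classify_columns(aln), 500, 250)

    def test_trailing_partial_window_dropped_by_default(self):
        aln = _alignment_with_snps(1100, set())
        prof = window_profile(classify_columns(aln), 500, 250)
        assert prof.ends.tolist() == [500, 750, 1000]
        partial = window_profile(classify_columns(aln), 500, 250,
                                 include_partial=True)
        assert partial.ends.tolist() == [500, 750, 1000, 1100]

    def test_indel_density_per_kb(self):
        aln = Alignment.from_strings([("r", "A" * 500),
                                      ("q", "A" * 250 + "-" * 50 + "A" * 200)])
        prof = window_profile(classify_columns(aln), 500, 500)
        assert prof.indel_counts.tolist() == [50]
        assert prof.indel_density_per_kb.tolist() == [100.0]

    def test_nonoverlapping_windows_sum_to_total(self, small_sim):
        _, _, _, alignment, truth = small_sim
        records = classify_columns(alignment)
        prof = window_profile(records, 500, 500)
        covered = int(prof.ends[-1])
        in_span = np.count_nonzero(truth.snp_columns < covered)
        assert int(prof.snp_counts.sum()) == in_span

    def test_profile_invariant_to_taxon_order(self, small_sim):
        _, _, _, alignment, _ = small_sim
        prof = window_profile(classify_columns(alignment), 500, 250)
        perm = np.random.default_rng(1).permutation(alignment.n_taxa)
        shuffled = Alignment(tuple(alignment.taxa[i] for i in perm),
                             alignment.matrix[perm])
        prof2 = window_profile(classify_columns(shuffled), 500, 250)
        assert prof.snp_counts.tolist() == prof2.snp_counts.tolist()
        assert prof.indel_counts.tolist() == prof2.indel_counts.tolist()

    def test_counts_match_brute_force_on_simulated_truth(self, small_sim):
        _, _, _, alignment, truth = small_sim
        prof = window_profile(classify_columns(alignment), 400, 150)
        assert prof.snp_counts.tolist() == brute_window_counts(
            truth.snp_columns, prof.starts, prof.ends)
        assert prof.indel_counts.tolist() == brute_window_counts(
            truth.indel_columns, prof.starts, prof.ends)


class TestHotspots:
    def test_merge_overlapping_windows_distinct_recount(self):
        aln = _alignment_with_snps(1000, {10, 260, 400, 600})
        records = classify_columns(aln)
        prof = window_profile(records, 500, 250)
        regions = detect_hotspots(prof, records, "min_count", 3)
        assert [(r.start, r.end) for r in regions] == [(0, 750)]
        assert regions[0].snp_total == 4  # distinct columns, no double count
        assert regions[0].merged_window_count == 2

    def test_no_window_meets_threshold(self):
        aln = _alignment_with_snps(1000, {10})
        records = classify_columns(aln)
        prof = window_profile(records, 500, 250)
        assert detect_hotspots(prof, records, "min_count", 5) == []

    def test_top_k_selects_highest_density_region(self, small_sim):
        _, _, _, alignment, truth = small_sim
        records = classify_columns(alignment)
        prof = window_profile(records, 500, 250)
        regions = detect_hotspots(prof, records, "top_k", 4)
        # every planted hotspot interval overlaps a reported region
        for h in truth.hotspots:
            assert any(r.start < h.end and h.start < r.end for r in regions), \
                f"planted hotspot {h} not recovered"

    def test_invalid_param(self):
        aln = _alignment_with_snps(1000, {10})
        records = classify_columns(aln)
        prof = window_profile(records, 500, 250)
        with pytest.raises(ValueError):
            detect_hotspots(prof, records, "min_count", 0)


class TestHighDeletionWindows:
    def test_threshold_arithmetic(self):
        # 400 gaps in a 500 bp window: 0.8 > 0.7 -> flagged
        aln = Alignment.from_strings([("r", "A" * 500),
                                      ("q", "-" * 400 + "A" * 100)])
        flagged = high_deletion_windows(aln, 500, 250, 0.70)
        assert flagged == [((0, 500), ("q",))]

    def test_below_threshold_everywhere(self):
        aln = Alignment.from_strings([("r", "A" * 1000),
                                      ("q", "-" * 300 + "A" * 700)])
        assert high_deletion_windows(aln, 500, 250, 0.70) == []

    def test_planted_long_deletion_flags_exact_windows(self):
        # one 600 bp deletion; flagged windows are exactly those overlapping
        # more than 350 of its positions (0.7 x 500)
        config = SimulationConfig(
            lsc_length=5_600, ira_length=1_600, ssc_length=1_200, seed=5,
            rate=0.0, indel_rate=0.0,
            long_deletions=(PlantedDeletion("taxon1", 2_000, 2_600),))
        _, _, alignment, _ = simulate(config)
        flagged = high_deletion_windows(alignment, 500, 250, 0.70)
        expected = []
        for start in range(0, alignment.length - 500 + 1, 250):
            overlap = max(0, min(start + 500, 2_600) - max(start, 2_000))
            if overlap / 500 > 0.70:
                expected.append(((start, start + 500), ("taxon1",)))
        assert flagged == expected
        assert expected  # the scenario must actually flag something


class TestIdentityProfile:
    def test_identical_sequences_and_self_reference(self):
        aln = Alignment.from_strings([("r", "ACGT" * 250),
                                      ("q", "ACGT" * 250)])
        df = identity_profile(aln, "r", 500, 250)
        assert (df["q"] == 100.0).all()
        assert (df["r"] == 100.0).all()

    def test_five_mismatches_in_comparable_window(self):
        seq = ["A"] * 500
        for c in range(5):
            seq[c * 17] = "C"
        aln = Alignment.from_strings([("r", "A" * 500), ("q", "".join(seq))])
        df = identity_profile(aln, "r", 500, 500)
        assert df["q"].tolist() == [99.0]

    def test_gap_vs_base_is_mismatch_gap_vs_gap_excluded(self):
        aln = Alignment.from_strings([("r", "AAAA----"),
                                      ("q", "AA------")])
        df = identity_profile(aln, "r", 8, 8)
        # comparable: 4 (AA match + 2 gap-vs-base), gap-gap excluded
        assert df["q"].tolist() == [50.0]

    def test_zero_comparable_columns_reported_undefined(self):
        aln = Alignment.from_strings([("r", "NNNN"), ("q", "ACGT")])
        df = identity_profile(aln, "r", 4, 4)
        assert np.isnan(df["q"]).all()


class TestAnnotateWindows:
    @pytest.fixture
    def labelled(self):
        # reference has a gap so lifting is non-trivial:
        # ungapped ref coords:  0-9 geneA, 14-19 geneB; spacer 10..13
        aln = Alignment.from_strings([
            ("ref", "AAAAA-AAAAAAAAAAAAAAA"),   # 21 cols, 20 ungapped
            ("oth", "AAAAACAAAAAAAAAAAAAAA"),
        ])
        features = FeatureTable([
            Feature("geneA", "coding", ((0, 10),), "+"),
            Feature("geneB", "tRNA", ((14, 20),), "+"),
        ])
        records = classify_columns(aln)
        prof = window_profile(records, 7, 7)
        return annotate_windows(prof, features, aln, "ref")

    def test_window_inside_gene(self, labelled):
        assert labelled.labels[0] == "geneA"

    def test_window_straddling_gene_end_gets_gene_and_spacer(self, labelled):
        # columns 7..14 overlap geneA (ends col 11) and the spacer
        assert "geneA" in labelled.labels[1]
        assert "geneA-geneB spacer" in labelled.labels[1]

    def test_spacer_window_label(self, labelled):
        # columns 14..21: spacer ends at ungapped 14 -> col 15, geneB after
        assert "geneB" in labelled.labels[2]
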