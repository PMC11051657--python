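"""Stratification and selection rules."""

import numpy as np
import pandas as pd
import pytest

from lamellakit import curation


class TestSplitEqualCount:
    @pytest.mark.parametrize("n, k, expected", [(9, 3, [3, 3, 3]), (10, 3, [4, 3, 3])])
    def test_sizes_with_remainder_to_lowest_key(self, n, k, expected):
        df = pd.DataFrame({"t": np.arange(n, dtype=float), "tomogram_id": "a"})
        labeled, report = curation.split_equal_count(df, "t", k)
        assert list(report["size"]) == expected
        # extras go to the lowest-key group
        assert labeled.loc[labeled["t"] < expected[0], "group"].eq(0).all()

    def test_partition_properties(self, small_table):
        labeled, report = curation.split_equal_count(
            small_table, "local_thickness_nm", 3
        )
        assert len(labeled) == len(small_table)
        sizes = labeled["group"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        # contiguous, non-overlapping key ranges except at shared boundaries
        for g in range(2):
            assert report.loc[g, "key_max"] <= report.loc[g + 1, "key_min"]

    def test_errors(self, small_table):
        with pytest.raises(ValueError):
            curation.split_equal_count(small_table.iloc[:2], "depth_nm", 3)
        with pytest.raises(KeyError):
            curation.split_equal_count(small_table, "missing", 3)
        with pytest.raises(ValueError):
            curation.split_equal_count(small_table.iloc[:0], "depth_nm", 3)


def brute_force_nearest(df, center, n, key="depth_nm"):
    """Oracle: full stable sort by |depth - center|."""
    order = np.argsort(np.abs(df[key].to_numpy() - center), kind="stable")[:n]
    return set(df.index[order])


class TestSelectDepthBins:
    def test_nearest_by_distance_with_stable_ties(self):
        df = pd.DataFrame(
            {"depth_nm": np.arange(1.0, 2001.0), "tomogram_id": "a"}
        )
        groups, _ = curation.select_depth_bins(df, [5.0], 3)
        assert sorted(groups[5.0]["depth_nm"]) == [4.0, 5.0, 6.0]

    def test_single_closest(self):
        df = pd.DataFrame({"depth_nm": [1.0, 4.9, 30.0], "tomogram_id": "a"})
        groups, _ = curation.select_depth_bins(df, [5.0], 1)
        assert groups[5.0]["depth_nm"].iloc[0] == 4.9

    def test_matches_brute_force_oracle_and_overlap(self):
        # few particles near the surface: shallow groups must overlap
        rng = np.random.default_rng(21)
        depth = np.concatenate(
            [rng.uniform(0, 10, 600), rng.uniform(10, 80, 5000)]
        )
        df = pd.DataFrame({"depth_nm": depth, "tomogram_id": "a"})
        groups, report = curation.select_depth_bins(df, [5.0, 10.0], 1000)
        for c in (5.0, 10.0):
            assert set(groups[c].index) == brute_force_nearest(df, c, 1000)
        assert (groups[5.0]["depth_nm"] > 10).any()
        assert report.loc[1, "overlap_with_previous"] > 0

    def test_too_few_particles(self):
        df = pd.DataFrame({"depth_nm": [1.0], "tomogram_id": "a"})
        with pytest.raises(ValueError):
            curation.select_depth_bins(df, [5.0], 10)


class TestSelectHighQuality:
    def test_count_by_enumeration(self, rng):
        n = 100
        df = pd.DataFrame(
            {
                "tomogram_id": rng.choice(["a", "b", "c"], n),
                "local_thickness_nm": rng.uniform(100, 260, n),
                "depth_nm": rng.uniform(0, 80, n),
            }
        )
        kept, breakdown = curation.select_high_quality(df, 180.0, 30.0)
        expected = (
            (df["local_thickness_nm"] < 180) & (df["depth_nm"] > 30)
        ).sum()
        assert len(kept) == expected
        assert breakdown["n_kept"].sum() == expected

    def test_strict_boundaries_excluded(self):
        df = pd.DataFrame(
            {
                "tomogram_id": ["a"] * 3,
                "local_thickness_nm": [180.0, 179.9, 179.9],
                "depth_nm": [40.0, 30.0, 30.1],
            }
        )
        kept, _ = curation.select_high_quality(df)
        assert len(kept) == 1 and kept["depth_nm"].iloc[0] == 30.1

    def test_identity_when_unrestrictive(self, small_table):
        table = small_table[small_table["depth_nm"] > 0]
        kept, _ = curation.select_high_quality(table, np.inf, 0.0)
        assert kept.equals(table)

    def test_idempotent_and_monotone(self, small_table):
        kept, _ = curation.select_high_quality(small_table, 180, 30)
        again, _ = curation.select_high_quality(kept, 180, 30)
        assert again.equals(kept)
        looser, _ = curation.select_high_quality(small_table, 220, 20)
        assert set(kept.index) <= set(looser.index)


class TestRandomSubsets:
    def test_nesting_and_determinism(self, small_table):
        subs1, _ = curation.random_subsets(small_table, [20, 50, 100], seed=3)
        subs2, _ = curation.random_subsets(small_table, [20, 50, 100], seed=3)
        assert set(subs1[20].index) <= set(subs1[50].index) <= set(subs1[100].index)
        for s in (20, 50, 100):
            assert subs1[s].equals(subs2[s])

    def test_thickness_distribution_unbiased(self, simulated):
        particles, truth = simulated
        df = particles.assign(
            local_thickness_nm=truth["true_thickness_nm"].to_numpy()
        )
        sizes = [250, 1000, 4000, min(16114, len(df))]
        _, report = curation.random_subsets(df, sizes, seed=11)
        assert (report["ks_pvalue"] > 0.01).all()

    def test_size_validation(self, small_table):
        with pytest.raises(ValueError):
            curation.random_subsets(small_table, [50, 20], seed=0)
        with pytest.raises(ValueError):
            curation.random_subsets(small_table, [10**6], seed=0)


class TestSelectByTomogram:
    def test_whole_tomogram_then_trim(self):
        df = pd.DataFrame(
            {
                "tomogram_id": np.repeat(["a", "b", "c"], 10),
                "x": np.arange(30.0),
            }
        )
        sel = curation.select_by_tomogram(df, 25, seed=4)
        assert len(sel) == 25
        counts = sel["tomogram_id"].value_counts()
        assert len(counts) == 3 and sorted(counts) == [5, 10, 10]

    def test_exact_single_tomogram(self):
        df = pd.DataFrame({"tomogram_id": ["a"] * 7, "x": np.arange(7.0)})
        assert curation.select_by_tomogram(df, 7, seed=0).equals(df)

    def test_seed_determinism(self, small_table):
        a = curation.select_by_tomogram(small_table, 120, seed=9)
        b = curation.select_by_tomogram(small_table, 120, seed=9)
        assert a.equals(b)
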