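"""Rarefaction, diversity indices, guild aggregation, and rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from darkox.community import (
    aggregate_guilds,
    alpha_diversity,
    bray_curtis,
    chao1,
    expected_rarefied_richness,
    group_difference,
    guild_vs_oxygen,
    load_guild_map,
    pseudo_log10,
    rarefy,
    rarefy_table,
    sample_seed,
)


class TestRarefy:
    def test_depth_equal_total_is_identity(self):
        counts = np.array([5, 3, 0, 2])
        out = rarefy(counts, 10, seed=1)
        assert np.array_equal(out, counts)

    def test_output_sums_to_depth_exactly(self):
        counts = np.array([100, 50, 25, 3, 0, 1])
        for seed in range(20):
            assert rarefy(counts, 60, seed).sum() == 60

    def test_never_creates_counts_from_zero(self):
        counts = np.array([40, 0, 60, 0])
        for seed in range(20):
            out = rarefy(counts, 30, seed)
            assert out[1] == 0 and out[3] == 0

    def test_reproducible_under_seed(self):
        counts = np.array([30, 20, 10])
        assert np.array_equal(rarefy(counts, 25, 42), rarefy(counts, 25, 42))

    def test_depth_above_total_raises(self):
        with pytest.raises(ValueError):
            rarefy(np.array([1, 2]), 10, 0)

    def test_expected_richness_matches_exhaustive_enumeration(self):
        # independent oracle: enumerate all subsets of individual reads
        counts = np.array([3, 2, 1])
        depth = 3
        reads = [t for t, c in enumerate(counts) for _ in range(c)]
        richness = [
            len(set(combo)) for combo in itertools.combinations(range(len(reads)), depth)
        ]
        taxa = [tuple(reads[i] for i in combo)
                for combo in itertools.combinations(range(len(reads)), depth)]
        brute = np.mean([len(set(t)) for t in taxa])
        assert expected_rarefied_richness(counts, depth) == pytest.approx(brute, rel=1e-12)

    def test_monte_carlo_richness_matches_hypergeometric_closed_form(self):
        counts = np.array([50, 20, 10, 5, 2, 1, 1, 1])
        depth = 30
        expected = expected_rarefied_richness(counts, depth)
        draws = [int((rarefy(counts, depth, seed) > 0).sum()) for seed in range(1000)]
        mc = float(np.mean(draws))
        se = float(np.std(draws, ddof=1) / math.sqrt(len(draws)))
        assert abs(mc - expected) < 4 * se

    def test_table_rarefaction_excludes_shallow_samples(self):
        counts = pd.DataFrame(
            {"a1": [50, 3], "a2": [50, 2]}, index=["deep", "shallow"]
        )
        rt = rarefy_table(counts, depth=20, seed=0)
        assert rt.excluded == ("shallow",)
        assert list(rt.counts.index) == ["deep"]
        assert int(rt.counts.loc["deep"].sum()) == 20

    def test_per_sample_seeds_are_deterministic_and_distinct(self):
        assert sample_seed(1, "A") == sample_seed(1, "A")
        assert sample_seed(1, "A") != sample_seed(1, "B")


class TestAlphaDiversity:
    def test_single_taxon_degenerate_community(self):
        d = alpha_diversity([7])
        assert d["richness"] == 1
        assert d["shannon"] == pytest.approx(0.0)
        assert d["inverse_simpson"] == pytest.approx(1.0)
        assert d["chao1"] == pytest.approx(1.0)

    def test_uniform_four_taxa(self):
        d = alpha_diversity([5, 5, 5, 5])
        assert d["shannon"] == pytest.approx(math.log(4), rel=1e-12)
        assert d["inverse_simpson"] == pytest.approx(4.0, rel=1e-12)

    def test_chao1_hand_fixture(self):
        # S_obs = 10, F1 = 2, F2 = 1 -> 10 + 4/2 = 12
        counts = [10, 9, 8, 7, 6, 5, 4, 1, 1, 2]
        assert len(counts) == 10
        assert sum(1 for c in counts if c == 1) == 2
        assert sum(1 for c in counts if c == 2) == 1
        assert chao1(counts) == pytest.approx(12.0)

    def test_chao1_bias_corrected_fallback_without_doubletons(self):
        counts = [5, 3, 1, 1]  # F1=2, F2=0 -> 4 + 2*1/2 = 5
        assert chao1(counts) == pytest.approx(5.0)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            counts = rng.integers(0, 50, size=30)
            if counts.sum() == 0:
                continue
            d = alpha_diversity(counts)
            assert d["shannon"] <= math.log(d["richness"]) + 1e-12

    def test_taxon_order_invariance(self):
        counts = [9, 4, 0, 2, 1, 1]
        assert alpha_diversity(counts) == alpha_diversity(counts[::-1])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == pytest.approx(0.0)
        assert bray_curtis([3, 0, 2], [0, 5, 0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bray_curtis([3, 1], [1, 3]) == pytest.approx(0.5)

    def test_symmetry(self):
        a, b = [5, 2, 0, 1], [1, 1, 3, 0]
        assert bray_curtis(a, b) == pytest.approx(bray_curtis(b, a))

    def test_undefined_for_double_zero(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


def _toy_tables():
    counts = pd.DataFrame(
        {
            "asv1": [30, 0],
            "asv2": [30, 10],
            "asv3": [40, 90],
        },
        index=["s1", "s2"],
    )
    taxonomy = pd.DataFrame(
        {
            "family": ["Methylophilaceae", "Comamonadaceae", "Unknownaceae"],
            "genus": ["Methylotenera", "Hydrogenophaga", "unc_genus"],
        },
        index=["asv1", "asv2", "asv3"],
    )
    return counts, taxonomy


class TestAggregateGuilds:
    def test_single_mapping_fraction(self):
        counts, taxonomy = _toy_tables()
        gm = pd.DataFrame(
            [{"rank": "genus", "name": "Methylotenera", "guild": "methylotroph"}]
        )
        out = aggregate_guilds(counts, taxonomy, gm)
        assert out.loc["s1", "methylotroph"] == pytest.approx(0.30)
        assert out.loc["s1", "Other"] == pytest.approx(0.70)

    def test_rows_sum_to_one(self):
        counts, taxonomy = _toy_tables()
        out = aggregate_guilds(counts, taxonomy, load_guild_map())
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_unmapped_pool_into_other(self):
        counts, taxonomy = _toy_tables()
        out = aggregate_guilds(counts, taxonomy, pd.DataFrame(columns=["rank", "name", "guild"]))
        assert list(out.columns) == ["Other"]
        assert np.allclose(out["Other"], 1.0)

    def test_family_fallback(self):
        counts, taxonomy = _toy_tables()
        gm = pd.DataFrame(
            [{"rank": "family", "name": "Methylophilaceae", "guild": "methylotroph"}]
        )
        out = aggregate_guilds(counts, taxonomy, gm)
        assert out.loc["s1", "methylotroph"] == pytest.approx(0.30)

    def test_merge_then_aggregate_commutes(self):
        counts, taxonomy = _toy_tables()
        gm = load_guild_map()
        merged = counts.sum(axis=0).to_frame().T
        merged.index = ["pooled"]
        via_merge = aggregate_guilds(merged, taxonomy, gm)
        agg_abs = (
            aggregate_guilds(counts, taxonomy, gm)
            .mul(counts.sum(axis=1), axis=0)
            .sum(axis=0)
        )
        assert np.allclose(
            via_merge.loc["pooled"].sort_index(),
            (agg_abs / agg_abs.sum()).sort_index(),
            atol=1e-12,
        )


class TestGroupDifference:
    def test_exact_enumeration_small_case(self):
        res = group_difference([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_pooled_values_p_one(self):
        res = group_difference([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        values = [3.2, 1.1, 4.0, 2.2, 5.5, 0.1]
        groups = ["x", "y", "x", "y", "x", "y"]
        swapped = ["y", "x", "y", "x", "y", "x"]
        assert group_difference(values, groups).p_value == pytest.approx(
            group_difference(values, swapped).p_value
        )

    def test_exact_matches_scipy_on_tie_free_partitions(self):
        # all two-group partitions of 8 distinct values vs scipy's exact mode
        values = np.array([0.3, 1.7, 2.2, 3.9, 5.1, 6.4, 8.8, 9.5])
        n = len(values)
        for n_a in range(1, n):
            for combo in itertools.combinations(range(n), n_a):
                groups = np.array(["b"] * n)
                groups[list(combo)] = "a"
                ours = group_difference(values, groups)
                ref = mannwhitneyu(
                    values[groups == "a"], values[groups == "b"],
                    alternative="two-sided", method="exact",
                )
                assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_exact_matches_brute_force_with_ties(self):
        # independent enumeration oracle over label assignments, midranks
        values = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        ours = group_difference(values, groups)
        ranks = rankdata(values)
        mean_w = 3 * (len(values) + 1) / 2
        w_obs = ranks[:3].sum()
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
                hits += 1
        assert ours.p_value == pytest.approx(hits / total)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)])
        groups = ["a"] * 15 + ["b"] * 15
        res = group_difference(values, groups)
        assert res.method == "normal_approx"
        assert res.p_value < 0.01

    def test_requires_exactly_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            group_difference([1, 2, 3], ["a", "a", "a"])


class TestGuildVsOxygen:
    def test_join_and_pseudo_log_zero_retained(self):
        fractions = pd.DataFrame(
            {"methylotroph": [0.4, 0.1], "Other": [0.6, 0.9]}, index=["s1", "s2"]
        )
        wells = pd.DataFrame(
            {"do_measured": [0.5, 0.0], "water_type": ["young", "old_sulfate_poor"]},
            index=["s1", "s2"],
        )
        tidy, summary, unmatched = guild_vs_oxygen(fractions, wells)
        assert unmatched == ()
        assert len(tidy) == 4
        zero_row = tidy[(tidy.sample_id == "s2") & (tidy.guild == "methylotroph")]
        assert math.isfinite(float(zero_row["do_pseudo_log10"].iloc[0]))
        assert float(pseudo_log10(0.0)) == 0.0
        assert {"q1", "median", "q3", "mean", "n"} <= set(summary.columns)

    def test_unmatched_samples_reported_not_dropped_silently(self):
        fractions = pd.DataFrame({"Other": [1.0]}, index=["mystery"])
        wells = pd.DataFrame(
            {"do_measured": [0.5], "water_type": ["young"]}, index=["s1"]
        )
        tidy, _, unmatched = guild_vs_oxygen(fractions, wells)
        assert unmatched == ("mystery",)
        assert tidy.empty
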