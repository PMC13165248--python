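"""QC filtering, rank aggregation, CRS, stratification, trait statistics."""

import numpy as np
import pandas as pd
import pytest

from turfhsi.indices import FIVE_QUALITY_INDICES
from turfhsi.ranking import (
    build_rank_ledger,
    combined_ranking_score,
    correlate_with_traits,
    group_compare,
    qc_filter,
    quality_quantity_ranks,
    rank_column,
    stratify,
)


def observations_frame(rep_counts, dates=("6WAT", "16WAT")):
    rows = []
    for gid, n in rep_counts.items():
        for date in dates:
            for rep in range(1, n + 1):
                rows.append(
                    {"genotype_id": gid, "date_label": date, "replicate": rep}
                )
    return pd.DataFrame(rows)


def ledger_from_ranks(rank_rows):
    """Build a ledger directly from per-genotype rank dictionaries."""
    df = pd.DataFrame(rank_rows).set_index("genotype_id")
    return df


class TestQcFilter:
    def test_two_replicates_excluded_three_retained(self):
        obs = observations_frame({"A": 2, "B": 3})
        retained, report = qc_filter(obs)
        assert set(retained["genotype_id"]) == {"B"}
        assert set(report["genotype_id"]) == {"A"}
        assert "2 replicate" in report["reason"].iloc[0]

    def test_all_sufficient_keeps_everyone(self):
        obs = observations_frame({g: 3 for g in "ABC"})
        retained, report = qc_filter(obs)
        assert retained["genotype_id"].nunique() == 3 and report.empty

    def test_mixed_roster_matches_hand_count(self):
        counts = {f"G{i}": n for i, n in enumerate([3, 2, 4, 1, 3, 0, 5, 3, 2, 3])}
        obs = observations_frame({g: n for g, n in counts.items() if n})
        retained, _ = qc_filter(obs)
        survivors = {g for g, n in counts.items() if n >= 3}
        assert set(retained["genotype_id"]) == survivors

    def test_shortfall_at_one_date_excludes(self):
        obs = pd.concat(
            [
                observations_frame({"A": 3}, dates=("6WAT",)),
                observations_frame({"A": 2}, dates=("16WAT",)),
                observations_frame({"B": 3}),
            ]
        )
        retained, _ = qc_filter(obs)
        assert set(retained["genotype_id"]) == {"B"}


class TestRankColumn:
    def test_higher_is_better(self):
        np.testing.assert_array_equal(
            rank_column([0.9, 0.5, 0.7], "higher_is_better"), [1, 3, 2]
        )

    def test_average_ties(self):
        np.testing.assert_array_equal(rank_column([0.5, 0.5], "higher_is_better"), [1.5, 1.5])

    def test_missing_values_rank_last(self):
        ranks = rank_column([0.2, np.nan, 0.9], "higher_is_better")
        np.testing.assert_array_equal(ranks, [2, 3, 1])

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 20)
        ranks = rank_column(vals, "higher_is_better")
        order = np.argsort(-vals)
        oracle = np.empty(20)
        oracle[order] = np.arange(1, 21)
        np.testing.assert_array_equal(ranks, oracle)

    def test_rank_sum_invariant_under_ties(self):
        """Average-tie ranks always sum to N(N+1)/2."""
        rng = np.random.default_rng(1)
        for n in (5, 12, 30):
            vals = rng.integers(0, 4, n).astype(float)  # heavy ties
            assert rank_column(vals, "lower_is_better").sum() == n * (n + 1) / 2


class TestCRS:
    def test_all_rank_one_gives_unity(self):
        row = {"genotype_id": "A", "rank_area": 1.0}
        row.update({f"rank_{n}": 1.0 for n in FIVE_QUALITY_INDICES})
        row2 = {"genotype_id": "B", "rank_area": 2.0}
        row2.update({f"rank_{n}": 2.0 for n in FIVE_QUALITY_INDICES})
        crs = combined_ranking_score(ledger_from_ranks([row, row2]))
        assert crs["A"] == pytest.approx(1.0)

    def test_weighted_formula(self):
        row = {"genotype_id": "A", "rank_area": 2.0}
        for n, r in zip(FIVE_QUALITY_INDICES, [1, 2, 3, 4, 5]):
            row[f"rank_{n}"] = float(r)
        crs = combined_ranking_score(ledger_from_ranks([row]))
        assert crs["A"] == pytest.approx((15 + 10) / 10)

    def test_four_genotype_table_matches_hand_arithmetic(self):
        rng = np.random.default_rng(2)
        means = pd.DataFrame(
            {
                "genotype_id": list("ABCD"),
                "pixel_count": [400, 100, 300, 200],
                **{n: rng.uniform(0, 1, 4) for n in FIVE_QUALITY_INDICES},
            }
        )
        ledger = build_rank_ledger(means)
        for gid in "ABCD":
            hand = 0.0
            for n in FIVE_QUALITY_INDICES:
                col = means.set_index("genotype_id")[n]
                hand += (col > col[gid]).sum() + 1  # distinct values: dense rank
            area = means.set_index("genotype_id")["pixel_count"]
            hand += 5.0 * ((area > area[gid]).sum() + 1)
            assert ledger.loc[gid, "crs"] == pytest.approx(hand / 10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        means = pd.DataFrame(
            {
                "genotype_id": [f"G{i}" for i in range(8)],
                "pixel_count": rng.integers(100, 1000, 8),
                **{n: rng.uniform(0, 1, 8) for n in FIVE_QUALITY_INDICES},
            }
        )
        shuffled = means.sample(frac=1, random_state=1)
        a = build_rank_ledger(means)["crs"].sort_index()
        b = build_rank_ledger(shuffled)["crs"].sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_consistency_limit_single_rank_ordering(self):
        """When all six rank columns coincide, CRS ordering equals that
        single ordering."""
        perm = np.array([3, 1, 4, 2, 5], dtype=float)
        rows = []
        for i, r in enumerate(perm):
            row = {"genotype_id": f"G{i}", "rank_area": r}
            row.update({f"rank_{n}": r for n in FIVE_QUALITY_INDICES})
            rows.append(row)
        crs = combined_ranking_score(ledger_from_ranks(rows))
        np.testing.assert_array_equal(np.argsort(crs.values), np.argsort(perm))

    def test_missing_rank_raises(self):
        row = {"genotype_id": "A", "rank_area": 1.0}
        with pytest.raises(KeyError):
            combined_ranking_score(ledger_from_ranks([row]))


class TestStratify:
    def _ledger(self, n):
        df = pd.DataFrame(index=[f"G{i:03d}" for i in range(n)])
        df["crs_rank"] = np.arange(1, n + 1)
        return df

    def test_small_even_split(self):
        strata = stratify(self._ledger(6), 2, 2, 2)
        assert list(strata) == [
            "Superior", "Superior", "Intermediate", "Intermediate", "Inferior", "Inferior",
        ]

    def test_odd_population_middle_starts_low(self):
        strata = stratify(self._ledger(7), 2, 2, 2)
        assert list(strata[2:4]) == ["Intermediate", "Intermediate"]
        assert strata.iloc[4] == "none"

    def test_overlapping_strata_raise(self):
        with pytest.raises(ValueError):
            stratify(self._ledger(5), 2, 2, 2)


class TestCorrelations:
    def _ledger_with_crs(self, crs_values):
        df = pd.DataFrame(index=[f"G{i}" for i in range(len(crs_values))])
        df["crs"] = crs_values
        return df

    def test_strictly_decreasing_trait_gives_spearman_minus_one(self):
        ledger = self._ledger_with_crs([1.0, 2.0, 3.0, 4.0])
        traits = pd.DataFrame(
            {"genotype_id": ledger.index, "aerial_shoot_count": [9, 7, 5, 1],
             "runner_count": [4, 3, 2, 1], "plant_height": [1, 2, 3, 4]}
        )
        out = correlate_with_traits(ledger, traits, method="spearman")
        shoot = out.set_index("trait").loc["aerial_shoot_count"]
        assert shoot["coefficient"] == pytest.approx(-1.0)

    def test_constant_trait_raises(self):
        ledger = self._ledger_with_crs([1.0, 2.0, 3.0])
        traits = pd.DataFrame(
            {"genotype_id": ledger.index, "aerial_shoot_count": [5, 5, 5],
             "runner_count": [1, 2, 3], "plant_height": [4, 5, 6]}
        )
        with pytest.raises(ValueError):
            correlate_with_traits(ledger, traits)

    def test_pearson_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(4)
        crs = rng.uniform(1, 100, 12)
        y = 50 - 0.3 * crs + rng.normal(0, 5, 12)
        ledger = self._ledger_with_crs(crs)
        traits = pd.DataFrame(
            {"genotype_id": ledger.index, "aerial_shoot_count": y,
             "runner_count": rng.poisson(2, 12), "plant_height": rng.uniform(3, 8, 12)}
        )
        out = correlate_with_traits(ledger, traits, method="pearson")
        r = out.set_index("trait").loc["aerial_shoot_count", "coefficient"]
        oracle = np.sum((crs - crs.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((crs - crs.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle)


class TestGroupCompare:
    def _setup(self, a_vals, b_vals):
        ids = [f"S{i}" for i in range(len(a_vals))] + [f"I{i}" for i in range(len(b_vals))]
        strata = pd.Series(
            ["Superior"] * len(a_vals) + ["Inferior"] * len(b_vals), index=ids
        )
        traits = pd.DataFrame(
            {
                "genotype_id": ids,
                "aerial_shoot_count": np.concatenate([a_vals, b_vals]),
                "runner_count": np.concatenate([a_vals, b_vals]) / 10,
                "plant_height": np.concatenate([a_vals, b_vals]) / 5,
            }
        )
        return traits, strata

    def test_identical_groups_give_p_one(self):
        vals = np.array([1.0, 2.0, 3.0])
        traits, strata = self._setup(vals, vals)
        out = group_compare(traits, strata)
        assert out["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert out["significance"].iloc[0] == "ns"

    def test_ten_sd_shift_is_highly_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(100, 1, 20)
        b = rng.normal(90, 1, 20)  # 10 SD shift
        traits, strata = self._setup(a, b)
        out = group_compare(traits, strata)
        assert out["p_value"].iloc[0] < 1e-3
        assert out["significance"].iloc[0] == "***"

    def test_means_and_sds_match_streaming_moment_oracle(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(0, 50, 8), rng.uniform(0, 50, 9)
        traits, strata = self._setup(a, b)
        out = group_compare(traits, strata).set_index("trait").loc["aerial_shoot_count"]
        # two-pass streaming moments
        def moments(x):
            m = sum(x) / len(x)
            return m, (sum((v - m) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        ma, sa = moments(list(a))
        mb, sb = moments(list(b))
        assert out["superior_mean"] == pytest.approx(ma)
        assert out["superior_sd"] == pytest.approx(sa)
        assert out["inferior_mean"] == pytest.approx(mb)
        assert out["inferior_sd"] == pytest.approx(sb)

    def test_tiny_group_raises(self):
        traits, strata = self._setup(np.array([1.0]), np.array([2.0, 3.0]))
        with pytest.raises(ValueError):
            group_compare(traits, strata)


def test_quality_quantity_ranks_re_rank_the_mean():
    rng = np.random.default_rng(7)
    rows = []
    for i in range(6):
        row = {"genotype_id": f"G{i}", "rank_area": float(i + 1)}
        row.update({f"rank_{n}": float(rng.integers(1, 7)) for n in FIVE_QUALITY_INDICES})
        rows.append(row)
    ledger = ledger_from_ranks(rows)
    qq = quality_quantity_ranks(ledger)
    mean_ranks = ledger[[f"rank_{n}" for n in FIVE_QUALITY_INDICES]].mean(axis=1)
    oracle = rank_column(mean_ranks, "lower_is_better")
    np.testing.assert_array_equal(qq["quality_rank"].values, oracle)
    np.testing.assert_array_equal(qq["quantity_rank"].values, ledger["rank_area"].values)
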