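"""Permutation t-tests, BH adjustment, p-ranking and progression markers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crcpathways.diffexpr import (
    adjust_bh,
    permutation_t_test,
    rank_probes_by_p,
    select_progression_markers,
)


def _frame(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        values,
        index=[f"P{i:03d}" for i in range(values.shape[0])],
        columns=samples or [f"S{j}" for j in range(values.shape[1])],
    )


def _labels(m, n1, g1="a", g2="b"):
    return pd.Series([g1] * n1 + [g2] * (m.shape[1] - n1), index=m.columns)


def bh_oracle(p):
    """Independent brute-force step-up: adj_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestPermutationTTest:
    def test_identical_constant_groups(self):
        m = _frame([[5.0] * 6])
        res = permutation_t_test(m, _labels(m, 3), n_perm=100, seed=0)
        assert res.loc["P000", "t"] == 0.0
        assert res.loc["P000", "p"] == 1.0

    def test_exhaustive_three_vs_three_max_separation(self):
        # 20 distinct splits; only the observed split and its mirror reach
        # the maximal |t| -> p = 2/20
        m = _frame([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        res = permutation_t_test(m, _labels(m, 3), n_perm=10_000, seed=0)
        assert res.loc["P000", "p"] == pytest.approx(2 / 20)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, (100, 20))
        values[:, 10:] += 2.0
        m = _frame(values)
        res = permutation_t_test(m, _labels(m, 10), n_perm=2000, seed=1)
        assert res["p"].median() < 0.01

    def test_exchangeability_of_sample_order(self):
        rng = np.random.default_rng(8)
        m = _frame(rng.normal(5, 1, (20, 10)))
        labels = _labels(m, 5)
        res1 = permutation_t_test(m, labels, n_perm=200, seed=3)
        perm = list(m.columns[::-1])
        res2 = permutation_t_test(m[perm], labels[perm], n_perm=200, seed=3)
        pd.testing.assert_frame_equal(res1, res2)

    def test_null_p_values_valid(self):
        rng = np.random.default_rng(12)
        m = _frame(rng.normal(0, 1, (2000, 12)))
        res = permutation_t_test(m, _labels(m, 6), n_perm=400, seed=5)
        for alpha in (0.01, 0.05):
            rate = float((res["p"] <= alpha).mean())
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(res))
            assert rate <= bound

    def test_group_of_one_rejected(self):
        m = _frame(np.ones((3, 5)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            permutation_t_test(m, _labels(m, 1), n_perm=10, seed=0)


class TestAdjustBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.037]), [0.037])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_saturate(self):
        np.testing.assert_allclose(adjust_bh([0.05] * 10), [0.05] * 10)

    def test_agrees_with_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_adjusted_dominates_raw_and_is_monotone(self, pvals):
        adj = adjust_bh(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRankProbes:
    def test_smaller_adjusted_p_ranks_first(self):
        stats = pd.DataFrame(
            {"t": [1.0, 3.0], "p": [0.2, 0.01], "p_adj": [0.2, 0.01]},
            index=["P000", "P001"],
        )
        assert rank_probes_by_p(stats).probe_ids == ("P001", "P000")

    def test_tie_broken_by_larger_t(self):
        stats = pd.DataFrame(
            {"t": [1.0, -3.0], "p": [0.05, 0.05], "p_adj": [0.1, 0.1]},
            index=["P000", "P001"],
        )
        assert rank_probes_by_p(stats).probe_ids == ("P001", "P000")

    def test_order_independent_of_input_order(self):
        rng = np.random.default_rng(2)
        stats = pd.DataFrame(
            {
                "t": rng.normal(size=30),
                "p": rng.random(30),
            },
            index=[f"P{i:03d}" for i in range(30)],
        )
        stats["p_adj"] = adjust_bh(stats["p"])
        shuffled = stats.sample(frac=1, random_state=9)
        assert rank_probes_by_p(stats).probe_ids == rank_probes_by_p(shuffled).probe_ids


def _marker_stats(mean_nc, mean_ad, mean_ca, p_adj, probes):
    a = pd.DataFrame(
        {
            "t": 1.0,
            "p": p_adj,
            "p_adj": p_adj,
            "mean_NC": mean_nc,
            "mean_AD": mean_ad,
        },
        index=probes,
    )
    b = pd.DataFrame(
        {
            "t": 1.0,
            "p": p_adj,
            "p_adj": p_adj,
            "mean_AD": mean_ad,
            "mean_CA": mean_ca,
        },
        index=probes,
    )
    return {"NC_vs_AD": a, "AD_vs_CA": b}


class TestProgressionMarkers:
    def test_monotone_in_all_arms_selected(self):
        arms = {k: _marker_stats(1.0, 2.0, 3.0, 0.001, ["P000"]) for k in "xyz"}
        up, down = select_progression_markers(arms)
        assert up == ["P000"] and down == []

    def test_two_of_three_arms_excluded(self):
        arms = {k: _marker_stats(1.0, 2.0, 3.0, 0.001, ["P000"]) for k in "xy"}
        arms["z"] = _marker_stats(1.0, 2.0, 3.0, 0.5, ["P000"])
        up, down = select_progression_markers(arms)
        assert up == []

    def test_non_monotone_means_excluded(self):
        arms = {"x": _marker_stats(1.0, 3.0, 2.0, 0.001, ["P000"])}
        up, down = select_progression_markers(arms)
        assert up == [] and down == []

    def test_missing_contrast_rejected(self):
        arms = {"x": {"NC_vs_AD": _marker_stats(1, 2, 3, 0.001, ["P000"])["NC_vs_AD"]}}
        with pytest.raises(ValueError, match="lacks contrast"):
            select_progression_markers(arms)

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(21)
        values = rng.normal(8, 1, (60, 30))
        values[:5, 10:20] += 1.0
        values[:5, 20:] += 2.0
        values[5:10, 10:20] -= 1.0
        values[5:10, 20:] -= 2.0
        m = _frame(values)
        labels = pd.Series(["NC"] * 10 + ["AD"] * 10 + ["CA"] * 10, index=m.columns)

        def stats_for(mat):
            out = {}
            for c, (g1, g2) in {"NC_vs_AD": ("NC", "AD"), "AD_vs_CA": ("AD", "CA")}.items():
                ids = labels.index[labels.isin([g1, g2])]
                out[c] = permutation_t_test(mat[ids], labels[ids], n_perm=500, seed=2)
            return out

        up_pos, down_pos = select_progression_markers({"arm": stats_for(m)}, alpha=0.05)
        up_neg, down_neg = select_progression_markers({"arm": stats_for(-m + 20)}, alpha=0.05)
        assert up_pos == down_neg and down_pos == up_neg

    def test_recovery_with_planted_monotone_probes(self):
        # 10 up-markers with a 1-log2 step per stage among 300 null probes
        rng = np.random.default_rng(31)
        n_per = 15
        values = rng.normal(8, 0.4, (300, 3 * n_per))
        values[:10, n_per : 2 * n_per] += 1.0
        values[:10, 2 * n_per :] += 2.0
        m = _frame(values)
        labels = pd.Series(
            ["NC"] * n_per + ["AD"] * n_per + ["CA"] * n_per, index=m.columns
        )
        stats = {}
        for c, (g1, g2) in {"NC_vs_AD": ("NC", "AD"), "AD_vs_CA": ("AD", "CA")}.items():
            ids = labels.index[labels.isin([g1, g2])]
            stats[c] = permutation_t_test(m[ids], labels[ids], n_perm=5000, seed=3)
        up, down = select_progression_markers({"arm": stats}, alpha=0.01)
        truth = {f"P{i:03d}" for i in range(10)}
        assert len(set(up) & truth) >= 9
        assert not set(up) - truth and not down
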