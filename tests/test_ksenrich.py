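"""One-sided KS rank enrichment: statistic, exact null, significance rule."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crcpathways.ksenrich import (
    asymptotic_dplus_sf,
    d_plus_from_ranks,
    exact_dplus_sf,
    ks_top_enrichment,
    pathway_probe_sets,
    significant_pathways,
    test_all_pathways as run_all_pathways,
)
from crcpathways.ranking import RankedProbeList


def _ranked(n, provenance="pairwise-p"):
    return RankedProbeList(
        probe_ids=tuple(f"P{i:04d}" for i in range(1, n + 1)),
        scores=tuple(float(i) / n for i in range(1, n + 1)),
        provenance=provenance,
    )


def brute_force_sf(d, n_total, m):
    total = hit = 0
    for ranks in combinations(range(1, n_total + 1), m):
        total += 1
        if d_plus_from_ranks(ranks, n_total) >= d - 1e-12:
            hit += 1
    return hit / total


class TestDPlus:
    def test_members_at_top(self):
        # ranks 1..5 in a list of 100: max_i(i/5 - (i-1)/100) = 0.96 at i=5
        assert d_plus_from_ranks(range(1, 6), 100) == pytest.approx(0.96)

    def test_members_at_bottom_near_null(self):
        assert d_plus_from_ranks([8, 9, 10], 10) == pytest.approx(0.1)

    def test_monotone_when_member_moves_up(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            m = int(rng.integers(2, 6))
            ranks = np.sort(rng.choice(np.arange(1, n + 1), m, replace=False))
            movable = [i for i, r in enumerate(ranks) if r - 1 not in ranks and r > 1]
            if not movable:
                continue
            i = movable[0]
            moved = ranks.copy()
            moved[i] -= 1
            assert d_plus_from_ranks(np.sort(moved), n) >= d_plus_from_ranks(ranks, n)


class TestExactNull:
    def test_matches_bruteforce_for_all_small_cases(self):
        for n in range(2, 13):
            for m in range(1, min(4, n) + 1):
                seen = {
                    d_plus_from_ranks(r, n)
                    for r in combinations(range(1, n + 1), m)
                }
                for d in seen:
                    assert exact_dplus_sf(d, n, m) == pytest.approx(
                        brute_force_sf(d, n, m), abs=1e-9
                    ), (n, m, d)

    def test_exact_p_is_enumeration_fraction(self):
        # N=10, m=3: p of any observed D+ equals the fraction of the 120
        # placements reaching it
        n, m = 10, 3
        for ranks in [(1, 2, 3), (2, 5, 9), (8, 9, 10)]:
            d = d_plus_from_ranks(ranks, n)
            assert exact_dplus_sf(d, n, m) == pytest.approx(brute_force_sf(d, n, m))

    def test_asymptotic_close_to_exact_at_scale(self):
        # at the sizes where `auto` would fall back to the iid tail
        for n, m, d in [(3000, 40, 0.1), (3000, 40, 0.2), (5000, 120, 0.08)]:
            pe = exact_dplus_sf(d, n, m)
            pa = asymptotic_dplus_sf(d, m)
            assert pa == pytest.approx(pe, rel=0.15)

    def test_uniform_null_calibration(self):
        rng = np.random.default_rng(77)
        n, m, draws = 300, 8, 2000
        pvals = np.empty(draws)
        for i in range(draws):
            ranks = np.sort(rng.choice(np.arange(1, n + 1), m, replace=False))
            pvals[i] = exact_dplus_sf(d_plus_from_ranks(ranks, n), n, m)
        for alpha in (0.01, 0.05):
            rate = float((pvals <= alpha).mean())
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / draws)
            assert rate <= bound


class TestKsTopEnrichment:
    def test_depends_only_on_ranks_not_scores(self):
        members = {"P0002", "P0010", "P0030"}
        a = ks_top_enrichment(_ranked(50), members)
        shuffled_scores = RankedProbeList(
            probe_ids=_ranked(50).probe_ids,
            scores=tuple(np.random.default_rng(0).random(50)),
            provenance="pairwise-p",
        )
        b = ks_top_enrichment(shuffled_scores, members)
        assert a == b

    def test_methods_agree_on_exact_range(self):
        members = {"P0001", "P0004", "P0009"}
        d_ex, p_ex = ks_top_enrichment(_ranked(12), members, method="exact")
        assert p_ex == pytest.approx(brute_force_sf(d_ex, 12, 3))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no pathway members"):
            ks_top_enrichment(_ranked(10), {"absent"})


class TestTestAllPathways:
    def test_single_pathway_adjustment_is_identity(self):
        ranked = _ranked(40)
        res = run_all_pathways(ranked, {"pw": set(ranked.probe_ids[:6])})
        assert res.loc["pw", "p_adj"] == pytest.approx(res.loc["pw", "p"])

    def test_small_pathway_gated_out(self):
        ranked = _ranked(40)
        res = run_all_pathways(
            ranked,
            {"small": set(ranked.probe_ids[:3]), "ok": set(ranked.probe_ids[:8])},
            min_size=5,
        )
        assert list(res.index) == ["ok"]

    def test_planted_top_pathway_wins(self, small_experiment, small_design, small_dictionary):
        from crcpathways import syndata

        annot = syndata.probe_annotation(small_design)
        probe_sets = pathway_probe_sets(small_dictionary, annot)
        # build a ranking with PW001's members at the top
        members = sorted(probe_sets["PW001"])
        rest = [p for p in annot.index if p not in set(members)]
        ranked = RankedProbeList(
            probe_ids=tuple(members + rest),
            scores=tuple(np.linspace(0, 1, len(annot))),
            provenance="pairwise-p",
        )
        res = run_all_pathways(ranked, probe_sets)
        assert res.index[0] == "PW001"
        assert res["p_adj"].iloc[0] < 0.01


class TestSignificanceRule:
    def _tables(self, p_by_arm_ordering):
        out = {}
        for arm, per in p_by_arm_ordering.items():
            out[arm] = {
                ordering: pd.DataFrame(
                    {"m": 10, "d_plus": 0.5, "p": p, "p_adj": p},
                    index=pd.Index(["pw"], name="pathway"),
                )
                for ordering, p in per.items()
            }
        return out

    def test_strict_in_one_arm_selected(self):
        res = self._tables(
            {"scaling": {"a": 0.005, "b": 0.005}, "lvs": {"a": 0.2, "b": 0.2}}
        )
        assert significant_pathways(res) == {"pw"}

    def test_lenient_in_both_arms_selected(self):
        res = self._tables(
            {"scaling": {"a": 0.03, "b": 0.03}, "lvs": {"a": 0.04, "b": 0.04}}
        )
        assert significant_pathways(res) == {"pw"}

    def test_neither_clause_not_selected(self):
        res = self._tables(
            {"scaling": {"a": 0.03, "b": 0.03}, "lvs": {"a": 0.2, "b": 0.2}}
        )
        assert significant_pathways(res) == set()

    def test_must_hold_in_every_ordering(self):
        res = self._tables(
            {"scaling": {"a": 0.005, "b": 0.5}, "lvs": {"a": 0.005, "b": 0.5}}
        )
        assert significant_pathways(res) == set()

    def test_mismatched_orderings_rejected(self):
        res = self._tables({"scaling": {"a": 0.005}, "lvs": {"b": 0.005}})
        with pytest.raises(ValueError, match="orderings"):
            significant_pathways(res)
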