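"""One-sided Kolmogorov-Smirnov rank-position enrichment.

Given a totally ordered probe list and a pathway with member ranks
``r_1 < ... < r_m`` among ``N`` probes, the statistic

    D+ = max_i ( i/m - (r_i - 1)/N )

measures how much the member-rank ECDF runs ahead of the uniform
distribution, i.e. how strongly the members concentrate at the top of the
list.  Under the null the members are an exchangeable random m-subset of the
N positions; the exact tail P(D+ >= d) over all C(N, m) placements is
computed by a lattice-path count (equivalent to full enumeration), with the
one-sided iid tail (Birnbaum-Tingey, effective size m) available as an
asymptotic alternative for very large member counts.
"""

from __future__ import annotations

from math import comb
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffexpr import adjust_bh
from .ranking import RankedProbeList

__all__ = [
    "d_plus_from_ranks",
    "exact_dplus_sf",
    "asymptotic_dplus_sf",
    "ks_top_enrichment",
    "pathway_probe_sets",
    "test_all_pathways",
    "significant_pathways",
]

#: `auto` method uses the exact lattice count while the DP table N*m stays
#: below this; beyond it the iid tail is an excellent approximation anyway.
_EXACT_CELLS = 5_000_000


def d_plus_from_ranks(ranks, n_total: int) -> float:
    """D+ for 1-based member ranks within a list of ``n_total`` probes."""
    r = np.sort(np.asarray(ranks, dtype=float))
    m = len(r)
    if m == 0:
        raise ValueError("no member ranks")
    if r[0] < 1 or r[-1] > n_total:
        raise ValueError("ranks outside 1..N")
    i = np.arange(1, m + 1, dtype=float)
    return float(np.max(i / m - (r - 1.0) / n_total))


def exact_dplus_sf(d: float, n_total: int, m: int) -> float:
    """Exact P(D+ >= d) over all C(N, m) member placements.

    Counts the placements with D+ < d by a cumulative-sum recursion over the
    admissible rank of each successive member: D+ < d iff every member i sits
    at a rank strictly greater than N*(i/m - d) + 1.  Identical to brute
    force enumeration, in O(N*m) time.
    """
    if m < 1 or m > n_total:
        raise ValueError("need 1 <= m <= N")
    if d <= 1.0 / m - (n_total - 1.0) / n_total - 1e-12:
        return 1.0  # below the smallest attainable D+
    if d > 1.0:
        return 0.0
    # minimal avoiding rank for member i: smallest integer > N*(i/m - d) + 1
    i = np.arange(1, m + 1, dtype=float)
    v = n_total * (i / m - d) + 1.0
    b = np.floor(v + 1e-9).astype(np.int64) + 1
    b = np.maximum(b, 1)
    if (b + (m - np.arange(1, m + 1)) > n_total).any():
        return 1.0  # avoiding is impossible: every placement reaches d
    # f[r] = number of ways to place the first i members with member i at rank r
    f = np.zeros(n_total + 1)
    f[b[0]:] = 1.0
    log_scale = 0.0
    for idx in range(1, m):
        c = np.concatenate(([0.0], np.cumsum(f)[:-1]))  # sum over ranks < r
        f = c
        f[: b[idx]] = 0.0
        total = f.sum()
        if total == 0.0:
            return 1.0
        if total > 1e250:
            f /= total
            log_scale += np.log(total)
    log_count = np.log(f.sum()) + log_scale
    log_c = gammaln(n_total + 1) - gammaln(m + 1) - gammaln(n_total - m + 1)
    p = 1.0 - np.exp(log_count - log_c)
    return float(min(max(p, 1e-300), 1.0))


def asymptotic_dplus_sf(d: float, m: int) -> float:
    """One-sided iid KS tail (Birnbaum-Tingey) with effective size ``m``."""
    return float(min(max(stats.ksone.sf(d, m), 1e-300), 1.0))


def ks_top_enrichment(
    ranked: RankedProbeList,
    members: Collection[str],
    method: str = "auto",
) -> tuple[float, float]:
    """(D+, p) for the members' concentration at the top of the ranked list.

    Members absent from the list are ignored; an empty intersection is an
    error.  ``method`` is ``"exact"``, ``"asymptotic"`` or ``"auto"``
    (exact while the null table stays small, asymptotic beyond).
    """
    n_total = len(ranked)
    if n_total < 2:
        raise ValueError("ranked universe must contain >= 2 probes")
    ranks = ranked.ranks_of(members)
    m = len(ranks)
    if m == 0:
        raise ValueError("no pathway members present in the ranked universe")
    d = d_plus_from_ranks(ranks, n_total)
    if method == "auto":
        method = "exact" if n_total * m <= _EXACT_CELLS else "asymptotic"
    if method == "exact":
        p = exact_dplus_sf(d, n_total, m)
    elif method == "asymptotic":
        p = asymptotic_dplus_sf(d, m)
    else:
        raise ValueError(f"unknown method {method!r}")
    return d, p


def pathway_probe_sets(
    dictionary: Mapping[str, Collection[str]],
    probe_annotation: pd.DataFrame,
) -> dict[str, set[str]]:
    """Map gene-symbol sets onto probe-id sets via the annotation table.

    A probe belongs to a pathway iff its gene symbol does; multiple probes
    per gene all inherit the membership.
    """
    by_gene: dict[str, list[str]] = {}
    for probe, gene in probe_annotation["gene_symbol"].items():
        by_gene.setdefault(gene, []).append(probe)
    out: dict[str, set[str]] = {}
    for name, genes in dictionary.items():
        probes: set[str] = set()
        for g in genes:
            probes.update(by_gene.get(g, ()))
        out[name] = probes
    return out


def test_all_pathways(
    ranked: RankedProbeList,
    probe_sets: Mapping[str, Collection[str]],
    min_size: int = 5,
    method: str = "auto",
) -> pd.DataFrame:
    """KS top-enrichment of every pathway with >= ``min_size`` members in the
    ranked universe, BH-adjusted across the tested pathways.

    Returns a DataFrame indexed by pathway id with columns ``m``,
    ``d_plus``, ``p`` and ``p_adj``, sorted by adjusted p (ties by id).
    """
    if not probe_sets:
        raise ValueError("empty pathway dictionary")
    rows = []
    for name in sorted(probe_sets):
        ranks = ranked.ranks_of(probe_sets[name])
        if len(ranks) < min_size:
            continue
        d = d_plus_from_ranks(ranks, len(ranked))
        if method == "auto":
            use = "exact" if len(ranked) * len(ranks) <= _EXACT_CELLS else "asymptotic"
        else:
            use = method
        p = (
            exact_dplus_sf(d, len(ranked), len(ranks))
            if use == "exact"
            else asymptotic_dplus_sf(d, len(ranks))
        )
        rows.append((name, len(ranks), d, p))
    result = pd.DataFrame(
        rows, columns=["pathway", "m", "d_plus", "p"]
    ).set_index("pathway")
    if len(result):
        result["p_adj"] = adjust_bh(result["p"].to_numpy())
        result = result.sort_index().sort_values(["p_adj", "p"], kind="stable")
    else:
        result["p_adj"] = []
    return result


def significant_pathways(
    results_by_arm: Mapping[str, Mapping[str, pd.DataFrame]],
    strict_alpha: float = 0.01,
    lenient_alpha: float = 0.05,
) -> set[str]:
    """Pathways passing the dual-normalization significance rule in every ordering.

    ``results_by_arm`` maps each normalization arm to its per-ordering
    enrichment tables (the same orderings in every arm).  A pathway is
    selected iff, in each ordering, its adjusted p is below ``strict_alpha``
    in at least one arm, or below ``lenient_alpha`` in all arms.
    """
    if not results_by_arm:
        raise ValueError("no normalization arms supplied")
    orderings = None
    for arm, per_ordering in results_by_arm.items():
        keys = set(per_ordering)
        if not keys:
            raise ValueError(f"arm {arm!r} has no orderings")
        if orderings is None:
            orderings = keys
        elif keys != orderings:
            raise ValueError(
                f"arm {arm!r} orderings {sorted(keys)} differ from {sorted(orderings)}"
            )
    selected: set[str] | None = None
    arms = list(results_by_arm)
    for ordering in sorted(orderings):
        tables = {arm: results_by_arm[arm][ordering]["p_adj"] for arm in arms}
        universe = set().union(*(set(t.index) for t in tables.values()))
        chosen = set()
        for pw in universe:
            padj = [float(t[pw]) for t in tables.values() if pw in t.index]
            strict = any(v < strict_alpha for v in padj)
            lenient = len(padj) == len(arms) and all(v < lenient_alpha for v in padj)
            if strict or lenient:
                chosen.add(pw)
        selected = chosen if selected is None else selected & chosen
    return selected or set()
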