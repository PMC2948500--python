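"""Supervised probe ranking.

Per-probe two-group Welch t statistics with permutation p-values (exhaustive
over label splits when feasible, otherwise Monte Carlo with a +1 correction),
Benjamini-Hochberg FDR adjustment, p-value-ordered probe lists, and the
monotone progression-marker screen over the normal -> adenoma -> carcinoma
sequence.

Statistics are computed on whatever scale the caller supplies; the pipeline
passes log2 intensities.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ranking import RankedProbeList

__all__ = [
    "permutation_t_test",
    "adjust_bh",
    "rank_probes_by_p",
    "select_progression_markers",
]

_CHUNK = 512  # permutations per matrix-product block


def _welch_t(s1, q1, n1, s_tot, q_tot, n):
    """Welch t from per-group sums and sums of squares; 0/0 -> t = 0."""
    n2 = n - n1
    mean1 = s1 / n1
    mean2 = (s_tot - s1) / n2
    var1 = np.maximum(q1 - n1 * mean1**2, 0.0) / (n1 - 1)
    var2 = np.maximum((q_tot - q1) - n2 * mean2**2, 0.0) / (n2 - 1)
    se = np.sqrt(var1 / n1 + var2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / se
    return np.where(se == 0.0, 0.0, t)


def permutation_t_test(
    m: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-probe Welch t with a two-sided permutation p-value.

    ``labels`` assigns each sample to one of exactly two groups; the t
    statistic is mean(first group) - mean(second group) with groups in
    sorted label order.  When the number of distinct label splits C(n, n1)
    does not exceed ``n_perm`` all splits are enumerated and
    ``p = #{splits : |t*| >= |t|} / #splits`` (the observed split is one of
    them, so p > 0); otherwise ``n_perm`` random splits are drawn and
    ``p = (1 + #{|t*| >= |t|}) / (1 + n_perm)``.

    Returns a DataFrame indexed by probe id with columns ``t``, ``p``,
    ``p_adj`` and ``mean_<group>`` for both groups.
    """
    labels = pd.Series(labels).reindex(m.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    g1, g2 = names
    mask1 = (labels == g1).to_numpy()
    n = len(labels)
    n1 = int(mask1.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("each group needs >= 2 samples")

    X = m.to_numpy(dtype=float)
    X2 = X**2
    s_tot = X.sum(axis=1)
    q_tot = X2.sum(axis=1)
    t_obs = _welch_t(X[:, mask1].sum(axis=1), X2[:, mask1].sum(axis=1), n1, s_tot, q_tot, n)
    abs_obs = np.abs(t_obs)
    tol = 1e-8 * (1.0 + abs_obs)

    n_total = comb(n, n1)
    exhaustive = n_total <= n_perm
    if exhaustive:
        indicator = np.zeros((n, n_total))
        for b, idx in enumerate(combinations(range(n), n1)):
            indicator[list(idx), b] = 1.0
    else:
        # draw label subsets in a canonical (sorted-sample-id) order so the
        # Monte Carlo p-values are invariant to permuting the input columns
        rng = np.random.default_rng(seed)
        canon = np.argsort(m.columns.to_numpy(), kind="stable")
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
        ind_canon = np.zeros((n_perm, n))
        np.put_along_axis(ind_canon, order, 1.0, axis=1)
        indicator = np.zeros((n, n_perm))
        indicator[canon, :] = ind_canon.T

    exceed = np.zeros(X.shape[0], dtype=np.int64)
    for start in range(0, indicator.shape[1], _CHUNK):
        block = indicator[:, start : start + _CHUNK]
        s1 = X @ block
        q1 = X2 @ block
        t_perm = _welch_t(s1, q1, n1, s_tot[:, None], q_tot[:, None], n)
        exceed += (np.abs(t_perm) >= (abs_obs - tol)[:, None]).sum(axis=1)

    if exhaustive:
        p = exceed / n_total
    else:
        p = (1 + exceed) / (1 + n_perm)
    out = pd.DataFrame(
        {
            "t": t_obs,
            "p": p,
            "p_adj": adjust_bh(p),
            f"mean_{g1}": X[:, mask1].mean(axis=1),
            f"mean_{g2}": X[:, ~mask1].mean(axis=1),
        },
        index=m.index,
    )
    return out


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def rank_probes_by_p(stats: pd.DataFrame) -> RankedProbeList:
    """Order probes by ascending adjusted p; ties broken by raw p, then by
    |t| descending, then by probe id."""
    order = sorted(
        range(len(stats)),
        key=lambda i: (
            stats["p_adj"].iat[i],
            stats["p"].iat[i],
            -abs(stats["t"].iat[i]),
            stats.index[i],
        ),
    )
    return RankedProbeList(
        probe_ids=tuple(stats.index[i] for i in order),
        scores=tuple(float(stats["p_adj"].iat[i]) for i in order),
        provenance="pairwise-p",
    )


def select_progression_markers(
    stats_by_arm: Mapping[object, Mapping[str, pd.DataFrame]],
    alpha: float = 0.01,
    group_order: tuple[str, str, str] = ("NC", "AD", "CA"),
) -> tuple[list[str], list[str]]:
    """Probes with monotone expression across the progression sequence.

    ``stats_by_arm`` maps an arm key — typically a (sample set,
    normalization) pair — to the two adjacent-contrast statistics tables,
    keyed ``"<g0>_vs_<g1>"`` and ``"<g1>_vs_<g2>"``, each carrying
    ``mean_<group>`` columns and BH-adjusted p-values.  A probe is "up" in an
    arm iff its group means increase strictly at both steps and both
    adjacent contrasts are significant at ``alpha`` (FDR-adjusted);
    symmetrically for "down".  The returned up/down sets are the
    intersections across all arms supplied.
    """
    if not stats_by_arm:
        raise ValueError("no arms supplied")
    g0, g1, g2 = group_order
    c01, c12 = f"{g0}_vs_{g1}", f"{g1}_vs_{g2}"
    up: set[str] | None = None
    down: set[str] | None = None
    for key, contrasts in stats_by_arm.items():
        if c01 not in contrasts or c12 not in contrasts:
            raise ValueError(f"arm {key!r} lacks contrast {c01!r} or {c12!r}")
        s01, s12 = contrasts[c01], contrasts[c12]
        common = s01.index.intersection(s12.index)
        a, b = s01.loc[common], s12.loc[common]
        sig = (a["p_adj"] < alpha) & (b["p_adj"] < alpha)
        arm_up = set(
            common[
                sig
                & (a[f"mean_{g0}"] < a[f"mean_{g1}"])
                & (b[f"mean_{g1}"] < b[f"mean_{g2}"])
            ]
        )
        arm_down = set(
            common[
                sig
                & (a[f"mean_{g0}"] > a[f"mean_{g1}"])
                & (b[f"mean_{g1}"] > b[f"mean_{g2}"])
            ]
        )
        up = arm_up if up is None else up & arm_up
        down = arm_down if down is None else down & arm_down
    return sorted(up or ()), sorted(down or ())
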