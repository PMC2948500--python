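"""Between-array normalization arms.

Matrix-level emulations of the two normalization contracts the pipeline
compares: per-array global scaling to a common trimmed mean (the MAS5-style
arm) and least-variant-set (LVS) normalization, which anchors a robust
per-array monotone correction on the probes most stable in rank across
arrays.  Quantile normalization is included as the baseline that LVS
replaces.

All functions take and return probe x sample DataFrames of linear-scale
intensities and never modify their input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_expression_matrix

__all__ = [
    "LeastVariantSet",
    "global_scaling_normalize",
    "quantile_normalize",
    "select_least_variant_set",
    "lvs_normalize",
]

#: smallest intensity used when taking logs; simulated and scanner
#: intensities are strictly positive but filtering can in principle leave
#: zeros from degenerate inputs.
_LOG_FLOOR = 2.0**-10


@dataclass(frozen=True)
class LeastVariantSet:
    """Probes with the most stable within-array ranks, plus the fraction asked for."""

    probe_ids: tuple[str, ...]
    proportion: float


def global_scaling_normalize(
    m: pd.DataFrame, trim_fraction: float = 0.02, target: float = 500.0
) -> pd.DataFrame:
    """Scale each array so its two-sided trimmed mean equals ``target``.

    ``trim_fraction`` is the fraction cut from each tail before averaging.
    Afterwards every column's trimmed mean equals ``target`` to within 1e-9
    relative, and the result is invariant to pre-multiplying any column by a
    positive constant.
    """
    validate_expression_matrix(m)
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if target <= 0:
        raise ValueError("target must be positive")
    values = m.to_numpy(dtype=float)
    tm = stats.trim_mean(values, trim_fraction, axis=0)
    if (tm <= 0).any():
        bad = m.columns[tm <= 0].tolist()
        raise ValueError(f"degenerate column(s) with trimmed mean <= 0: {bad}")
    return pd.DataFrame(values * (target / tm)[None, :], index=m.index, columns=m.columns)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean of sorted columns.

    Ties within a column receive the mean of the reference values they span
    (mid-rank convention), so identical columns pass through unchanged.
    """
    validate_expression_matrix(m)
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = m.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def select_least_variant_set(m: pd.DataFrame, proportion: float = 0.6) -> LeastVariantSet:
    """Rank probes by the variance of their within-array ranks and keep the
    lowest ``proportion`` fraction.

    Rank variance is invariant to any monotone per-array transformation, so
    the selection sees through both scale factors and smooth rank
    distortions.  Ties are broken by probe id; the set size is
    ``round(proportion * n_probes)`` (half away from zero).
    """
    validate_expression_matrix(m)
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    if m.shape[1] < 2:
        raise ValueError("need >= 2 samples to measure rank variance")
    values = m.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    rank_var = ranks.var(axis=1, ddof=1)
    k = int(np.floor(proportion * m.shape[0] + 0.5))
    order = sorted(range(m.shape[0]), key=lambda i: (rank_var[i], m.index[i]))
    chosen = sorted(m.index[i] for i in order[:k])
    return LeastVariantSet(probe_ids=tuple(chosen), proportion=proportion)


def lvs_normalize(m: pd.DataFrame, lvs: LeastVariantSet) -> pd.DataFrame:
    """Normalize each array by a robust linear fit of its LVS probes' log
    intensities onto the LVS reference profile (across-array median).

    The fitted map (Theil-Sen slope and intercept on log2 intensities,
    estimated on a deterministic quantile-spread subsample of the LVS probes)
    is applied to all probes of the array, so arrays differing by a global
    factor or a smooth log-linear distortion are brought onto the reference
    exactly while probes outside the LVS set keep their biological
    differences.
    """
    validate_expression_matrix(m)
    if len(lvs.probe_ids) < 10:
        raise ValueError("insufficient reference: LVS must contain >= 10 probes")
    missing = set(lvs.probe_ids) - set(m.index)
    if missing:
        raise ValueError(f"LVS probes absent from matrix: {sorted(missing)[:5]}")
    log_all = np.log2(np.maximum(m.to_numpy(dtype=float), _LOG_FLOOR))
    lvs_pos = m.index.get_indexer(list(lvs.probe_ids))
    log_lvs = log_all[lvs_pos, :]
    reference = np.median(log_lvs, axis=1)
    # deterministic subsample spread over the reference quantiles keeps the
    # O(n^2) pairwise-slope estimator tractable on large LVS sets
    max_fit = 400
    if len(reference) > max_fit:
        fit_idx = np.unique(
            np.argsort(reference, kind="stable")[
                np.linspace(0, len(reference) - 1, max_fit).round().astype(int)
            ]
        )
    else:
        fit_idx = np.arange(len(reference))
    out = np.empty_like(log_all)
    for j in range(log_all.shape[1]):
        x = log_lvs[fit_idx, j]
        y = reference[fit_idx]
        if np.ptp(x) == 0:
            slope, intercept = 1.0, float(np.median(y - x))
        else:
            slope, intercept, _, _ = stats.theilslopes(y, x)
        out[:, j] = intercept + slope * log_all[:, j]
    return pd.DataFrame(np.exp2(out), index=m.index, columns=m.columns)
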