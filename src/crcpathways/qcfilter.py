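"""Probe-set filtering.

Two rules are applied to each normalized matrix before ranking:

1. a detection filter — a probe must exceed a detection threshold in at
   least 5% of samples, the threshold being the 98th percentile of Y-linked
   probe intensities in female samples (where those probes measure only
   background);
2. for whole-tissue-section data, a variation filter — a probe must deviate
   from its own median by more than 1.5-fold in at least 6 samples.

Both filters keep the sample set and probe order unchanged and are
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable

import numpy as np
import pandas as pd

from .io import validate_expression_matrix

__all__ = [
    "DetectionThreshold",
    "compute_detection_threshold",
    "filter_expressed",
    "filter_fold_change",
]


@dataclass(frozen=True)
class DetectionThreshold:
    """A detection limit on the matrix's intensity scale with its provenance."""

    value: float
    percentile: float
    n_female_samples: int
    n_y_probes: int


def compute_detection_threshold(
    m: pd.DataFrame,
    y_probes: Iterable[str],
    female_samples: Iterable[str],
    percentile: float = 98.0,
) -> DetectionThreshold:
    """Nearest-rank percentile of the pooled Y-probe x female-sample signals.

    The nearest-rank convention takes the ``ceil(p/100 * n)``-th order
    statistic of the pooled values, so ``percentile=100`` returns the pool
    maximum.  Invariant under any permutation of probes or samples.
    """
    validate_expression_matrix(m)
    y_probes = [p for p in y_probes]
    female_samples = [s for s in female_samples]
    if not y_probes or not female_samples:
        raise ValueError("Y-probe and female-sample sets must be nonempty")
    missing_p = set(y_probes) - set(m.index)
    missing_s = set(female_samples) - set(m.columns)
    if missing_p or missing_s:
        raise ValueError(
            f"ids absent from matrix: probes {sorted(missing_p)[:3]}, "
            f"samples {sorted(missing_s)[:3]}"
        )
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")
    pool = np.sort(m.loc[y_probes, female_samples].to_numpy(dtype=float).ravel())
    k = min(max(ceil(percentile / 100.0 * pool.size), 1), pool.size)
    return DetectionThreshold(
        value=float(pool[k - 1]),
        percentile=percentile,
        n_female_samples=len(female_samples),
        n_y_probes=len(y_probes),
    )


def filter_expressed(
    m: pd.DataFrame, t: DetectionThreshold, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Keep probes strictly above the threshold in >= ceil(min_fraction * n) samples."""
    validate_expression_matrix(m)
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    need = ceil(min_fraction * m.shape[1])
    keep = (m.to_numpy(dtype=float) > t.value).sum(axis=1) >= need
    return m.loc[keep]


def filter_fold_change(
    m: pd.DataFrame, fc: float = 1.5, min_samples: int = 6
) -> pd.DataFrame:
    """Keep probes whose fold change versus their own median exceeds ``fc``
    in at least ``min_samples`` samples.

    The fold change in sample j is two-sided: ``max(x_j/med, med/x_j)`` with
    ``med`` the probe's median across all samples, so both induced and
    repressed deviations count.  A probe whose median is zero has no defined
    fold change and raises.
    """
    validate_expression_matrix(m)
    if fc <= 1.0:
        raise ValueError("fc must exceed 1")
    if m.shape[1] < min_samples:
        raise ValueError("fewer samples than min_samples")
    values = m.to_numpy(dtype=float)
    med = np.median(values, axis=1)
    if (med == 0).any():
        bad = m.index[med == 0].tolist()
        raise ValueError(f"degenerate probe(s) with zero median: {bad[:5]}")
    with np.errstate(divide="ignore"):
        ratio = values / med[:, None]
        fold = np.maximum(ratio, 1.0 / ratio)
    keep = (fold > fc).sum(axis=1) >= min_samples
    return m.loc[keep]
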