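"""Unsupervised probe ranking by SVD mode contribution.

The expression matrix (probes x samples, typically log2 of normalized
intensities) is decomposed into orthogonal variability modes ("supergenes").
Each mode has per-probe loadings, per-sample scores and a variance fraction;
probes are ranked by absolute loading on a chosen mode.  The sample scores of
the leading mode double as a diagnostic: tumor samples whose score falls on
the normal side of the between-group midpoint — typically low-malignant-
content specimens — can be flagged for exclusion from supervised contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .ranking import RankedProbeList

__all__ = ["SVDModes", "decompose", "rank_probes_by_mode", "flag_low_separation_samples"]


@dataclass(frozen=True)
class SVDModes:
    """A thin SVD of a (optionally probe-centered) expression matrix.

    ``loadings`` is probes x modes (left singular vectors), ``scores`` is
    samples x modes (right singular vectors scaled by the singular values).
    Modes are oriented so the largest-|loading| probe of each mode has a
    positive loading, which makes results reproducible across linear-algebra
    backends.
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    singular_values: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    centered: bool

    @property
    def n_modes(self) -> int:
        return len(self.singular_values)


def decompose(m: pd.DataFrame, center: bool = True) -> SVDModes:
    """Thin SVD of the matrix; with ``center=True`` probe-wise means are
    removed first (the decomposition then describes covariation around each
    probe's average)."""
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 probes and >= 2 samples")
    X = m.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # orient each mode: the largest-|loading| probe loads positively
    for k in range(len(s)):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    total = float((s**2).sum())
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return SVDModes(
        probe_ids=tuple(m.index),
        sample_ids=tuple(m.columns),
        singular_values=s,
        loadings=U,
        scores=Vt.T * s[None, :],
        variance_fraction=var_frac,
        centered=center,
    )


def rank_probes_by_mode(modes: SVDModes, k: int = 1) -> RankedProbeList:
    """Probes ordered by descending absolute loading on mode ``k`` (1-based);
    ties broken by probe id.  Invariant under a global sign flip of the mode."""
    if not 1 <= k <= modes.n_modes:
        raise ValueError(f"mode index {k} outside 1..{modes.n_modes}")
    contrib = np.abs(modes.loadings[:, k - 1])
    order = sorted(range(len(contrib)), key=lambda i: (-contrib[i], modes.probe_ids[i]))
    return RankedProbeList(
        probe_ids=tuple(modes.probe_ids[i] for i in order),
        scores=tuple(float(contrib[i]) for i in order),
        provenance=f"svd-mode-{k}",
    )


def flag_low_separation_samples(
    modes: SVDModes,
    k: int,
    labels: pd.Series | Mapping[str, str],
    case_group: str,
) -> list[str]:
    """Case-group samples whose mode-``k`` score falls on the control side of
    the midpoint between the two groups' score medians.

    Advisory only: with tissue specimens this typically picks out tumors
    whose malignant-cell content is too low for the tumor expression program
    to dominate, and the caller decides whether to drop them from supervised
    comparisons.
    """
    if not 1 <= k <= modes.n_modes:
        raise ValueError(f"mode index {k} outside 1..{modes.n_modes}")
    labels = pd.Series(labels).reindex(list(modes.sample_ids))
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    if case_group not in names:
        raise ValueError(f"case_group {case_group!r} not among labels {names}")
    control_group = names[0] if names[1] == case_group else names[1]
    scores = pd.Series(modes.scores[:, k - 1], index=list(modes.sample_ids))
    med_case = scores[labels == case_group].median()
    med_ctrl = scores[labels == control_group].median()
    midpoint = 0.5 * (med_case + med_ctrl)
    direction = np.sign(med_case - med_ctrl)
    case_scores = scores[labels == case_group]
    flagged = case_scores.index[(case_scores - midpoint) * direction <= 0]
    return sorted(flagged)
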