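"""Ranked probe lists shared between the supervised and unsupervised orderings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["RankedProbeList"]


@dataclass(frozen=True)
class RankedProbeList:
    """A total ordering of probe identifiers with the score that produced it.

    ``provenance`` records how the order was obtained, e.g. ``"pairwise-p"``
    for a permutation-test ordering or ``"svd-mode-1"`` for an ordering by
    absolute loading on the first SVD mode.  Rank 1 is the top of the list
    (most significant / largest contribution).
    """

    probe_ids: tuple[str, ...]
    scores: tuple[float, ...]
    provenance: str
    _positions: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.probe_ids) != len(self.scores):
            raise ValueError("probe_ids and scores differ in length")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("ranked list contains duplicate probe ids")
        object.__setattr__(
            self, "_positions", {p: i + 1 for i, p in enumerate(self.probe_ids)}
        )

    def __len__(self) -> int:
        return len(self.probe_ids)

    def ranks_of(self, members: Iterable[str]) -> np.ndarray:
        """1-based ranks of the members present in the list, ascending."""
        ranks = sorted(self._positions[p] for p in members if p in self._positions)
        return np.asarray(ranks, dtype=np.int64)
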