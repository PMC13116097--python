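"""Shared ranking primitives: scores -> integer ranks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MethodResult", "assign_ranks"]


@dataclass(frozen=True)
class MethodResult:
    """Per-alternative scores and the integer ranks they induce."""

    method: str
    alternatives: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray
    better_direction: str  # "lower" or "higher"

    def rank_of(self, alternative: str) -> int:
        return int(self.ranks[self.alternatives.index(alternative)])

    def score_of(self, alternative: str) -> float:
        return float(self.scores[self.alternatives.index(alternative)])


def assign_ranks(scores: np.ndarray, better_direction: str) -> np.ndarray:
    """Competition ("min") ranking of scores.

    The best score gets rank 1; exact ties share the smallest rank and
    the following rank is skipped (1, 1, 3 ...).  Reporting order is the
    input order, so ranking is deterministic.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot rank an empty score list")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if better_direction == "lower":
        key = s
    elif better_direction == "higher":
        key = -s
    else:
        raise ValueError(
            f"better_direction must be 'lower' or 'higher', "
            f"got {better_direction!r}"
        )
    # rank = 1 + number of strictly better scores (competition rule)
    ranks = 1 + (key[None, :] < key[:, None]).sum(axis=1)
    return ranks.astype(int)
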