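"""Rank-concordance assessment between two ranking methods.

Spearman's rho on the produced rank vectors, per-alternative rank
shifts, and top-k / bottom-k stability sets.  For tie-free permutations
the classic formula ``rho = 1 - 6 * sum(d_i^2) / (m (m^2 - 1))`` is
exact; with ties the standard tie-safe definition (Pearson correlation
of average ranks) applies, which this module delegates to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ranking import MethodResult

__all__ = ["ConcordanceReport", "spearman_rho", "build_report"]


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between two rankings of the same alternatives."""

    alternatives: tuple[str, ...]
    ranks_a: np.ndarray
    ranks_b: np.ndarray
    rho: float
    shifts: np.ndarray  # rank_a - rank_b per alternative
    stable_top: tuple[str, ...]  # in the top-k of both rankings
    stable_bottom: tuple[str, ...]  # in the bottom-k of both
    k: int


def spearman_rho(ranks_a, ranks_b) -> float:
    """Spearman rank correlation of two rank vectors.

    Tie-safe: equivalent to Pearson correlation of (average) ranks, and
    for tie-free permutations of 1..m equal to the d^2 formula.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"rank vectors must be 1-D and equal length, "
            f"got shapes {a.shape} and {b.shape}"
        )
    if a.size < 2:
        raise ValueError("need at least 2 alternatives")
    return float(stats.spearmanr(a, b).statistic)


def build_report(
    result_a: MethodResult, result_b: MethodResult, k: int = 5
) -> ConcordanceReport:
    """Compare two method results over the same alternative set."""
    if result_a.alternatives != result_b.alternatives:
        raise ValueError("method results rank different alternative sets")
    if k < 1:
        raise ValueError("k must be >= 1")
    alts = result_a.alternatives
    ra = np.asarray(result_a.ranks)
    rb = np.asarray(result_b.ranks)
    m = len(alts)
    top = tuple(
        a for a, x, y in zip(alts, ra, rb) if x <= k and y <= k
    )
    bottom = tuple(
        a for a, x, y in zip(alts, ra, rb) if x > m - k and y > m - k
    )
    return ConcordanceReport(
        alternatives=alts,
        ranks_a=ra,
        ranks_b=rb,
        rho=spearman_rho(ra, rb),
        shifts=ra - rb,
        stable_top=top,
        stable_bottom=bottom,
        k=k,
    )
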