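"""MAIRCA ranking: total gap between theoretical and real evaluations.

MAIRCA (Multi Attributive Ideal Real Comparative Analysis) gives every
alternative the same prior preference ``P = 1/m`` and spreads it over
criteria by the weights, forming a theoretical evaluation matrix
``Tp_ij = P * w_j`` whose rows are identical.  The real evaluation
matrix scales each theoretical cell by the direction-aware min-max
normalized value, ``Tr_ij = Tp_ij * r_ij``, so an alternative that
attains the column best realizes its full theoretical credit there.
The per-cell gap is ``g_ij = Tp_ij - Tr_ij`` and the score is the total
gap ``G_i = sum_j g_ij``; the smallest total gap wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .critic import WeightVector
from .decision_matrix import (
    ConfigurationError,
    DecisionMatrix,
    minmax_normalize,
)
from .ranking import MethodResult, assign_ranks

__all__ = ["MaircaArtifacts", "mairca_rank"]


@dataclass(frozen=True)
class MaircaArtifacts:
    """Intermediate matrices of a MAIRCA run."""

    priority: float  # P = 1/m, uniform
    theoretical: np.ndarray  # (m, n) Tp_ij = P * w_j
    real: np.ndarray  # (m, n) Tr_ij
    gap: np.ndarray  # (m, n) g_ij = Tp_ij - Tr_ij
    total_gap: np.ndarray  # (m,) G_i


def _coerce_weights(weights, n: int) -> np.ndarray:
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(
        weights, dtype=float
    )
    if w.shape != (n,):
        raise ConfigurationError(
            f"weight vector length {w.size} does not match {n} criteria"
        )
    if abs(w.sum() - 1.0) > 1e-6:
        raise ConfigurationError(f"weights must sum to 1, got {w.sum()!r}")
    return w


def mairca_rank(
    matrix: DecisionMatrix, weights
) -> tuple[MethodResult, MaircaArtifacts]:
    """Score and rank alternatives by total gap (lower is better).

    ``weights`` may be a :class:`~healthrank.critic.WeightVector` or a
    plain array summing to 1 (e.g. published rounded weights for
    table-reproduction checks).
    """
    m, n = matrix.shape
    w = _coerce_weights(weights, n)
    priority = 1.0 / m
    tp = np.tile(priority * w, (m, 1))
    tr = tp * minmax_normalize(matrix)
    gap = tp - tr
    total = gap.sum(axis=1)
    result = MethodResult(
        method="MAIRCA",
        alternatives=tuple(matrix.alternatives),
        scores=total,
        ranks=assign_ranks(total, "lower"),
        better_direction="lower",
    )
    return result, MaircaArtifacts(priority, tp, tr, gap, total)
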