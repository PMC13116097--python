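"""MARCOS ranking: utility relative to ideal and anti-ideal references.

MARCOS (Measurement of Alternatives and Ranking according to Compromise
Solution) appends two reference rows to the decision matrix: the ideal
solution AI (per-column best observed value) and the anti-ideal AAI
(per-column worst).  Ratio normalization maps benefit columns to
``x_ij / x_AI_j``.  For cost columns two variants exist:

``ideal_referenced`` (default)
    ``n_ij = x_AI_j / x_ij`` — the ideal row normalizes to exactly 1 in
    every column, so ``S_AI = sum_j w_j = 1`` and the utility degree
    ``K+ = S_i / S_AI`` lies in (0, 1].  This is the internally
    consistent form: the ideal is the utility ceiling.

``anti_ideal_referenced``
    ``n_ij = x_AAI_j / x_ij`` — an alternative form found in print, under
    which the *anti-ideal* row normalizes to 1 and ``K+`` can exceed 1.
    Kept behind a flag for fidelity comparisons; it does not make the
    ideal the ceiling and is not the default.

After weighting (``v_ij = n_ij * w_j``) each row is summed to ``S_i``,
including ``S_AI`` and ``S_AAI`` for the reference rows, and utility
degrees are ``K+_i = S_i / S_AI`` and ``K-_i = S_i / S_AAI``.  The final
utility also has two variants:

``standard_compromise`` (default)
    The MARCOS utility function,
    ``f_i = (K+ + K-) / (1 + (1 - f(K+))/f(K+) + (1 - f(K-))/f(K-))``
    with ``f(K+) = K-/(K+ + K-)`` and ``f(K-) = K+/(K+ + K-)``;
    always in (0, 1).

``simple_mean``
    The simple average ``(K+ + K-)/2``.  Monotone in ``S_i`` like the
    compromise form (so it induces the same ordering) but can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_matrix import DecisionMatrix
from .mairca import _coerce_weights
from .ranking import MethodResult, assign_ranks

__all__ = [
    "MarcosArtifacts",
    "extend_with_references",
    "marcos_normalize",
    "marcos_rank",
]

NORMALIZATION_VARIANTS = ("ideal_referenced", "anti_ideal_referenced")
UTILITY_VARIANTS = ("standard_compromise", "simple_mean")


class DegenerateAntiIdealError(ValueError):
    """Anti-ideal utility S_AAI is zero; utility degrees undefined."""


@dataclass(frozen=True)
class MarcosArtifacts:
    """Intermediate quantities of a MARCOS run."""

    ideal: np.ndarray  # (n,) x_AI per criterion
    anti_ideal: np.ndarray  # (n,) x_AAI per criterion
    normalized: np.ndarray  # (m+2, n), rows = alternatives, AI, AAI
    weighted: np.ndarray  # (m+2, n) v_ij
    S: np.ndarray  # (m,) row utilities of the alternatives
    S_AI: float
    S_AAI: float
    K_plus: np.ndarray  # (m,) S_i / S_AI
    K_minus: np.ndarray  # (m,) S_i / S_AAI
    f_plus: np.ndarray  # (m,) f(K+) = K- / (K+ + K-)
    f_minus: np.ndarray  # (m,) f(K-) = K+ / (K+ + K-)
    final: np.ndarray  # (m,) f_i


def extend_with_references(matrix: DecisionMatrix) -> np.ndarray:
    """Return the (m+2, n) array: original rows, then AI row, then AAI row.

    AI holds the per-column best (max for benefit, min for cost), AAI the
    per-column worst.
    """
    x = matrix.values
    benefit = matrix.directions
    ai = np.where(benefit, x.max(axis=0), x.min(axis=0))
    aai = np.where(benefit, x.min(axis=0), x.max(axis=0))
    return np.vstack([x, ai, aai])


def marcos_normalize(
    extended: np.ndarray,
    benefit: np.ndarray,
    variant: str = "ideal_referenced",
) -> np.ndarray:
    """Ratio-normalize the extended matrix (last two rows = AI, AAI)."""
    if variant not in NORMALIZATION_VARIANTS:
        raise ValueError(
            f"variant must be one of {NORMALIZATION_VARIANTS}, got {variant!r}"
        )
    ext = np.asarray(extended, dtype=float)
    ai = ext[-2]
    aai = ext[-1]
    cost = ~np.asarray(benefit)
    if np.any(ext[:, cost] <= 0) or np.any(ai[~cost] <= 0):
        raise ValueError(
            "ratio normalization needs strictly positive values in cost "
            "columns (and positive ideal values in benefit columns); "
            "min-max shift the data first"
        )
    reference = ai if variant == "ideal_referenced" else aai
    n = np.where(benefit, ext / ai, reference / ext)
    return n


def marcos_rank(
    matrix: DecisionMatrix,
    weights,
    *,
    normalization_variant: str = "ideal_referenced",
    utility_variant: str = "standard_compromise",
) -> tuple[MethodResult, MarcosArtifacts]:
    """Score and rank alternatives by MARCOS utility (higher is better)."""
    if utility_variant not in UTILITY_VARIANTS:
        raise ValueError(
            f"utility_variant must be one of {UTILITY_VARIANTS}, "
            f"got {utility_variant!r}"
        )
    m, nc = matrix.shape
    w = _coerce_weights(weights, nc)
    ext = extend_with_references(matrix)
    norm = marcos_normalize(ext, matrix.directions, normalization_variant)
    weighted = norm * w
    row_sums = weighted.sum(axis=1)
    s, s_ai, s_aai = row_sums[:m], row_sums[-2], row_sums[-1]
    if s_aai == 0:
        raise DegenerateAntiIdealError("anti-ideal utility S_AAI is zero")
    k_plus = s / s_ai
    k_minus = s / s_aai
    f_plus = k_minus / (k_plus + k_minus)
    f_minus = k_plus / (k_plus + k_minus)
    if utility_variant == "standard_compromise":
        final = (k_plus + k_minus) / (
            1 + (1 - f_plus) / f_plus + (1 - f_minus) / f_minus
        )
    else:
        final = (k_plus + k_minus) / 2.0
    result = MethodResult(
        method="MARCOS",
        alternatives=tuple(matrix.alternatives),
        scores=final,
        ranks=assign_ranks(final, "higher"),
        better_direction="higher",
    )
    artifacts = MarcosArtifacts(
        ideal=ext[-2],
        anti_ideal=ext[-1],
        normalized=norm,
        weighted=weighted,
        S=s,
        S_AI=float(s_ai),
        S_AAI=float(s_aai),
        K_plus=k_plus,
        K_minus=k_minus,
        f_plus=f_plus,
        f_minus=f_minus,
        final=final,
    )
    return result, artifacts
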