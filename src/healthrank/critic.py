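"""CRITIC objective criterion weighting.

CRITIC (Criteria Importance Through Intercriteria Correlation) derives
weights from the data alone: a criterion is important if its normalized
column is dispersed (contrast intensity, the sample standard deviation
``sigma_j``) and if it disagrees with the other criteria (conflict,
``sum_k (1 - rho_jk)`` over the Pearson correlations of normalized
columns).  The information content is

    C_j = sigma_j * sum_k (1 - rho_jk)

and the weight is ``w_j = C_j / sum_k C_k``, so the weights are positive
and sum to one.

Correlation is computed on the direction-adjusted (min-max normalized)
matrix, so flipping a cost criterion's sign is already accounted for
before the conflict term is formed.  Negative correlations are kept
as-is; they increase conflict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_matrix import (
    DecisionMatrix,
    DegenerateCriterionError,
    minmax_normalize,
)

__all__ = [
    "CriticDiagnostics",
    "WeightVector",
    "correlation_matrix",
    "contrast_intensity",
    "compute_weights",
]


@dataclass(frozen=True)
class CriticDiagnostics:
    """Intermediate quantities of a CRITIC run, for reporting."""

    correlation: np.ndarray  # (n, n) Pearson rho of normalized columns
    sigma: np.ndarray  # (n,) contrast intensity per criterion
    info_content: np.ndarray  # (n,) C_j = sigma_j * sum(1 - rho_jk)


@dataclass(frozen=True)
class WeightVector:
    """Criterion weights, positive and summing to one."""

    weights: np.ndarray
    codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("weights must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(w)):
            raise ValueError(
                "weights must be finite (zero total information content?)"
            )
        if np.any(w <= 0):
            raise ValueError("all weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def __len__(self) -> int:
        return self.weights.size

    def as_dict(self) -> dict[str, float]:
        codes = self.codes or tuple(f"w{j+1}" for j in range(len(self)))
        return dict(zip(codes, self.weights.tolist()))


def correlation_matrix(normalized: np.ndarray) -> np.ndarray:
    """Pearson product-moment correlation between normalized columns."""
    r = np.asarray(normalized, dtype=float)
    if np.any(r.std(axis=0) == 0):
        raise DegenerateCriterionError(
            "zero-variance normalized column; cannot correlate"
        )
    rho = np.corrcoef(r, rowvar=False)
    return np.asarray(rho)


def contrast_intensity(normalized: np.ndarray, *, ddof: int = 1) -> np.ndarray:
    """Standard deviation of each normalized column (sample, m-1 by default)."""
    r = np.asarray(normalized, dtype=float)
    if r.shape[0] < 2:
        raise ValueError("need at least 2 alternatives to measure contrast")
    return r.std(axis=0, ddof=ddof)


def compute_weights(
    matrix: DecisionMatrix, *, sd: str = "sample"
) -> tuple[WeightVector, CriticDiagnostics]:
    """Run the full CRITIC chain on a validated decision matrix.

    Parameters
    ----------
    matrix : DecisionMatrix
        Raw decision matrix with directions.
    sd : {"sample", "population"}
        Denominator of the contrast intensity: ``m - 1`` (default) or
        ``m``.  The sample form is the standard one; the population form
        is provided only for cross-checking other implementations (it
        changes sigma by a constant factor and therefore, with the
        conflict term, the weights slightly).

    Returns
    -------
    (WeightVector, CriticDiagnostics)
    """
    if sd not in ("sample", "population"):
        raise ValueError(f"sd must be 'sample' or 'population', got {sd!r}")
    r = minmax_normalize(matrix)
    rho = correlation_matrix(r)
    sigma = contrast_intensity(r, ddof=1 if sd == "sample" else 0)
    info = sigma * (1.0 - rho).sum(axis=1)
    total = info.sum()
    if total <= 0:
        raise DegenerateCriterionError(
            "zero total information content: all criteria are perfectly "
            "correlated, so CRITIC cannot distinguish them"
        )
    weights = info / total
    return (
        WeightVector(weights, codes=tuple(matrix.codes)),
        CriticDiagnostics(correlation=rho, sigma=sigma, info_content=info),
    )
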