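"""Synthetic decision-matrix generator with controlled structure.

Emulates the shape of real cross-country indicator tables: positive
continuous columns on heterogeneous scales, mixed benefit/cost
directions, and configurable inter-criterion correlation.  Columns are
drawn through a Gaussian copula — a latent multivariate normal with the
target correlation, pushed through the normal CDF to uniform marginals
and rescaled to per-criterion ranges — so marginals stay bounded and
strictly positive (required by MARCOS ratio normalization) while the
rank correlation structure is controlled.

A "planted" row can be injected that attains the best possible value in
every column; by weak dominance it must rank first under any valid
weights, giving property suites a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .decision_matrix import CriterionSpec, DecisionMatrix, Direction

__all__ = ["SyntheticSpec", "generate", "perturb"]


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass
class SyntheticSpec:
    """Specification of a synthetic decision matrix.

    Parameters
    ----------
    m, n : int
        Numbers of alternatives and criteria.
    seed : int
        Mandatory RNG seed; generation is a pure function of the spec.
    directions : sequence of Direction or str, optional
        Per-criterion directions; defaults to all benefit.
    ranges : sequence of (low, high), optional
        Positive marginal bounds per criterion; defaults to spreading
        scales over several orders of magnitude (1..10, 10..100, ...),
        mimicking heterogeneous indicator units.
    correlation : (n, n) array, optional
        Target latent correlation; must be symmetric PSD with unit
        diagonal.  Defaults to identity.
    plant : {"none", "dominant", "dominated"}
        Optionally overwrite the first row with the per-column best
        (``dominant``) or worst (``dominated``) possible value.
    """

    m: int
    n: int
    seed: int
    directions: Optional[Sequence] = None
    ranges: Optional[Sequence[tuple[float, float]]] = None
    correlation: Optional[np.ndarray] = None
    plant: str = "none"

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise SpecError("need m >= 2 and n >= 2")
        if self.plant not in ("none", "dominant", "dominated"):
            raise SpecError(f"unknown plant mode {self.plant!r}")
        if self.directions is None:
            self.directions = [Direction.BENEFIT] * self.n
        self.directions = [Direction.coerce(d) for d in self.directions]
        if len(self.directions) != self.n:
            raise SpecError("directions length must equal n")
        if self.ranges is None:
            self.ranges = [
                (10.0**j, 10.0 ** (j + 1)) for j in range(self.n)
            ]
        self.ranges = [(float(lo), float(hi)) for lo, hi in self.ranges]
        if len(self.ranges) != self.n:
            raise SpecError("ranges length must equal n")
        for lo, hi in self.ranges:
            if lo >= hi:
                raise SpecError(f"range low {lo} must be < high {hi}")
            if lo <= 0:
                raise SpecError(
                    "range lows must be positive (ratio-normalization domain)"
                )
        if self.correlation is None:
            self.correlation = np.eye(self.n)
        self.correlation = np.asarray(self.correlation, dtype=float)
        c = self.correlation
        if c.shape != (self.n, self.n):
            raise SpecError("correlation must be n x n")
        if not np.allclose(c, c.T, atol=1e-12):
            raise SpecError("correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise SpecError("correlation must have unit diagonal")
        eigmin = np.linalg.eigvalsh(c).min()
        if eigmin < -1e-10:
            raise SpecError(
                f"correlation not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )


def _criteria(spec: SyntheticSpec) -> list[CriterionSpec]:
    return [
        CriterionSpec(f"C{j+1}", d, name=f"synthetic criterion {j+1}")
        for j, d in enumerate(spec.directions)
    ]


def generate(spec: SyntheticSpec) -> DecisionMatrix:
    """Draw a decision matrix from the spec (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    # Gaussian copula: correlated latent normals -> uniform -> ranges
    chol = np.linalg.cholesky(
        spec.correlation + 1e-12 * np.eye(spec.n)
    )
    z = rng.standard_normal((spec.m, spec.n)) @ chol.T
    u = stats.norm.cdf(z)
    lows = np.array([r[0] for r in spec.ranges])
    highs = np.array([r[1] for r in spec.ranges])
    x = lows + u * (highs - lows)
    if spec.plant == "dominant":
        best = np.where(
            [d is Direction.BENEFIT for d in spec.directions], highs, lows
        )
        x[0] = best
    elif spec.plant == "dominated":
        worst = np.where(
            [d is Direction.BENEFIT for d in spec.directions], lows, highs
        )
        x[0] = worst
    labels = [f"A{i+1:02d}" for i in range(spec.m)]
    return DecisionMatrix(labels, _criteria(spec), x)


def perturb(
    matrix: DecisionMatrix, relative_noise: float, seed: int
) -> DecisionMatrix:
    """Multiply every cell by ``1 + eps``, eps ~ U(-noise, +noise).

    Values are clipped away from zero so cost-column ratio
    normalization stays defined.  ``relative_noise = 0`` is the
    identity.
    """
    if relative_noise < 0:
        raise SpecError("relative_noise must be >= 0")
    if relative_noise == 0:
        return matrix.replace_values(matrix.values.copy())
    rng = np.random.default_rng(seed)
    eps = rng.uniform(-relative_noise, relative_noise, matrix.values.shape)
    tiny = np.finfo(float).tiny
    noisy = np.maximum(matrix.values * (1.0 + eps), tiny)
    return matrix.replace_values(noisy)
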