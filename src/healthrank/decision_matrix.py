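"""Decision-matrix data model, validation and I/O.

A decision matrix holds ``m`` alternatives (rows) evaluated on ``n``
criteria (columns).  Each criterion carries an optimization direction:
*benefit* (larger is better) or *cost* (smaller is better).  The module
also embeds the OECD health-system fixture: 27 countries scored on six
indicators (life expectancy, health spending per capita, avoidable
mortality, chronic disease morbidity, infant mortality, maternal
mortality).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Direction",
    "CriterionSpec",
    "DecisionMatrix",
    "ValidationError",
    "ConfigurationError",
    "DegenerateCriterionError",
    "load_matrix",
    "write_matrix",
    "load_criteria_config",
    "oecd_fixture",
    "minmax_normalize",
    "column_extremes",
]


class ValidationError(ValueError):
    """Raised when matrix contents violate a structural invariant."""


class ConfigurationError(ValueError):
    """Raised when the criteria configuration does not match the data."""


class DegenerateCriterionError(ValidationError):
    """Raised when a criterion column has zero range (max == min)."""


class Direction(str, enum.Enum):
    """Optimization direction of a criterion."""

    BENEFIT = "benefit"
    COST = "cost"

    @classmethod
    def coerce(cls, value: Union[str, "Direction"]) -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ConfigurationError(
                f"direction must be 'benefit' or 'cost', got {value!r}"
            ) from None


@dataclass(frozen=True)
class CriterionSpec:
    """A single criterion: short code, human-readable name, direction."""

    code: str
    direction: Direction
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if not self.code:
            raise ValidationError("criterion code must be non-empty")


@dataclass
class DecisionMatrix:
    """An m x n table of indicator values with labelled rows and columns.

    Parameters
    ----------
    alternatives : sequence of str
        Row labels (countries, products, ...), order preserved.
    criteria : sequence of CriterionSpec
        Column specifications, order preserved.
    values : (m, n) array_like of float
        Raw indicator values ``x_ij``; units vary per column.
    """

    alternatives: list[str]
    criteria: list[CriterionSpec]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.alternatives = [str(a) for a in self.alternatives]
        self.criteria = list(self.criteria)
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.shape
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if m < 2 or n < 2:
            raise ValidationError(f"need at least 2x2 matrix, got {m}x{n}")
        if self.values.shape != (m, n):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{m} alternatives x {n} criteria"
            )
        if len(set(self.alternatives)) != m:
            dupes = sorted(
                {a for a in self.alternatives if self.alternatives.count(a) > 1}
            )
            raise ValidationError(f"duplicate alternative labels: {dupes}")
        codes = [c.code for c in self.criteria]
        if len(set(codes)) != n:
            raise ValidationError(f"duplicate criterion codes in {codes}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-finite value at alternative {self.alternatives[i]!r}, "
                f"criterion {codes[j]!r}"
            )
        rng = self.values.max(axis=0) - self.values.min(axis=0)
        degenerate = np.flatnonzero(rng == 0)
        if degenerate.size:
            raise DegenerateCriterionError(
                f"zero-range (constant) criterion column(s): "
                f"{[codes[j] for j in degenerate]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.alternatives), len(self.criteria)

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.criteria]

    @property
    def directions(self) -> np.ndarray:
        """Boolean mask per criterion: True where direction is benefit."""
        return np.array(
            [c.direction is Direction.BENEFIT for c in self.criteria]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.alternatives, columns=self.codes
        )

    def replace_values(self, values: np.ndarray) -> "DecisionMatrix":
        """New matrix with the same labels/criteria and different values."""
        return DecisionMatrix(
            list(self.alternatives), list(self.criteria), np.asarray(values)
        )


def column_extremes(matrix: DecisionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (max, min) pairs; raises on a zero-range column."""
    hi = matrix.values.max(axis=0)
    lo = matrix.values.min(axis=0)
    if np.any(hi == lo):  # unreachable for a validated matrix; keep the guard
        raise DegenerateCriterionError("zero-range column")
    return hi, lo


def _parse_cell(token: object, row: str, col: str) -> float:
    """Parse one numeric cell; commas are thousands separators (stripped)."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        raise ValidationError(f"missing value at row {row!r}, column {col!r}")
    text = str(token).strip().replace(",", "")
    if not text:
        raise ValidationError(f"missing value at row {row!r}, column {col!r}")
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"non-numeric value {token!r} at row {row!r}, column {col!r}"
        ) from None


def load_criteria_config(path: Union[str, Path]) -> dict[str, CriterionSpec]:
    """Read a YAML/JSON mapping ``code -> {direction, name}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("criteria config must be a mapping")
    specs: dict[str, CriterionSpec] = {}
    for code, entry in raw.items():
        if isinstance(entry, str):
            entry = {"direction": entry}
        if not isinstance(entry, Mapping) or "direction" not in entry:
            raise ConfigurationError(
                f"criterion {code!r} must specify a direction"
            )
        specs[str(code)] = CriterionSpec(
            code=str(code),
            direction=Direction.coerce(entry["direction"]),
            name=str(entry.get("name", "")),
        )
    return specs


def load_matrix(
    path: Union[str, Path],
    criteria_config: Mapping[str, Union[CriterionSpec, str, Direction]],
    *,
    sep: str = ",",
) -> DecisionMatrix:
    """Load a decision matrix from delimited text.

    The file must have a header row of criterion codes, with the first
    column holding alternative labels.  ``criteria_config`` maps every
    criterion code in the file to a :class:`CriterionSpec` (or bare
    direction).  Thousands-separator commas inside quoted numeric tokens
    are stripped; decimal commas are not supported.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError("file needs a label column and >=1 criterion")
    label_col = df.columns[0]
    codes = [str(c) for c in df.columns[1:]]
    criteria: list[CriterionSpec] = []
    for code in codes:
        if code not in criteria_config:
            raise ConfigurationError(
                f"criterion {code!r} in file but not in criteria config"
            )
        spec = criteria_config[code]
        if not isinstance(spec, CriterionSpec):
            spec = CriterionSpec(code=code, direction=Direction.coerce(spec))
        criteria.append(spec)
    alternatives = [str(a) for a in df[label_col]]
    values = np.empty((len(alternatives), len(codes)))
    for i, alt in enumerate(alternatives):
        for j, code in enumerate(codes):
            values[i, j] = _parse_cell(df.iat[i, j + 1], alt, code)
    return DecisionMatrix(alternatives, criteria, values)


def write_matrix(
    matrix: DecisionMatrix, path: Union[str, Path], *, sep: str = ","
) -> None:
    """Write a matrix back to delimited text at full double precision."""
    df = matrix.to_frame()
    df.index.name = "alternative"
    df.to_csv(path, sep=sep, float_format="%.17g")


def minmax_normalize(matrix: DecisionMatrix) -> np.ndarray:
    """Direction-aware min-max normalization to [0, 1].

    Benefit columns map ``(x - min) / (max - min)``; cost columns map
    ``(max - x) / (max - min)``, so the best value in every column is 1
    and the worst is 0 regardless of direction.
    """
    hi, lo = column_extremes(matrix)
    x = matrix.values
    r = np.where(matrix.directions, (x - lo) / (hi - lo), (hi - x) / (hi - lo))
    return r


# --- Embedded OECD fixture ------------------------------------------------
# 27 OECD countries x 6 indicators, one reference year; values exactly as
# published (spending figures for Slovak Republic and Slovenia carry fewer
# decimals in the source and are kept as-is).

_OECD_CRITERIA = (
    CriterionSpec("C1", Direction.BENEFIT, "Life expectancy"),
    CriterionSpec("C2", Direction.BENEFIT, "Health spending per capita"),
    CriterionSpec("C3", Direction.COST, "Avoidable mortality"),
    CriterionSpec("C4", Direction.COST, "Chronic disease morbidity"),
    CriterionSpec("C5", Direction.COST, "Infant mortality rate"),
    CriterionSpec("C6", Direction.COST, "Maternal mortality"),
)

_OECD_ROWS: tuple[tuple[str, float, float, float, float, float, float], ...] = (
    ("Australia", 83.2, 6730.995117, 156, 8.1, 3.2, 4.7),
    ("Austria", 81.4, 5851.962402, 187, 5.2, 2.4, 3.6),
    ("Belgium", 81.8, 5404.624023, 184, 6.7, 2.9, 8.8),
    ("Canada", 81.3, 6255.027832, 184, 6.8, 4.7, 8.5),
    ("Chile", 81.2, 1547.289673, 229, 14, 5.9, 11.6),
    ("Costa Rica", 80.9, 978.8415527, 241, 23.2, 9.5, 15),
    ("Czechia", 79, 2431.084961, 250, 7.7, 2.3, 4),
    ("Denmark", 81.3, 6456.083984, 175, 2.3, 2.3, 3.4),
    ("Germany", 80.7, 6182.34375, 195, 6.6, 3.2, 4.1),
    ("Greece", 80.8, 1768.110718, 213, 7.2, 3, 3.9),
    ("Hungary", 76, 1224.433838, 422, 11.2, 3.6, 7.9),
    ("Israel", 82.8, 4223.872559, 134, 7.9, 2.9, 1.1),
    ("Italy", 82.8, 3134.680664, 135, 7.2, 2.3, 3.6),
    ("Japan", 84.1, 3889.357178, 131, 6.4, 1.8, 4.3),
    ("Korea", 82.7, 3049.671631, 151, 10.4, 2.3, 8.4),
    ("Latvia", 74.5, 1642.471313, 449, 9.3, 2.4, 31.6),
    ("Mexico", 75.2, 650.9707031, 418, 14.3, 12.1, 38.2),
    ("Netherlands", 81.7, 5796.034668, 156, 6.4, 3.2, 3),
    ("Poland", 77.2, 1193.130615, 316, 10.8, 3.8, 2),
    ("Portugal", 81.8, 2580.756348, 180, 7.4, 2.6, 13.1),
    ("Slovak Republic", 77, 4021, 341, 8.9, 5.4, 3.8),
    ("Slovenia", 81.3, 5527, 210, 10.8, 2.5, 11.5),
    ("Spain", 83.2, 2910.837646, 154, 3.6, 2.6, 3.3),
    ("Sweden", 83.1, 5943.361328, 138, 5.1, 2.2, 4.8),
    ("Switzerland", 83.7, 10963.43066, 124, 4.3, 3.8, 1.2),
    ("Türkiye", 77.3, 385.8799744, 243, 16.6, 9.1, 12.6),
    ("United States", 77.5, 12434.43359, 312, 12.5, 5.6, 22.3),
)


def oecd_fixture() -> DecisionMatrix:
    """The embedded OECD health-system decision matrix (27 x 6).

    Returns a fresh, validated :class:`DecisionMatrix`; values are
    bit-identical across calls.
    """
    labels = [row[0] for row in _OECD_ROWS]
    values = np.array([row[1:] for row in _OECD_ROWS], dtype=float)
    return DecisionMatrix(labels, list(_OECD_CRITERIA), values)
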