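"""End-to-end analysis pipeline: load -> weights -> rank -> concordance.

The pipeline is a pure function of the input matrix and configuration:
it computes CRITIC weights, ranks the alternatives with MAIRCA and
MARCOS, measures rank concordance, and renders machine-readable (JSON)
and tabular (CSV) reports.  A provenance block (input hash, variant
flags, package version) makes every run exactly re-executable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .concordance import ConcordanceReport, build_report
from .critic import CriticDiagnostics, WeightVector, compute_weights
from .decision_matrix import (
    DecisionMatrix,
    load_criteria_config,
    load_matrix,
    oecd_fixture,
)
from .mairca import mairca_rank
from .marcos import marcos_rank
from .ranking import MethodResult

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "write_report"]

DISPLAY_DECIMALS = 9  # scores rendered at 9 decimals; JSON keeps full doubles


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run."""

    input_path: Optional[Union[str, Path]] = None
    criteria_path: Optional[Union[str, Path]] = None
    fixture: Optional[str] = None  # "oecd" to use the embedded matrix
    sd: str = "sample"
    marcos_normalization: str = "ideal_referenced"
    marcos_utility: str = "standard_compromise"
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.fixture is None and self.input_path is None:
            raise ValueError("either an input path or a fixture is required")
        if self.fixture is not None and self.fixture != "oecd":
            raise ValueError(f"unknown fixture {self.fixture!r}")


@dataclass(frozen=True)
class PipelineReport:
    """Everything one pipeline run produced."""

    matrix: DecisionMatrix
    weights: WeightVector
    diagnostics: CriticDiagnostics
    mairca: MethodResult
    marcos: MethodResult
    concordance: ConcordanceReport
    provenance: dict


def _input_hash(matrix: DecisionMatrix) -> str:
    h = hashlib.sha256()
    h.update("|".join(matrix.alternatives).encode())
    h.update("|".join(matrix.codes).encode())
    h.update(
        "|".join(c.direction.value for c in matrix.criteria).encode()
    )
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    return h.hexdigest()


def _load_input(config: PipelineConfig) -> DecisionMatrix:
    if config.fixture == "oecd":
        return oecd_fixture()
    if config.criteria_path is None:
        raise ValueError("a criteria config is required with --input")
    criteria = load_criteria_config(config.criteria_path)
    sep = "\t" if str(config.input_path).endswith((".tsv", ".tab")) else ","
    return load_matrix(config.input_path, criteria, sep=sep)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order and return the full report."""
    matrix = _load_input(config)
    weights, diagnostics = compute_weights(matrix, sd=config.sd)
    mairca_result, _ = mairca_rank(matrix, weights)
    marcos_result, _ = marcos_rank(
        matrix,
        weights,
        normalization_variant=config.marcos_normalization,
        utility_variant=config.marcos_utility,
    )
    concordance = build_report(mairca_result, marcos_result, k=config.top_k)
    provenance = {
        "package_version": __version__,
        "input_hash": _input_hash(matrix),
        "fixture": config.fixture,
        "input_path": str(config.input_path) if config.input_path else None,
        "sd": config.sd,
        "marcos_normalization": config.marcos_normalization,
        "marcos_utility": config.marcos_utility,
        "top_k": config.top_k,
    }
    return PipelineReport(
        matrix=matrix,
        weights=weights,
        diagnostics=diagnostics,
        mairca=mairca_result,
        marcos=marcos_result,
        concordance=concordance,
        provenance=provenance,
    )


def weights_frame(report: PipelineReport) -> pd.DataFrame:
    """One-row weights table (criterion codes as columns)."""
    return pd.DataFrame([report.weights.as_dict()])


def ranking_frame(report: PipelineReport) -> pd.DataFrame:
    """Combined per-alternative score/rank table for both methods."""
    return pd.DataFrame(
        {
            "alternative": report.matrix.alternatives,
            "mairca_score": np.round(report.mairca.scores, DISPLAY_DECIMALS),
            "mairca_rank": report.mairca.ranks,
            "marcos_score": np.round(report.marcos.scores, DISPLAY_DECIMALS),
            "marcos_rank": report.marcos.ranks,
        }
    )


def report_to_dict(report: PipelineReport) -> dict:
    """Full-precision JSON-serializable view of the report."""
    con = report.concordance
    return {
        "provenance": report.provenance,
        "weights": report.weights.as_dict(),
        "critic_diagnostics": {
            "sigma": dict(zip(report.matrix.codes, report.diagnostics.sigma)),
            "info_content": dict(
                zip(report.matrix.codes, report.diagnostics.info_content)
            ),
            "correlation": report.diagnostics.correlation.tolist(),
        },
        "mairca": {
            "scores": dict(
                zip(report.mairca.alternatives, report.mairca.scores)
            ),
            "ranks": dict(
                zip(
                    report.mairca.alternatives,
                    [int(r) for r in report.mairca.ranks],
                )
            ),
        },
        "marcos": {
            "scores": dict(
                zip(report.marcos.alternatives, report.marcos.scores)
            ),
            "ranks": dict(
                zip(
                    report.marcos.alternatives,
                    [int(r) for r in report.marcos.ranks],
                )
            ),
        },
        "concordance": {
            "spearman_rho": con.rho,
            "shifts": dict(
                zip(con.alternatives, [int(s) for s in con.shifts])
            ),
            "stable_top": list(con.stable_top),
            "stable_bottom": list(con.stable_bottom),
            "k": con.k,
        },
    }


def write_report(report: PipelineReport, out_dir: Union[str, Path]) -> dict:
    """Write report.json plus weights.csv and rankings.csv under out_dir.

    Returns a mapping of artifact name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "report.json",
        "weights": out / "weights.csv",
        "rankings": out / "rankings.csv",
    }
    try:
        with open(paths["report"], "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
        weights_frame(report).to_csv(paths["weights"], index=False)
        ranking_frame(report).to_csv(paths["rankings"], index=False)
    except Exception:
        for p in paths.values():  # no partial outputs
            p.unlink(missing_ok=True)
        raise
    return {k: str(v) for k, v in paths.items()}
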