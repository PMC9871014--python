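"""Machine-readable actionability reports.

A report is a single versioned JSON document juxtaposing the diagnosis-phase
metric, the optional action-phase metric, the optional net-benefit curve,
and the optional correctness-stratified diagnostics. The two families of
metric are reported side by side, not combined: how entropy reduction and
net benefit should be jointly summarized is an open question, so the report
deliberately leaves them separate.

The schema is defined by pydantic models; :func:`report_json_schema` exports
the equivalent JSON Schema document, and :func:`validate_report` checks any
dict against it. Floats survive a JSON round trip exactly (Python's float
repr is shortest-round-trip).
"""

from __future__ import annotations

import json
import math
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field

from .models import ActionabilityResults, StratifiedReport
from .netbenefit import NetBenefitCurve

SCHEMA_VERSION = "1.0"


def _jsonable_float(x: float) -> float | str:
    # JSON has no inf/nan literals; encode as strings the validator accepts
    if math.isinf(x):
        return "Infinity" if x > 0 else "-Infinity"
    if math.isnan(x):
        return "NaN"
    return x


class MetricSection(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    phase: str
    reference_name: str
    candidate_name: str
    n_samples: int
    log_base: float
    mode: Optional[str] = None
    # entropies/deltas may be infinite (unsupported zeros); JSON has no inf
    # literal, so non-finite values are encoded as the strings "Infinity",
    # "-Infinity", "NaN"
    mean_delta: float | str
    mean_reference_entropy: float | str
    mean_candidate_term: float | str
    per_sample_delta: list[float | str]
    bootstrap_ci: Optional[tuple[float, float]] = None
    n_boot: Optional[int] = None
    bootstrap_seed: Optional[int] = None
    warnings: list[str] = Field(default_factory=list)


class StratumRow(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stratum: str
    n: int
    mean_delta: float
    mean_candidate_entropy: float


class StrataSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rows: list[StratumRow]
    n_ties: int
    correct_fraction: float


class NetBenefitSection(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    thresholds: list[float]
    model_nb: list[float]
    treat_all_nb: list[float]
    treat_none_nb: list[float]
    n: int
    prevalence: float


class ReportDocument(BaseModel):
    """Top-level actionability report."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    diagnosis: MetricSection
    action: Optional[MetricSection] = None
    net_benefit: Optional[NetBenefitSection] = None
    strata: Optional[StrataSection] = None
    warnings: list[str] = Field(default_factory=list)


def metric_section(result: ActionabilityResults) -> dict[str, Any]:
    """Convert an ActionabilityResults into the report's metric section."""
    return {
        "phase": result.phase,
        "reference_name": result.reference_name,
        "candidate_name": result.candidate_name,
        "n_samples": result.n_samples,
        "log_base": result.options.log_base,
        "mode": result.mode,
        "mean_delta": _jsonable_float(result.mean_delta),
        "mean_reference_entropy": _jsonable_float(
            float(result.per_sample_reference_entropy.mean())
        ),
        "mean_candidate_term": _jsonable_float(
            float(result.per_sample_candidate_term.mean())
        ),
        "per_sample_delta": [_jsonable_float(float(d)) for d in result.per_sample_delta],
        "bootstrap_ci": result.bootstrap_ci,
        "n_boot": result.n_boot,
        "bootstrap_seed": result.bootstrap_seed,
        "warnings": list(result.warnings),
    }


def strata_section(report: StratifiedReport) -> dict[str, Any]:
    rows = [
        {
            "stratum": stratum,
            "n": int(row["n"]),
            "mean_delta": float(row["mean_delta"]),
            "mean_candidate_entropy": float(row["mean_candidate_entropy"]),
        }
        for stratum, row in report.table.iterrows()
    ]
    return {
        "rows": rows,
        "n_ties": report.n_ties,
        "correct_fraction": report.correct_fraction,
    }


def full_report(
    diag: ActionabilityResults,
    action: ActionabilityResults | None = None,
    nb: NetBenefitCurve | None = None,
    strata: StratifiedReport | None = None,
) -> dict[str, Any]:
    """Assemble (and validate) the full report document as a plain dict."""
    warnings = list(diag.warnings)
    if action is not None:
        warnings += action.warnings
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "diagnosis": metric_section(diag),
        "action": metric_section(action) if action is not None else None,
        "net_benefit": nb.to_dict() if nb is not None else None,
        "strata": strata_section(strata) if strata is not None else None,
        "warnings": warnings,
    }
    validate_report(doc)
    return doc


def validate_report(doc: dict[str, Any]) -> ReportDocument:
    """Validate a report dict against the schema; returns the parsed model."""
    return ReportDocument.model_validate(doc)


def report_json_schema() -> dict[str, Any]:
    """The report's published JSON Schema."""
    return ReportDocument.model_json_schema()


def dumps_report(doc: dict[str, Any]) -> str:
    """Serialize a report deterministically (sorted keys, exact floats)."""
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def write_report(doc: dict[str, Any], path) -> None:
    from pathlib import Path

    Path(path).write_text(dumps_report(doc))
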