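"""End-to-end analysis report: schemes, charts, outcomes, model, provenance.

``analyze_series`` runs the whole pipeline on one case series — derive the
phase rates from a benchmark, build both schemes, run the chained
LC-CUSUM/CUSUM, summarize outcomes, compare Ba pre/post and fit the
adjusted-odds-ratio model — and bundles the results into one
machine-readable report.  Re-running on the same inputs reproduces the
report bit-for-bit apart from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .benchmarks import PooledBenchmark, derive_phase_rates
from .charts import LEARNING, MONITORING, MonitoringTrace, derive_scheme, run_two_phase
from .cohort import CaseSeries
from .errors import ConvergenceError, ValidationError
from .outcomes import (
    DEFAULT_COVARIATES,
    compare_ba_prepost,
    fit_healing_model,
    summarize_outcomes,
)

__all__ = ["AnalysisReport", "analyze_series", "REPORT_SCHEMA", "validate_report"]

#: Minimal structural schema of the report JSON: required key -> type
#: (dicts nest).  Checked by :func:`validate_report`.
REPORT_SCHEMA: dict = {
    "package_version": str,
    "timestamp": str,
    "seed": (int, type(None)),
    "inputs": dict,
    "schemes": {
        "learning": dict,
        "monitoring": dict,
    },
    "chart": {
        "proficiency_index": (int, type(None)),
        "alarm_index": (int, type(None)),
        "proficiency_attained": bool,
        "n_cases": int,
    },
    "outcomes": dict,
    "benchmark": (dict, type(None)),
    "ba_comparison": (dict, type(None)),
    "logistic_model": (dict, type(None)),
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA, _path: str = "") -> None:
    """Check a report dict against the shipped structural schema.

    Raises :class:`ValidationError` naming the first missing or mistyped key.
    """
    for key, expected in schema.items():
        where = f"{_path}{key}"
        if key not in report:
            raise ValidationError(f"report is missing key {where!r}")
        value = report[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ValidationError(f"report key {where!r} must be an object")
            validate_report(value, expected, _path=f"{where}.")
        elif not isinstance(value, expected):
            raise ValidationError(
                f"report key {where!r} has type {type(value).__name__}"
            )


@dataclass(frozen=True)
class AnalysisReport:
    """Self-contained result bundle of one full analysis."""

    payload: dict
    trace: MonitoringTrace

    def to_json(self, path=None) -> str:
        text = json.dumps(self.payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _sha256(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def analyze_series(
    series: CaseSeries,
    benchmark: PooledBenchmark | None = None,
    rates: dict[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
    beta: float = 0.20,
    window: int = 49,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    fit_model: bool = True,
    series_path: str | Path | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full proficiency analysis on one case series.

    Exactly one of ``benchmark`` (phase rates derived by the standard rule)
    or ``rates`` (explicit ``{"learning": (p0, p1), "monitoring": (p0, p1)}``)
    must be given.  The chart runs over *all* cases in order (an outcome is
    observed per operation); rates, cure and the risk model use the
    follow-up-complete subset.  Model fitting can be disabled for series
    without covariates.
    """
    if (benchmark is None) == (rates is None):
        raise ValidationError("give exactly one of benchmark or rates")
    if benchmark is not None:
        rates = derive_phase_rates(benchmark)
    learning = derive_scheme(*rates["learning"], alpha, beta, LEARNING)
    monitoring = derive_scheme(*rates["monitoring"], alpha, beta, MONITORING)
    trace = run_two_phase(series.outcomes, learning, monitoring)

    summary = summarize_outcomes(series, window=min(window, len(series.complete())))
    try:
        ba = compare_ba_prepost(series).__dict__
    except ValidationError:
        ba = None
    model = None
    if fit_model:
        try:
            model = fit_healing_model(series, covariates=covariates).as_dict()
        except (ValidationError, ConvergenceError) as exc:
            model = {"error": str(exc)}

    payload = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "inputs": {
            "series_sha256": _sha256(series_path),
            "n_cases": len(series),
            "n_followup_complete": len(series.complete()),
        },
        "schemes": {
            "learning": learning.as_dict(),
            "monitoring": monitoring.as_dict(),
        },
        "chart": {
            "proficiency_index": trace.signal_index,
            "alarm_index": trace.alarm_index,
            "proficiency_attained": trace.signal_index is not None,
            "n_cases": len(series),
        },
        "outcomes": summary.as_dict(),
        "benchmark": None if benchmark is None else benchmark.as_dict(),
        "ba_comparison": ba,
        "logistic_model": model,
    }
    validate_report(payload)
    return AnalysisReport(payload=payload, trace=trace)
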