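"""Pooling of prior-study failure rates into chart benchmarks.

The acceptable/unacceptable failure rates of the two chart phases are
derived from the published complication experience of earlier cohorts:
event counts are summed across studies, the pooled proportion is the point
estimate, and an upper confidence bound at the chosen level caps it.  The
monitoring chart then uses (point estimate, upper bound) as (p0, p1); the
learning chart uses (upper bound + offset, upper bound), with a default
offset of 10 percentage points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import SchemaError, ValidationError

__all__ = [
    "PriorStudy",
    "PooledBenchmark",
    "pool_prior_rates",
    "derive_phase_rates",
    "read_prior_studies",
]

_CI_METHODS = {"exact": "beta", "wilson": "wilson", "normal": "normal"}


@dataclass(frozen=True)
class PriorStudy:
    """One prior cohort: either an event count or a rate, plus its size.

    Exactly one of ``events``/``rate`` must be given; a rate is converted to
    a reconstructed count ``round(rate * n)``.
    """

    label: str
    n: int
    events: int | None = None
    rate: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"study {self.label!r}: n must be >= 1")
        if (self.events is None) == (self.rate is None):
            raise ValidationError(
                f"study {self.label!r}: give exactly one of events or rate"
            )
        if self.rate is not None:
            if not (0.0 <= self.rate <= 1.0):
                raise ValidationError(
                    f"study {self.label!r}: rate {self.rate} outside [0, 1]"
                )
            object.__setattr__(self, "events", round(self.rate * self.n))
        if not (0 <= self.events <= self.n):
            raise ValidationError(
                f"study {self.label!r}: events {self.events} outside [0, n={self.n}]"
            )


@dataclass(frozen=True)
class PooledBenchmark:
    """Pooled proportion with its upper confidence bound."""

    events: int
    n: int
    estimate: float
    upper: float
    ci_method: str
    level: float

    def __post_init__(self):
        if not (0.0 <= self.estimate <= self.upper <= 1.0):
            raise ValidationError(
                f"need 0 <= estimate ({self.estimate}) <= upper ({self.upper}) <= 1"
            )

    def as_dict(self) -> dict:
        return {
            "events": self.events,
            "n": self.n,
            "estimate": self.estimate,
            "upper": self.upper,
            "ci_method": self.ci_method,
            "level": self.level,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def pool_prior_rates(
    studies: Sequence[PriorStudy],
    ci_method: str = "exact",
    level: float = 0.95,
) -> PooledBenchmark:
    """Pool prior-study proportions by summing events and denominators.

    Parameters
    ----------
    studies
        At least one :class:`PriorStudy`.
    ci_method
        ``"exact"`` (Clopper-Pearson, default), ``"wilson"`` or ``"normal"``.
    level
        Two-sided confidence level of the interval whose upper bound is kept.

    Returns
    -------
    PooledBenchmark
        Point estimate = pooled proportion; ``upper`` = the interval's upper
        bound.  With a single study this is the study's own interval.
    """
    if not studies:
        raise ValidationError("at least one prior study is required")
    if ci_method not in _CI_METHODS:
        raise ValidationError(
            f"ci_method must be one of {sorted(_CI_METHODS)}, got {ci_method!r}"
        )
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    events = sum(s.events for s in studies)
    n = sum(s.n for s in studies)
    _, upper = proportion_confint(
        events, n, alpha=1 - level, method=_CI_METHODS[ci_method]
    )
    return PooledBenchmark(
        events=events,
        n=n,
        estimate=events / n,
        upper=float(upper),
        ci_method=ci_method,
        level=level,
    )


def derive_phase_rates(
    benchmark: PooledBenchmark, lc_offset: float = 0.10
) -> dict[str, tuple[float, float]]:
    """Derive the (p0, p1) pairs of both chart phases from a benchmark.

    Monitoring (p0, p1) = (point estimate, upper bound): the chart alarms
    when performance deteriorates from the literature average to its upper
    bound.  Learning (p0, p1) = (upper bound + ``lc_offset``, upper bound):
    proficiency is declared when performance distinguishably beats the
    inflated novice rate.  ``lc_offset`` is in absolute probability units
    (default 0.10, i.e. 10 percentage points).
    """
    if lc_offset < 0:
        raise ValidationError(f"lc_offset must be >= 0, got {lc_offset}")
    learning_p0 = benchmark.upper + lc_offset
    if learning_p0 >= 1.0:
        raise ValidationError(
            f"upper bound + offset = {learning_p0:.3f} is not a valid rate"
        )
    if benchmark.estimate <= 0.0:
        raise ValidationError("pooled estimate of 0 cannot parameterize a chart")
    return {
        "monitoring": (benchmark.estimate, benchmark.upper),
        "learning": (learning_p0, benchmark.upper),
    }


def read_prior_studies(path: str | Path) -> list[PriorStudy]:
    """Read prior studies from CSV (columns: label, n, and events or rate)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"no prior studies in {path}")
    for col in ("label", "n"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    if "events" not in df.columns and "rate" not in df.columns:
        raise SchemaError(f"need an 'events' or 'rate' column in {path}")
    out = []
    for _, row in df.iterrows():
        events = row.get("events")
        rate = row.get("rate")
        out.append(
            PriorStudy(
                label=str(row["label"]),
                n=int(row["n"]),
                events=None if pd.isna(events) else int(events),
                rate=None if rate is None or pd.isna(rate) else float(rate),
            )
        )
    return out
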