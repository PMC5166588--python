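"""Bernoulli sequential charts for operator proficiency and quality control.

Two one-sided charts over a binary failure sequence share one normalized
scheme.  Writing ``p0`` for the acceptable and ``p1`` for the unacceptable
failure rate, the raw sequential test accumulates the log-likelihood ratio
of each observation and signals at ``ln((1 - beta)/alpha)``.  Dividing the
increments by

    D = ln( q_hi (1 - q_lo) / (q_lo (1 - q_hi)) ),    q_lo < q_hi,

gives the normalized chart of the applied literature: every failure moves
the score ``1 - s`` toward the limit, every success moves it ``s`` away,
with

    s = ln( (1 - q_lo) / (1 - q_hi) ) / D,
    h = ln( (1 - beta) / alpha ) / D,

a holding barrier at zero that the score cannot cross, and a signal when
the score reaches ``h``.

* Learning phase (LC-CUSUM): H0 is "performance is inadequate".  Successes
  drive the score toward the limit; a signal means proficiency is attained.
  By convention the curve is plotted downward (negative scores, limit
  ``-h``).
* Monitoring phase (CUSUM): H0 is "performance is adequate".  Failures
  drive the score toward the limit; a signal is a deterioration alarm.
  The curve is plotted upward (positive scores, limit ``+h``).

``run_two_phase`` chains them the way a learning-curve study applies them:
the LC-CUSUM runs from case 1, and once it signals, the CUSUM starts from
zero at the next case.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSchemeError, PhaseError, ValidationError

__all__ = [
    "LEARNING",
    "MONITORING",
    "MonitoringScheme",
    "MonitoringTrace",
    "SignalTimeSummary",
    "derive_scheme",
    "run_lc_cusum",
    "run_cusum",
    "run_two_phase",
    "signal_time_monte_carlo",
]

LEARNING = "learning"
MONITORING = "monitoring"

#: Reaching the limit exactly counts as a signal, up to this tolerance.
SIGNAL_ATOL = 1e-12


@dataclass(frozen=True)
class MonitoringScheme:
    """Constants of one chart phase.

    ``s`` and ``h`` are dimensionless score units; ``plot_sign`` is -1 for
    the learning phase (curve plotted below zero) and +1 for monitoring.
    """

    phase: str
    p0: float
    p1: float
    alpha: float
    beta: float
    s: float
    h: float
    plot_sign: int

    def __post_init__(self):
        if self.phase not in (LEARNING, MONITORING):
            raise ValidationError(f"unknown phase {self.phase!r}")
        for name in ("p0", "p1", "alpha", "beta"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DegenerateSchemeError(f"{name}={v} outside (0, 1)")
        if self.p0 == self.p1:
            raise DegenerateSchemeError("p0 == p1 gives a degenerate scheme")
        if not (0.0 < self.s < 1.0):
            raise DegenerateSchemeError(f"s={self.s} outside (0, 1)")
        if self.h <= 0:
            raise DegenerateSchemeError(f"h={self.h} must be positive")

    @property
    def plotted_limit(self) -> float:
        """The decision limit with the plotting sign applied."""
        return self.plot_sign * self.h

    def as_dict(self) -> dict:
        return {
            "phase": self.phase,
            "p0": self.p0,
            "p1": self.p1,
            "alpha": self.alpha,
            "beta": self.beta,
            "s": self.s,
            "h": self.h,
            "plot_sign": self.plot_sign,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


@dataclass(frozen=True)
class MonitoringTrace:
    """Per-case score path of one chart run (or a chained two-phase run).

    ``scores[i]`` is the score after case ``i + 1``'s update, already on the
    plotting sign of its phase (learning scores are <= 0, monitoring >= 0).
    ``signal_index`` is the 1-based case whose update first reached the
    learning limit (proficiency), or the single-phase signal; ``alarm_index``
    is the monitoring-phase alarm case in a chained run.  ``barrier_hits``
    counts updates truncated at the zero holding barrier.
    """

    scores: np.ndarray
    phases: tuple[str, ...]
    signal_index: int | None
    barrier_hits: int
    alarm_index: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if len(self.scores) != len(self.phases):
            raise ValidationError("scores and phase labels differ in length")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-case table (case_index, phase, score, signal flag)."""
        n = len(self)
        idx = np.arange(1, n + 1)
        signal = np.zeros(n, dtype=bool)
        for j in (self.signal_index, self.alarm_index):
            if j is not None:
                signal[j - 1] = True
        return pd.DataFrame(
            {
                "case_index": idx,
                "phase": list(self.phases),
                "score": self.scores,
                "signal": signal,
            }
        )


def derive_scheme(
    p0: float, p1: float, alpha: float, beta: float, phase: str
) -> MonitoringScheme:
    """Derive the normalized Bernoulli scheme constants for one phase.

    The two failure rates are ordered internally as ``q_lo < q_hi`` so that
    ``q_lo`` is the rate under the hypothesis favoured by successes; for the
    monitoring phase that is ``p0 < p1``, for the learning phase the roles
    are reversed (``p1 < p0``: the learning chart tests whether performance
    has come *down* to the adequate rate).

    Parameters
    ----------
    p0, p1
        Acceptable and unacceptable failure rates (probabilities).
    alpha, beta
        Type-I and type-II error rates of the underlying sequential test.
    phase
        ``"learning"`` or ``"monitoring"``.

    Returns
    -------
    MonitoringScheme
        With step constant ``s`` in (0, 1) and positive decision limit ``h``.
    """
    if phase not in (LEARNING, MONITORING):
        raise ValidationError(f"unknown phase {phase!r}")
    for name, v in (("p0", p0), ("p1", p1), ("alpha", alpha), ("beta", beta)):
        if not (0.0 < v < 1.0):
            raise DegenerateSchemeError(f"{name}={v} outside (0, 1)")
    if p0 == p1:
        raise DegenerateSchemeError("p0 == p1 gives a degenerate scheme")
    q_lo, q_hi = sorted((p0, p1))
    if phase == MONITORING and p0 > p1:
        raise DegenerateSchemeError(
            "monitoring phase requires p0 < p1 (acceptable below unacceptable)"
        )
    if phase == LEARNING and p1 > p0:
        raise DegenerateSchemeError(
            "learning phase requires the adequate rate (p1) below p0"
        )
    D = math.log(q_hi * (1 - q_lo) / (q_lo * (1 - q_hi)))
    s = math.log((1 - q_lo) / (1 - q_hi)) / D
    h = math.log((1 - beta) / alpha) / D
    return MonitoringScheme(
        phase=phase,
        p0=p0,
        p1=p1,
        alpha=alpha,
        beta=beta,
        s=s,
        h=h,
        plot_sign=-1 if phase == LEARNING else +1,
    )


def _as_binary(outcomes: Sequence[int]) -> np.ndarray:
    x = np.asarray(outcomes)
    if x.size and not np.isin(x, (0, 1)).all():
        bad = x[~np.isin(x, (0, 1))][0]
        raise ValidationError(f"outcomes must be 0/1, got {bad!r}")
    return x.astype(int)


def _run_chart(
    outcomes: np.ndarray, scheme: MonitoringScheme
) -> tuple[np.ndarray, int | None, int]:
    """Shared recursion in positive internal magnitude.

    The normalized log-likelihood-ratio increment of a failure is ``1 - s``
    and of a success ``-s``; the learning chart accumulates the negated
    increments (evidence for adequate performance), so there each success
    moves the score ``s`` toward the limit and each failure moves it
    ``1 - s`` away, while the monitoring chart moves ``1 - s`` toward on a
    failure and ``s`` away on a success.  Truncation at the zero barrier
    happens after each update.  Returns (scores, 1-based signal index or
    None, barrier hits); scores stop at the signal.
    """
    if scheme.phase == LEARNING:
        toward, away = scheme.s, 1 - scheme.s
        favourable = outcomes == 0
    else:
        toward, away = 1 - scheme.s, scheme.s
        favourable = outcomes == 1
    scores = np.empty(len(outcomes), dtype=float)
    x = 0.0
    barrier_hits = 0
    signal = None
    n_run = 0
    for i, fav in enumerate(favourable):
        x += toward if fav else -away
        if x < 0.0:
            x = 0.0
            barrier_hits += 1
        scores[i] = x
        n_run = i + 1
        if x >= scheme.h - SIGNAL_ATOL:
            signal = i + 1
            break
    return scores[:n_run], signal, barrier_hits


def run_lc_cusum(
    outcomes: Sequence[int], scheme: MonitoringScheme
) -> MonitoringTrace:
    """Run the learning-phase LC-CUSUM over a binary failure sequence.

    The score starts at zero; each success subtracts ``s`` (plotted
    convention), each failure adds ``1 - s``, the score is truncated at the
    zero holding barrier, and the chart signals — proficiency attained — at
    the first case whose update takes the score to ``-h``.  The trace ends
    at the signal.
    """
    if scheme.phase != LEARNING:
        raise PhaseError(f"run_lc_cusum needs a learning scheme, got {scheme.phase}")
    x = _as_binary(outcomes)
    scores, signal, hits = _run_chart(x, scheme)
    return MonitoringTrace(
        scores=-scores + 0.0,  # avoid -0.0 at the barrier
        phases=(LEARNING,) * len(scores),
        signal_index=signal,
        barrier_hits=hits,
    )


def run_cusum(
    outcomes: Sequence[int], scheme: MonitoringScheme
) -> MonitoringTrace:
    """Run the monitoring-phase CUSUM over a binary failure sequence.

    Failures add ``1 - s``, successes subtract ``s``, the score is truncated
    below at zero, and the chart alarms — performance inadequate — at the
    first case whose update reaches ``+h``.
    """
    if scheme.phase != MONITORING:
        raise PhaseError(f"run_cusum needs a monitoring scheme, got {scheme.phase}")
    x = _as_binary(outcomes)
    scores, signal, hits = _run_chart(x, scheme)
    return MonitoringTrace(
        scores=scores,
        phases=(MONITORING,) * len(scores),
        signal_index=signal,
        barrier_hits=hits,
    )


def run_two_phase(
    outcomes: Sequence[int],
    learning: MonitoringScheme,
    monitoring: MonitoringScheme,
) -> MonitoringTrace:
    """Chain the LC-CUSUM into the CUSUM over one case sequence.

    The LC-CUSUM runs from case 1.  If it signals at case ``k`` (proficiency
    attained; ``k`` itself belongs to the learning phase), the CUSUM restarts
    from score zero on cases ``k+1 … n``.  If the LC-CUSUM never signals, no
    monitoring phase occurs.

    Returns a single trace whose ``signal_index`` is the proficiency case and
    whose ``alarm_index`` is the monitoring alarm case (or None).
    """
    x = _as_binary(outcomes)
    lc = run_lc_cusum(x, learning)
    if lc.signal_index is None:
        return lc
    k = lc.signal_index
    mon = run_cusum(x[k:], monitoring)
    alarm = None if mon.signal_index is None else k + mon.signal_index
    return MonitoringTrace(
        scores=np.concatenate([lc.scores, mon.scores]),
        phases=lc.phases + mon.phases,
        signal_index=k,
        barrier_hits=lc.barrier_hits + mon.barrier_hits,
        alarm_index=alarm,
    )


@dataclass(frozen=True)
class SignalTimeSummary:
    """Monte-Carlo operating characteristics of one chart."""

    signal_fraction: float
    mean_signal_time: float | None
    quantiles: dict[float, float]
    replicates: int
    horizon: int
    true_rate: float


def signal_time_monte_carlo(
    scheme: MonitoringScheme,
    true_rate: float,
    horizon: int,
    replicates: int,
    seed: int,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
) -> SignalTimeSummary:
    """Estimate signal probability and signal-time distribution by simulation.

    Simulates ``replicates`` i.i.d. Bernoulli(``true_rate``) failure
    sequences of length ``horizon``, runs the phase-appropriate chart on
    each, and summarizes the first signal times.  Deterministic under a
    fixed seed.
    """
    if not (0.0 <= true_rate <= 1.0):
        raise ValidationError(f"true_rate={true_rate} outside [0, 1]")
    if replicates < 1 or horizon < 1:
        raise ValidationError("replicates and horizon must be >= 1")
    rng = np.random.default_rng(seed)
    fails = rng.random((replicates, horizon)) < true_rate
    if scheme.phase == LEARNING:
        favourable, toward, away = ~fails, scheme.s, 1 - scheme.s
    else:
        favourable, toward, away = fails, 1 - scheme.s, scheme.s
    score = np.zeros(replicates)
    signal_at = np.full(replicates, -1, dtype=int)
    active = np.ones(replicates, dtype=bool)
    for i in range(horizon):
        step = np.where(favourable[:, i], toward, -away)
        score = np.maximum(score + np.where(active, step, 0.0), 0.0)
        newly = active & (score >= scheme.h - SIGNAL_ATOL)
        signal_at[newly] = i + 1
        active &= ~newly
        if not active.any():
            break
    signalled = signal_at > 0
    times = signal_at[signalled].astype(float)
    return SignalTimeSummary(
        signal_fraction=float(signalled.mean()),
        mean_signal_time=float(times.mean()) if times.size else None,
        quantiles=(
            {float(q): float(np.quantile(times, q)) for q in quantiles}
            if times.size
            else {}
        ),
        replicates=replicates,
        horizon=horizon,
        true_rate=true_rate,
    )
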