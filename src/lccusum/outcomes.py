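"""Case-series outcome statistics.

Covers the descriptive side of a learning-curve case series: overall and
windowed healing-abnormality rates, the running (cumulative) rate curve,
anterior-compartment POP-Q staging and anatomic cure, the pre/post paired
comparison of the Ba point, and the multivariable logistic model of
healing-abnormality risk.

Rates are computed over follow-up-complete cases: a patient lost to
follow-up can contribute neither an observed abnormality nor an observed
absence of one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CaseSeries, PopqExam
from .errors import ConvergenceError, ValidationError

__all__ = [
    "OutcomeSummary",
    "PairedComparison",
    "LogisticFit",
    "summarize_outcomes",
    "stage_anterior",
    "classify_cure",
    "compare_ba_prepost",
    "fit_healing_model",
    "DEFAULT_COVARIATES",
]

#: Covariates of the adjusted healing-abnormality model, in report order.
DEFAULT_COVARIATES = ("age", "bmi", "case_index", "operation_time", "parity")

_COVARIATE_LABELS = {
    "age": "Age (years)",
    "bmi": "BMI (kg/m^2)",
    "case_index": "Surgeon case volume",
    "operation_time": "Operation time",
    "parity": "Parity",
}


@dataclass(frozen=True)
class OutcomeSummary:
    """Event counts and rates of one case series (follow-up-complete cases)."""

    n: int
    events: int
    overall_rate: float
    window: int
    first_window_rate: float
    after_window_rate: float
    running_rate: np.ndarray
    cure_count: int | None
    cure_rate: float | None
    reoperation_count: int | None

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "events": self.events,
            "overall_rate": self.overall_rate,
            "window": self.window,
            "first_window_rate": self.first_window_rate,
            "after_window_rate": self.after_window_rate,
            "cure_count": self.cure_count,
            "cure_rate": self.cure_rate,
            "reoperation_count": self.reoperation_count,
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def summarize_outcomes(series: CaseSeries, window: int = 49) -> OutcomeSummary:
    """Summarize healing-abnormality outcomes of a case series.

    Parameters
    ----------
    series
        The full case series; only follow-up-complete cases enter the rates.
    window
        Split point for the early/late comparison: the first ``window``
        complete cases versus the rest.

    Returns
    -------
    OutcomeSummary
        With the running rate (cumulative events / cases at each case) and,
        when postoperative exams are available, the anatomic cure count
        (postoperative anterior stage <= 1) over the complete cases.
    """
    complete = series.complete()
    n = len(complete)
    if n == 0:
        raise ValidationError("series has no follow-up-complete cases")
    if not (0 < window <= n):
        raise ValidationError(f"window {window} outside [1, {n}]")
    y = complete.outcomes
    events = int(y.sum())
    running = np.cumsum(y) / np.arange(1, n + 1)
    first = float(y[:window].mean())
    after = float(y[window:].mean()) if window < n else 0.0
    with_post = [r for r in complete if r.popq_post is not None]
    if with_post:
        cures = sum(classify_cure(r.popq_post) == "cure" for r in with_post)
        cure_count, cure_rate = int(cures), cures / n
    else:
        cure_count = cure_rate = None
    reop = [r.reoperation for r in complete if r.reoperation is not None]
    return OutcomeSummary(
        n=n,
        events=events,
        overall_rate=events / n,
        window=window,
        first_window_rate=first,
        after_window_rate=after,
        running_rate=running,
        cure_count=cure_count,
        cure_rate=cure_rate,
        reoperation_count=int(np.sum(reop)) if reop else None,
    )


def stage_anterior(exam: PopqExam) -> int:
    """Anterior-compartment POP-Q stage (0-4) from Aa, Ba and TVL.

    The leading edge is ``max(Aa, Ba)``.  Stage 0 requires full support
    (Aa = Ba = -3); stage 1 a leading edge above -1 cm; stage 2 an edge
    within 1 cm of the hymen; stage 3 an edge beyond +1 cm but with at
    least 2 cm of vagina unprolapsed; stage 4 essentially complete
    eversion (edge >= TVL - 2).
    """
    for name in ("Aa", "Ba", "TVL"):
        if getattr(exam, name) is None:
            raise ValidationError(f"POP-Q point {name} required for staging")
    edge = max(exam.Aa, exam.Ba)
    if exam.Aa == -3.0 and exam.Ba == -3.0:
        return 0
    if edge < -1.0:
        return 1
    if edge <= 1.0:
        return 2
    if edge < exam.TVL - 2.0:
        return 3
    return 4


def classify_cure(exam_post: PopqExam) -> str:
    """Anatomic result of the repair: ``"cure"`` iff postoperative anterior
    stage <= 1, ``"failure"`` for stage >= 2."""
    return "cure" if stage_anterior(exam_post) <= 1 else "failure"


@dataclass(frozen=True)
class PairedComparison:
    """Pre/post paired comparison of one POP-Q point."""

    n_pairs: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    mean_diff: float
    t_stat: float
    p_value: float


def compare_ba_prepost(series: CaseSeries) -> PairedComparison:
    """Paired two-sided t-test of the Ba point, pre versus 12 months.

    Uses every record with Ba in both exams; requires at least two pairs.
    """
    pre, post = [], []
    for r in series:
        if (
            r.popq_pre is not None
            and r.popq_post is not None
            and r.popq_pre.Ba is not None
            and r.popq_post.Ba is not None
        ):
            pre.append(r.popq_pre.Ba)
            post.append(r.popq_post.Ba)
    if len(pre) < 2:
        raise ValidationError("need >= 2 cases with Ba in both exams")
    pre_a, post_a = np.array(pre), np.array(post)
    diff = post_a - pre_a
    if np.allclose(diff.std(ddof=1), 0.0):
        # Degenerate paired test: constant differences.
        t_stat = 0.0 if np.allclose(diff.mean(), 0.0) else np.inf * np.sign(diff.mean())
        p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    else:
        t_stat, p = stats.ttest_rel(post_a, pre_a)
    return PairedComparison(
        n_pairs=len(pre),
        mean_pre=float(pre_a.mean()),
        sd_pre=float(pre_a.std(ddof=1)),
        mean_post=float(post_a.mean()),
        sd_post=float(post_a.std(ddof=1)),
        mean_diff=float(diff.mean()),
        t_stat=float(t_stat),
        p_value=float(p),
    )


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``table`` has one row per covariate (coef, se, odds_ratio, ci_low,
    ci_high, p_value); the intercept is kept in ``intercept``.  Cox & Snell
    R^2 = 1 - exp((2/n)(LL_null - LL_model)).
    """

    table: pd.DataFrame
    intercept: float
    llf: float
    llnull: float
    cox_snell_r2: float
    n_used: int

    def as_dict(self) -> dict:
        return {
            "covariates": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.table.iterrows()
            },
            "intercept": self.intercept,
            "llf": self.llf,
            "llnull": self.llnull,
            "cox_snell_r2": self.cox_snell_r2,
            "n_used": self.n_used,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def fit_healing_model(
    series: CaseSeries,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    use_all_cases: bool = False,
    level: float = 0.95,
) -> LogisticFit:
    """Adjusted odds ratios for healing abnormality by logistic regression.

    Regresses the binary outcome on the requested covariates (default: age,
    BMI, surgeon case volume, operation time, parity, each entering
    linearly; case volume as the raw 1-based order of operation).  Only
    cases with all covariates present are used; by default the fit is
    restricted to follow-up-complete cases.

    Returns Wald confidence intervals and p-values (mirroring standard
    statistical-package output) and Cox & Snell R^2.

    Raises
    ------
    ConvergenceError
        On complete separation or other MLE non-convergence — never a
        silently inflated estimate.
    ValidationError
        If a covariate is constant, the outcome is constant, or fewer than
        ``len(covariates) + 1`` usable cases remain.
    """
    pool = series if use_all_cases else series.complete()
    rows = []
    for r in pool:
        vals = {c: getattr(r, c) for c in covariates}
        if any(v is None for v in vals.values()):
            continue
        rows.append({"outcome": r.outcome, **vals})
    df = pd.DataFrame(rows)
    if len(df) < len(covariates) + 1:
        raise ValidationError(
            f"only {len(df)} usable cases for {len(covariates)} covariates"
        )
    y = df["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValidationError("outcome is constant; model is not identifiable")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValidationError(f"covariate {c!r} is constant")
    X = sm.add_constant(df[list(covariates)].astype(float), prepend=True)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    if np.abs(res.params.to_numpy()).max() > 50:
        raise ConvergenceError(
            "implausibly large coefficient magnitude: likely quasi-separation"
        )
    z = stats.norm.ppf(0.5 + level / 2)
    coefs = res.params[list(covariates)]
    ses = res.bse[list(covariates)]
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "odds_ratio": np.exp(coefs),
            "ci_low": np.exp(coefs - z * ses),
            "ci_high": np.exp(coefs + z * ses),
            "p_value": res.pvalues[list(covariates)],
        }
    )
    n = len(df)
    return LogisticFit(
        table=table,
        intercept=float(res.params["const"]),
        llf=float(res.llf),
        llnull=float(res.llnull),
        cox_snell_r2=float(1.0 - np.exp((2.0 / n) * (res.llnull - res.llf))),
        n_used=n,
    )
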