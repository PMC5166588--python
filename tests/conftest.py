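"""Shared fixtures: study-like schemes, small series builders, and the
(expensive, run-once) odds-ratio recovery experiment."""

from __future__ import annotations

import math

import numpy as np
import pytest

import lccusum as lc

# The two chart schemes of the study figure: monitoring rates = (pooled
# estimate, upper bound), learning rates = (upper bound + 10 pp, upper bound).
MON_RATES = (0.105, 0.172)
LRN_RATES = (0.272, 0.172)
ALPHA, BETA = 0.05, 0.20


@pytest.fixture(scope="session")
def monitoring_scheme() -> lc.MonitoringScheme:
    return lc.derive_scheme(*MON_RATES, ALPHA, BETA, lc.MONITORING)


@pytest.fixture(scope="session")
def learning_scheme() -> lc.MonitoringScheme:
    return lc.derive_scheme(*LRN_RATES, ALPHA, BETA, lc.LEARNING)


@pytest.fixture(scope="session")
def prior_studies() -> list[lc.PriorStudy]:
    return [
        lc.PriorStudy("study-a", 76, events=8),
        lc.PriorStudy("study-b", 48, events=5),
    ]


def make_series(outcomes, **record_kwargs) -> lc.CaseSeries:
    """Minimal case series from an outcome vector."""
    return lc.CaseSeries(
        lc.CaseRecord(case_index=i + 1, outcome=int(y), **record_kwargs)
        for i, y in enumerate(outcomes)
    )


def llr_signal_oracle(outcomes, p0, p1, alpha, beta, phase):
    """Independent chart oracle on the raw log-likelihood-ratio scale.

    Accumulates the unnormalized LLR increments with a holding barrier at
    zero and signals at ln((1-beta)/alpha); the normalized chart is this
    one divided by D, so signal indices must agree.
    """
    if phase == lc.MONITORING:
        q_lo, q_hi = p0, p1
        inc_fail = math.log(q_hi / q_lo)
        inc_succ = math.log((1 - q_hi) / (1 - q_lo))
    else:  # learning: evidence for the adequate (lower) rate
        q_lo, q_hi = p1, p0
        inc_fail = math.log(q_lo / q_hi)
        inc_succ = math.log((1 - q_lo) / (1 - q_hi))
    limit = math.log((1 - beta) / alpha)
    x = 0.0
    for i, y in enumerate(outcomes):
        x = max(x + (inc_fail if y else inc_succ), 0.0)
        if x >= limit - 1e-12:
            return i + 1
    return None


@pytest.fixture(scope="session")
def or_recovery_experiment():
    """200 seeded replicates of the parameter-recovery experiment.

    Cohorts of n = 5000 are generated with the direct logistic mechanism
    (case-volume log-odds ln 0.96, intercept 2.0, no other effects), and the
    one-covariate model is refit to each.  Returns the arrays of fitted
    odds ratios and Wald 95% CI bounds.  Session-scoped because both the
    generator's recovery property and the chart-acceptance coverage check
    consume the same experiment.
    """
    slope = math.log(0.96)
    ors, lo, hi = [], [], []
    for seed in range(200):
        spec = lc.CohortSpec(
            n=5000,
            logit_intercept=2.0,
            logit_slopes={"case_index": slope},
            seed=seed,
        )
        series = lc.generate_cohort(spec)
        fit = lc.fit_healing_model(series, covariates=("case_index",))
        row = fit.table.loc["case_index"]
        ors.append(row["odds_ratio"])
        lo.append(row["ci_low"])
        hi.append(row["ci_high"])
    return np.array(ors), np.array(lo), np.array(hi)
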