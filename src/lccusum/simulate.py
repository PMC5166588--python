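"""Seeded synthetic case-series generator with a learning-curve mechanism.

Emulates a single-surgeon consecutive series in which the probability of a
healing abnormality declines with case volume.  Two outcome mechanisms are
available:

* ``change_point`` — a novice failure rate up to case ``tau``, an expert
  rate thereafter (the pattern of a series whose events all fall in an
  early window);
* ``logistic_decay`` — a smooth decline from the novice to the expert rate
  centred at ``tau`` with width ``kappa``;

or, alternatively, a *direct logistic mechanism*: the per-case failure
log-odds are ``intercept + sum(slope_c * covariate_c)``, with
``case_index`` available as a covariate — the generating process of the
adjusted-odds-ratio model, used for parameter-recovery checks.

Covariates are drawn independently from truncated normals calibrated to a
typical prolapse-repair cohort; POP-Q exams are drawn around a severe
preoperative and a well-supported postoperative anterior compartment.  One
master seed is split into independent sub-streams for outcomes,
covariates and POP-Q draws, so adding fields never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort import CaseRecord, CaseSeries, PopqExam
from .errors import ValidationError

__all__ = ["CohortSpec", "generate_cohort", "study_like_defaults"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Exactly one mechanism drives the outcome: the learning model
    (``model`` + rates + ``tau``) by default, or the direct logistic
    mechanism when ``logit_intercept`` is set.
    """

    n: int = 114
    model: str = "change_point"  # change_point | logistic_decay
    p_novice: float = 0.102
    p_expert: float = 0.0
    tau: int = 49
    kappa: float = 10.0
    age_mean: float = 65.8
    age_sd: float = 7.0
    bmi_mean: float = 25.1
    bmi_sd: float = 3.0
    parity_mean: float = 4.0
    parity_sd: float = 1.7
    optime_mean: float = 69.1
    optime_sd: float = 33.7
    pre_ba_mean: float = 2.5
    pre_ba_sd: float = 1.6
    post_ba_mean: float = -2.8
    post_ba_sd: float = 0.8
    tvl_mean: float = 8.0
    tvl_sd: float = 1.0
    logit_intercept: float | None = None
    logit_slopes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.model not in ("change_point", "logistic_decay"):
            raise ValidationError(f"unknown learning model {self.model!r}")
        if not (0.0 <= self.p_expert <= self.p_novice <= 1.0):
            raise ValidationError(
                f"need 0 <= p_expert ({self.p_expert}) <= p_novice "
                f"({self.p_novice}) <= 1"
            )
        if not (1 <= self.tau <= self.n):
            raise ValidationError(f"tau={self.tau} outside [1, n={self.n}]")
        if self.kappa <= 0:
            raise ValidationError(f"kappa must be positive, got {self.kappa}")
        if self.logit_intercept is not None and not self.logit_slopes:
            raise ValidationError(
                "direct logistic mechanism needs at least one slope"
            )
        object.__setattr__(self, "logit_slopes", dict(self.logit_slopes))

    @property
    def uses_direct_mechanism(self) -> bool:
        return self.logit_intercept is not None

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def study_like_defaults(seed: int = 0) -> CohortSpec:
    """The calibrated default cohort: 114 cases, change-point learning curve
    with all failure risk concentrated in the first 49 cases (novice rate
    ~10%, expert rate 0), covariates per a typical prolapse-repair cohort."""
    return CohortSpec(seed=seed)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _floor_matched_mu(target_mean: float, sd: float, lo: float) -> float:
    """Latent normal mean whose floor-at-``lo`` draw has the target mean.

    POP-Q points are bounded below at -3 cm (full support); a cohort whose
    printed mean sits near that bound has a point mass there.  We emulate it
    by flooring a latent normal, and moment-match the latent mean so the
    floored draw recovers the printed mean: E[max(X, lo)] =
    lo + (mu - lo) * Phi((mu - lo)/sd) + sd * phi((mu - lo)/sd).
    """
    if target_mean - lo > 4 * sd:  # bound is irrelevant
        return target_mean

    def floored_mean(mu):
        z = (mu - lo) / sd
        return lo + (mu - lo) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)

    from scipy.optimize import brentq

    return brentq(
        lambda mu: floored_mean(mu) - target_mean,
        lo - 8 * sd,
        target_mean + 8 * sd,
        xtol=1e-10,
    )


def _failure_probabilities(spec: CohortSpec, covs: dict[str, np.ndarray]) -> np.ndarray:
    i = np.arange(1, spec.n + 1)
    if spec.uses_direct_mechanism:
        eta = np.full(spec.n, float(spec.logit_intercept))
        for name, slope in spec.logit_slopes.items():
            x = i.astype(float) if name == "case_index" else covs[name]
            eta = eta + slope * x
        return 1.0 / (1.0 + np.exp(-eta))
    if spec.model == "change_point":
        return np.where(i <= spec.tau, spec.p_novice, spec.p_expert)
    # logistic_decay: smooth transition from novice to expert rate at tau.
    w = 1.0 / (1.0 + np.exp(-(spec.tau - i) / spec.kappa))
    return spec.p_expert + (spec.p_novice - spec.p_expert) * w


def generate_cohort(spec: CohortSpec) -> CaseSeries:
    """Generate one synthetic case series; deterministic under a fixed seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_outcome, rng_cov, rng_popq = (np.random.default_rng(s) for s in ss.spawn(3))
    n = spec.n

    covs = {
        "age": _trunc_normal(rng_cov, spec.age_mean, spec.age_sd, 30, 90, n),
        "bmi": _trunc_normal(rng_cov, spec.bmi_mean, spec.bmi_sd, 15, 45, n),
        "parity": np.round(
            _trunc_normal(rng_cov, spec.parity_mean, spec.parity_sd, 0, 12, n)
        ).astype(int),
        "operation_time": _trunc_normal(
            rng_cov, spec.optime_mean, spec.optime_sd, 10, 240, n
        ),
    }

    p = _failure_probabilities(spec, covs)
    outcomes = (rng_outcome.random(n) < p).astype(int)

    tvl = _trunc_normal(rng_popq, spec.tvl_mean, spec.tvl_sd, 6.0, 12.0, n)
    pre_mu = _floor_matched_mu(spec.pre_ba_mean, spec.pre_ba_sd, -3.0)
    post_mu = _floor_matched_mu(spec.post_ba_mean, spec.post_ba_sd, -3.0)
    pre_ba = np.clip(rng_popq.normal(pre_mu, spec.pre_ba_sd, n), -3.0, tvl)
    post_ba = np.clip(rng_popq.normal(post_mu, spec.post_ba_sd, n), -3.0, tvl)
    gh = _trunc_normal(rng_popq, 4.0, 1.0, 0.5, 8.0, n)
    pb = _trunc_normal(rng_popq, 3.0, 1.0, 0.5, 8.0, n)
    # Aa tracks the leading edge but is anatomically capped at +/-3 cm.
    pre_aa = np.clip(pre_ba, -3.0, 3.0)
    post_aa = np.clip(post_ba, -3.0, 3.0)

    records = []
    for k in range(n):
        pre = PopqExam(
            Aa=float(pre_aa[k]),
            Ba=float(pre_ba[k]),
            TVL=float(tvl[k]),
            GH=float(gh[k]),
            PB=float(pb[k]),
            timing="preoperative",
        )
        post = PopqExam(
            Aa=float(post_aa[k]),
            Ba=float(post_ba[k]),
            TVL=float(tvl[k]),
            GH=float(gh[k]),
            PB=float(pb[k]),
            timing="12-month",
        )
        records.append(
            CaseRecord(
                case_index=k + 1,
                outcome=int(outcomes[k]),
                age=float(covs["age"][k]),
                bmi=float(covs["bmi"][k]),
                parity=int(covs["parity"][k]),
                operation_time=float(covs["operation_time"][k]),
                popq_pre=pre,
                popq_post=post,
                followup_complete=True,
            )
        )
    return CaseSeries(records)
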