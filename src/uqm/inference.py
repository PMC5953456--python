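"""Likelihood machinery for the UQM response model.

Each survey condition observes ``yes ~ Binomial(n, lambda)`` with
marginal "yes" probability ``lambda = p * pi_s + (1 - p) * pi_n``.
This module provides the binomial log-likelihood in the prevalence
``pi_s``, the shared-prevalence maximum-likelihood estimate pooling
several conditions, and the one-degree-of-freedom likelihood-ratio test
of equal prevalence across two randomization designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .design import UQMDesign
from .estimation import SurveyCounts, estimate_prevalence

# One survey condition is fully described by its counts, which carry
# their design; no separate wrapper type is needed.
ConditionData = SurveyCounts


@dataclass(frozen=True)
class CombinedEstimate:
    """Shared-prevalence MLE across conditions with Wald interval."""

    pi_hat: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio test of equal prevalence across two designs."""

    chi2: float
    df: int
    p_value: float
    pi_hat_shared: float
    pi_hats: tuple[float, float]


def yes_probability(design: UQMDesign, pi_s: float) -> float:
    """Marginal "yes" probability lambda = p*pi_s + (1-p)*pi_n."""
    p, pi_n = float(design.p), float(design.pi_n)
    lam = p * pi_s + (1 - p) * pi_n
    # guard tiny float overshoot at the boundaries
    return min(1.0, max(0.0, lam))


def log_likelihood(condition: ConditionData, pi_s: float) -> float:
    """Binomial log-likelihood of one condition at prevalence ``pi_s``.

    The binomial coefficient is omitted (constant in ``pi_s``).  Returns
    ``-inf`` when a degenerate marginal probability contradicts a
    nonzero count.
    """
    lam = yes_probability(condition.design, pi_s)
    out = 0.0
    if condition.yes:
        out += -math.inf if lam == 0.0 else condition.yes * math.log(lam)
    if condition.no:
        out += -math.inf if lam == 1.0 else condition.no * math.log(1.0 - lam)
    return out


def _total_log_likelihood(conditions: list[ConditionData], pi_s: float) -> float:
    return sum(log_likelihood(c, pi_s) for c in conditions)


def fit_shared_prevalence(
    conditions: list[ConditionData], level: float = 0.95
) -> CombinedEstimate:
    """Maximum-likelihood estimate of one prevalence shared by all conditions.

    The summed log-likelihood is maximized over ``pi_s`` in [0, 1] by a
    1000-point grid pre-scan followed by bounded scalar optimization
    (absolute tolerance 1e-10).  The standard error comes from the
    observed Fisher information at the maximum,

        I(pi_s) = sum_i p_i^2 * ( yes_i / lambda_i^2 + no_i / (1-lambda_i)^2 )

    and the confidence interval is Wald at the requested level.
    """
    if not conditions:
        raise ValueError("empty input: need at least one condition")
    if sum(c.n for c in conditions) == 0:
        raise ValueError("empty input: all conditions have zero counts")

    grid = np.linspace(0.0, 1.0, 1000)
    values = np.zeros_like(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in conditions:
            p, pi_n = float(c.design.p), float(c.design.pi_n)
            lam = np.clip(p * grid + (1 - p) * pi_n, 0.0, 1.0)
            term = np.zeros_like(grid)
            if c.yes:
                term += np.where(lam > 0, c.yes * np.log(lam), -np.inf)
            if c.no:
                term += np.where(lam < 1, c.no * np.log1p(-lam), -np.inf)
            values += term
    best = int(np.argmax(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -_total_log_likelihood(conditions, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    pi_hat = float(res.x)

    info = 0.0
    for c in conditions:
        p = float(c.design.p)
        lam = yes_probability(c.design, pi_hat)
        if 0.0 < lam < 1.0:
            info += p * p * (c.yes / lam**2 + c.no / (1.0 - lam) ** 2)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    z = norm.ppf(0.5 + level / 2)
    return CombinedEstimate(
        pi_hat=pi_hat, se=se, ci_low=pi_hat - z * se, ci_high=pi_hat + z * se,
        level=level,
    )


def _condition_max_log_likelihood(condition: ConditionData) -> tuple[float, float]:
    """Per-condition maximum of the likelihood over pi_s in [0, 1].

    The unconstrained maximum sits at lambda = a (the observed
    proportion); when the implied pi_s = (a - (1-p) pi_n) / p leaves
    [0, 1] the maximum of the constrained problem is at the nearest
    boundary (the likelihood is unimodal in pi_s).
    """
    if condition.n == 0:
        raise ValueError("empty condition")
    pi_unc = estimate_prevalence(condition).pi_hat
    pi_c = min(1.0, max(0.0, pi_unc))
    return log_likelihood(condition, pi_c), pi_c


def lr_test(cond1: ConditionData, cond2: ConditionData) -> LRTestResult:
    """Likelihood-ratio test of H0: equal prevalence under both designs.

    H1 allows each condition its own prevalence (each maximized over
    [0, 1]); H0 fits one shared prevalence.  The statistic
    ``2 * (llH1 - llH0)`` is referred to a chi-square distribution with
    one degree of freedom.
    """
    ll1_a, pi1 = _condition_max_log_likelihood(cond1)
    ll1_b, pi2 = _condition_max_log_likelihood(cond2)
    shared = fit_shared_prevalence([cond1, cond2])
    ll0 = _total_log_likelihood([cond1, cond2], shared.pi_hat)
    stat = 2.0 * (ll1_a + ll1_b - ll0)
    if stat < 0:
        if stat < -1e-8:
            raise RuntimeError(f"negative LR statistic {stat}")
        stat = 0.0
    return LRTestResult(
        chi2=stat,
        df=1,
        p_value=float(chi2_sf(stat)),
        pi_hat_shared=shared.pi_hat,
        pi_hats=(pi1, pi2),
    )


def chi2_sf(stat: float, df: int = 1) -> float:
    """Upper-tail chi-square probability."""
    return float(chi2.sf(stat, df))


def inverse_variance_combined(conditions: list[ConditionData]) -> float:
    """Inverse-variance-weighted average of per-condition estimates.

    Cross-check utility for the pooled MLE: on well-behaved data the two
    agree to the printed decimal, but the MLE is the primary pooled
    estimate.
    """
    ests = [estimate_prevalence(c) for c in conditions]
    weights = [1.0 / e.se**2 for e in ests]
    return sum(w * e.pi_hat for w, e in zip(weights, ests)) / sum(weights)
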