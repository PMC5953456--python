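"""Power and sample-size analysis for UQM surveys.

Two questions arise when planning a randomized-response survey: how
many respondents are needed to show that a sensitive behavior exists at
all (test of H0: pi_s = 0 under one design), and how many to detect a
difference in apparent prevalence between two randomization designs.
Both are answered here with normal-approximation (Wald) power formulas;
the difference test also offers a Monte-Carlo mode that simulates
surveys and applies the likelihood-ratio test.

Power increases with the randomization probability ``p``: a larger
share of the sample actually answers the sensitive question, so the
design noise (the neutral question's contribution to the "yes" rate)
is diluted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .design import UQMDesign
from .estimation import SurveyCounts
from .inference import lr_test


@dataclass(frozen=True)
class PowerSpec:
    """One power scenario: one design tests pi_s = 0, two test a difference."""

    designs: tuple[UQMDesign, ...]
    pi_s_true: tuple[float, ...]
    n: int
    alpha: float = 0.05
    sided: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if len(self.designs) != len(self.pi_s_true) or not 1 <= len(self.designs) <= 2:
            raise ValueError("need one or two (design, prevalence) pairs")
        if any(not 0 <= pi <= 1 for pi in self.pi_s_true):
            raise ValueError("prevalences must lie in [0, 1]")

    def power(self) -> float:
        if len(self.designs) == 1:
            return power_prevalence_test(
                self.designs[0], self.pi_s_true[0], self.n, self.alpha, self.sided
            )
        return power_difference_test(
            *self.designs, *self.pi_s_true, self.n, self.alpha, self.sided
        )


def _z(alpha: float, sided: str) -> float:
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    return norm.ppf(1 - alpha / (1 if sided == "one" else 2))


def power_prevalence_test(
    design: UQMDesign,
    pi_s_true: float,
    n: int,
    alpha: float = 0.05,
    sided: str = "one",
) -> float:
    """Power of the Wald test of H0: pi_s = 0 under one design.

    With marginal "yes" probabilities ``lambda0 = (1-p) pi_n`` under the
    null and ``lambda1 = p pi_s + (1-p) pi_n`` under the alternative,
    and standard errors ``SE_k = sqrt(lambda_k (1-lambda_k) / (n p^2))``
    on the prevalence scale, the one-sided power is

        Phi( (pi_s - z_{1-alpha} * SE0) / SE1 )

    (two-sided replaces ``z_{1-alpha}`` with ``z_{1-alpha/2}``).
    A true prevalence of exactly zero returns ``alpha`` by convention.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= pi_s_true <= 1:
        raise ValueError("pi_s_true must be in [0, 1]")
    if n < 2:
        raise ValueError("n must be at least 2")
    if pi_s_true == 0:
        return alpha
    p, pi_n = float(design.p), float(design.pi_n)
    lam0 = (1 - p) * pi_n
    lam1 = p * pi_s_true + (1 - p) * pi_n
    se0 = math.sqrt(lam0 * (1 - lam0) / (n * p * p))
    se1 = math.sqrt(lam1 * (1 - lam1) / (n * p * p))
    return float(norm.cdf((pi_s_true - _z(alpha, sided) * se0) / se1))


def required_sample_size(
    design: UQMDesign,
    pi_s_true: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    sided: str = "one",
) -> int:
    """Smallest n whose analytic power reaches ``target_power``."""
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    lo, hi = 2, 4
    while power_prevalence_test(design, pi_s_true, hi, alpha, sided) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10**9:
            raise ValueError("infeasible design: power never reaches target")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_prevalence_test(design, pi_s_true, mid, alpha, sided) >= target_power:
            hi = mid
        else:
            lo = mid
    # monotone in n up to float fuzz; scan the immediate neighborhood
    for n in range(max(2, hi - 2), hi + 3):
        if power_prevalence_test(design, pi_s_true, n, alpha, sided) >= target_power:
            return n
    return hi


def power_difference_test(
    design1: UQMDesign,
    design2: UQMDesign,
    pi1: float,
    pi2: float,
    n: int,
    alpha: float = 0.05,
    sided: str = "two",
) -> float:
    """Analytic power for detecting pi1 != pi2 across two designs.

    Two-sample Wald test of delta = pi1 - pi2 = 0 with per-condition
    variances ``lambda_i (1-lambda_i) / (n p_i^2)`` evaluated at the
    assumed prevalences (n respondents per condition).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    delta = pi1 - pi2
    se = 0.0
    for d, pi in ((design1, pi1), (design2, pi2)):
        p, pi_n = float(d.p), float(d.pi_n)
        lam = p * pi + (1 - p) * pi_n
        se += lam * (1 - lam) / (n * p * p)
    se = math.sqrt(se)
    z = _z(alpha, sided)
    if sided == "one":
        return float(norm.cdf(delta / se - z))
    return float(norm.cdf(delta / se - z) + norm.cdf(-delta / se - z))


def power_difference_monte_carlo(
    design1: UQMDesign,
    design2: UQMDesign,
    pi1: float,
    pi2: float,
    n: int,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo power of the likelihood-ratio test for a difference.

    Simulates honest-responding yes counts for both conditions, applies
    :func:`uqm.inference.lr_test` at level ``alpha``, and returns the
    rejection fraction with its binomial Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    lam1 = float(design1.p) * pi1 + (1 - float(design1.p)) * float(design1.pi_n)
    lam2 = float(design2.p) * pi2 + (1 - float(design2.p)) * float(design2.pi_n)
    yes1 = rng.binomial(n, lam1, size=n_sims)
    yes2 = rng.binomial(n, lam2, size=n_sims)
    rejections = 0
    for y1, y2 in zip(yes1, yes2):
        c1 = SurveyCounts("sim", design1, int(y1), n - int(y1))
        c2 = SurveyCounts("sim", design2, int(y2), n - int(y2))
        if lr_test(c1, c2).p_value < alpha:
            rejections += 1
    frac = rejections / n_sims
    return frac, math.sqrt(frac * (1 - frac) / n_sims)


def power_table(
    designs: list[UQMDesign],
    sample_sizes: list[int],
    prevalences: list[float],
    alpha: float = 0.05,
    sided: str = "one",
) -> list[dict]:
    """Analytic power over a grid of (design, n, pi_s) for reporting."""
    rows = []
    for d in designs:
        for n in sample_sizes:
            for pi in prevalences:
                rows.append(
                    {
                        "design_label": d.label,
                        "p": float(d.p),
                        "n": n,
                        "pi_s": pi,
                        "alpha": alpha,
                        "sided": sided,
                        "power": power_prevalence_test(d, pi, n, alpha, sided),
                    }
                )
    return rows
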