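"""Closed-form prevalence estimation for the unrelated question model.

With randomization probability ``p`` and neutral "yes" probability
``pi_n`` known by design, the observed overall "yes" proportion ``a``
identifies the sensitive-attribute prevalence through the moment
estimator

    pi_hat = (a - (1 - p) * pi_n) / p

with sampling variance  Var(pi_hat) = a (1 - a) / (n p^2)  and a Wald
95% confidence interval.  The point estimate is deliberately *not*
truncated to [0, 1]: truncation would bias averages over replicated
surveys; callers who need a displayable proportion can ask for the
truncated value explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy.stats import norm

from .design import UQMDesign


@dataclass(frozen=True)
class SurveyCounts:
    """Aggregated yes/no counts for one item under one design."""

    item: str
    design: UQMDesign
    yes: int
    no: int

    def __post_init__(self) -> None:
        if self.yes < 0 or self.no < 0:
            raise ValueError(f"counts must be non-negative, got {self.yes}/{self.no}")

    @property
    def n(self) -> int:
        return self.yes + self.no


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point estimate with Wald standard error and confidence bounds."""

    pi_hat: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    a: float
    n: int

    @property
    def pi_hat_truncated(self) -> float:
        """The point estimate clipped into [0, 1] for display."""
        return min(1.0, max(0.0, self.pi_hat))


def yes_proportion(counts: SurveyCounts) -> float:
    """Observed overall "yes" proportion ``a`` (both branches pooled)."""
    if counts.n == 0:
        raise ValueError("empty input: yes + no must be at least 1")
    return counts.yes / counts.n


def estimate_prevalence(counts: SurveyCounts, level: float = 0.95) -> PrevalenceEstimate:
    """Moment estimator of the sensitive prevalence with Wald interval.

    Parameters
    ----------
    counts : SurveyCounts
        Pooled yes/no counts under one design.
    level : float
        Confidence level of the Wald interval (default 0.95).

    Returns
    -------
    PrevalenceEstimate
        ``pi_hat`` may fall outside [0, 1] for unlucky samples; use
        ``pi_hat_truncated`` for display.
    """
    p = float(counts.design.p)
    pi_n = float(counts.design.pi_n)
    if p == 0:
        raise ValueError("invalid design: p must be positive")
    a = yes_proportion(counts)
    pi_hat = (a - (1 - p) * pi_n) / p
    se = math.sqrt(a * (1 - a) / (counts.n * p * p))
    z = norm.ppf(0.5 + level / 2)
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        ci_low=pi_hat - z * se,
        ci_high=pi_hat + z * se,
        level=level,
        a=a,
        n=counts.n,
    )


def percent(x: float, decimals: int = 1) -> float:
    """Proportion -> percentage, rounded half-away-from-zero.

    Matches the reporting convention of the published tables (one
    decimal, ties away from zero — ``round`` would round half to even).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x) * 100)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_se_percent(est: PrevalenceEstimate) -> float:
    """Standard error on the percent scale, one decimal."""
    return percent(est.se)


def estimate_table(counts_list: list[SurveyCounts], level: float = 0.95) -> list[dict]:
    """Per-item report records mirroring the published prevalence table.

    Each record carries the raw counts, the yes proportion, and the
    percent-scale estimate / SE / CI rounded to one decimal, alongside
    the full-precision proportions.
    """
    rows = []
    for counts in counts_list:
        est = estimate_prevalence(counts, level=level)
        rows.append(
            {
                "item": counts.item,
                "design_label": counts.design.label,
                "yes": counts.yes,
                "no": counts.no,
                "a": round(est.a, 3),
                "pi_hat_pct": percent(est.pi_hat),
                "se_pct": percent(est.se),
                "ci_pct": [percent(est.ci_low), percent(est.ci_high)],
                "pi_hat": est.pi_hat,
                "se": est.se,
                "ci": [est.ci_low, est.ci_high],
                "n": counts.n,
            }
        )
    return rows
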