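"""Randomization designs for the unrelated question model (UQM).

A UQM question directs each respondent, via a private chance mechanism,
either to the sensitive question (probability ``p``) or to an unrelated
neutral question whose population "yes" probability ``pi_n`` is known.
The randomizer implemented here is the day-of-month of a self-chosen
birthday: over an average 365.25-day year (February counted as 28.25
days), the fraction of birthdays whose day-of-month falls in a given
range is an exact rational number with denominator 365.25.  Designs
constructed from the birthday randomizer therefore carry exact
:class:`fractions.Fraction` parameters, so that serialization
round-trips lose no precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Union

Probability = Union[float, Fraction]

#: Days per month of an average (Julian) year; February = 113/4 = 28.25
#: because day 29 exists in one year of every four.
_MONTH_LENGTHS: tuple[Fraction, ...] = (
    Fraction(31), Fraction(113, 4), Fraction(31), Fraction(30),
    Fraction(31), Fraction(30), Fraction(31), Fraction(31),
    Fraction(30), Fraction(31), Fraction(30), Fraction(31),
)

#: Average year length, 1461/4 = 365.25 days.
YEAR_DAYS: Fraction = Fraction(1461, 4)

#: Days from 1 January to 30 June inclusive: 181.25 of 365.25, the "yes"
#: probability of the neutral question "is this birthday before 1 July?".
NEUTRAL_YES_DAYS: Fraction = sum(_MONTH_LENGTHS[:6], Fraction(0))


@dataclass(frozen=True)
class UQMDesign:
    """Parameters of one unrelated-question-model question.

    Parameters
    ----------
    p : float or Fraction
        Probability of being directed to the sensitive question, in (0, 1].
    pi_n : float or Fraction
        Probability that the neutral question is answered "yes", in (0, 1).
    label : str
        Free-text identifier, e.g. ``"p≈1/3"``.
    """

    p: Probability
    pi_n: Probability
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"p must lie in (0, 1], got {self.p!r}")
        if not 0 < self.pi_n < 1:
            raise ValueError(f"pi_n must lie in (0, 1), got {self.pi_n!r}")

    # -- serialization ---------------------------------------------------
    def to_config(self) -> dict:
        """Plain-mapping form, with parameters expressed as day counts."""
        return {
            "label": self.label,
            "numerator_days_sensitive": float(Fraction(self.p) * YEAR_DAYS),
            "numerator_days_neutral_yes": float(Fraction(self.pi_n) * YEAR_DAYS),
            "denominator_days": float(YEAR_DAYS),
        }

    @classmethod
    def from_config(cls, config: Mapping) -> "UQMDesign":
        denom = Fraction(str(config.get("denominator_days", "365.25")))
        return cls(
            p=Fraction(str(config["numerator_days_sensitive"])) / denom,
            pi_n=Fraction(str(config["numerator_days_neutral_yes"])) / denom,
            label=str(config.get("label", "")),
        )


def day_fraction(first_day: int, last_day: int) -> Fraction:
    """Probability that a uniform birthday's day-of-month is in a range.

    Counts the qualifying day slots of each month over an average year
    (February contributing 28.25 days) and divides by 365.25.

    Parameters
    ----------
    first_day, last_day : int
        Inclusive day-of-month bounds, ``1 <= first_day <= last_day <= 31``.

    Returns
    -------
    Fraction
        Exact probability with denominator dividing 1461.
    """
    if not (isinstance(first_day, int) and isinstance(last_day, int)):
        raise TypeError("day bounds must be integers")
    if not 1 <= first_day <= last_day <= 31:
        raise ValueError(
            f"require 1 <= first_day <= last_day <= 31, got ({first_day}, {last_day})"
        )
    days = Fraction(0)
    for length in _MONTH_LENGTHS:
        # e.g. range (21, 31) in February: min(31, 28.25) - 21 + 1 = 8.25
        days += max(Fraction(0), min(Fraction(last_day), length) - first_day + 1)
    return days / YEAR_DAYS


#: Day-of-month on which the sensitive branch starts, per variant: the
#: questionnaire sends days 1..20 ("one_third") or 1..10 ("two_thirds")
#: to the neutral question and the rest of the month to the sensitive one.
SENSITIVE_FIRST_DAY: dict[str, int] = {"one_third": 21, "two_thirds": 11}


def birthday_design(variant: str) -> UQMDesign:
    """The study's birthday-randomizer design for one *p* variant.

    ``"one_third"`` gives p = 125.25/365.25 (≈ 0.343, birthday day 21-31);
    ``"two_thirds"`` gives p = 245.25/365.25 (≈ 0.671, day 11-31).  Both
    share pi_n = 181.25/365.25 (birthday before 1 July).
    """
    try:
        start = SENSITIVE_FIRST_DAY[variant]
    except KeyError:
        raise ValueError(
            f"unknown design variant {variant!r}; expected one of "
            f"{sorted(SENSITIVE_FIRST_DAY)}"
        ) from None
    return UQMDesign(
        p=day_fraction(start, 31),
        pi_n=NEUTRAL_YES_DAYS / YEAR_DAYS,
        label="p≈1/3" if variant == "one_third" else "p≈2/3",
    )


def disclosure_risk(design: UQMDesign, pi_s: float) -> float:
    """Posterior probability of carrying the sensitive attribute given "yes".

    Under fully honest responding, Bayes' rule gives

        P(carrier | yes) = pi_s * (p + (1-p) * pi_n)
                           / (p * pi_s + (1-p) * pi_n)

    which increases with *p*: the more likely the randomizer points at the
    sensitive question, the more a "yes" reveals.  At p = 1 it equals 1,
    and as p -> 0 it approaches the prior pi_s.
    """
    if not 0 <= pi_s <= 1:
        raise ValueError(f"pi_s must lie in [0, 1], got {pi_s!r}")
    p, pi_n = float(design.p), float(design.pi_n)
    denom = p * pi_s + (1 - p) * pi_n
    if denom == 0.0:
        return 0.0  # only reachable with pi_s == 0 and p == 1
    return pi_s * (p + (1 - p) * pi_n) / denom
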