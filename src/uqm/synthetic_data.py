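"""Respondent-level simulator of the UQM doping survey.

The generator emulates the study's questionnaire mechanics end to end:
eight counterbalanced versions crossing item order (physical or
cognitive doping first) with the randomization probability of each
question (p ≈ 1/3 or p ≈ 2/3); a private birthday randomizer in which
the day-of-month routes the respondent to the sensitive or the neutral
question and the month answers the neutral question ("is this birthday
before 1 July?"); optional self-protective cheating by carriers on the
sensitive branch; and item nonresponse (answering neither question, or
only the first).

Birthdays are drawn uniformly from a 1461-day four-year calendar cycle
(three 365-day years plus one leap year), which reproduces the design
constants p = 125.25/365.25, 245.25/365.25 and pi_n = 181.25/365.25
exactly in expectation, with no fractional-day approximations.

Each question draws its own independent birthday — the questionnaire
invites respondents to "consider a certain birthday" anew per question;
``share_birthday=True`` reuses one draw for both questions as a
sensitivity analysis.

One calendar subtlety matters.  In the printed questionnaire a single
birthday determines both the branch (its day-of-month) and the neutral
answer (its month).  Because every month has at least 20 days, the
month is *not* independent of the day-of-month: conditional on being
routed to the neutral question (day 1-10 or 1-20), the probability of
"first half of the year" is exactly 6/12 = 1/2, not the marginal
181.25/365.25 that the estimator uses as pi_n.  A simulator that wires
both through one birthday therefore biases recovered prevalences
upward by (1-p)/p * (1/2 - 181.25/365.25).  By default the generator
draws the neutral answer from an independent uniform birthday, so the
neutral "yes" probability conditional on the branch is exactly the
design constant; ``neutral_same_birthday=True`` reproduces the literal
single-birthday questionnaire and lets users quantify that bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .design import SENSITIVE_FIRST_DAY, birthday_design
from .estimation import SurveyCounts

# ---------------------------------------------------------------------------
# questionnaire versions (item order x randomization probabilities)


@dataclass(frozen=True)
class QuestionnaireVersion:
    version_id: int
    first_item: str  # "physical" or "cognitive"
    p_first: str  # design variant of the first question
    second_item: str
    p_second: str


#: The eight counterbalanced versions: version 1 asks cognitive doping
#: first at p≈2/3 then physical at p≈1/3, and so on.
VERSIONS: dict[int, QuestionnaireVersion] = {
    1: QuestionnaireVersion(1, "cognitive", "two_thirds", "physical", "one_third"),
    2: QuestionnaireVersion(2, "cognitive", "one_third", "physical", "one_third"),
    3: QuestionnaireVersion(3, "cognitive", "two_thirds", "physical", "two_thirds"),
    4: QuestionnaireVersion(4, "cognitive", "one_third", "physical", "two_thirds"),
    5: QuestionnaireVersion(5, "physical", "two_thirds", "cognitive", "one_third"),
    6: QuestionnaireVersion(6, "physical", "one_third", "cognitive", "one_third"),
    7: QuestionnaireVersion(7, "physical", "two_thirds", "cognitive", "two_thirds"),
    8: QuestionnaireVersion(8, "physical", "one_third", "cognitive", "two_thirds"),
}


# ---------------------------------------------------------------------------
# four-year calendar cycle

_DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _build_cycle() -> tuple[np.ndarray, np.ndarray]:
    """Month (1-12) and day-of-month (1-31) for each of 1461 cycle days."""
    months, days = [], []
    for year in range(4):
        lengths = _DAYS_PER_MONTH.copy()
        if year == 3:  # one leap year per cycle
            lengths[1] = 29
        for m, length in enumerate(lengths, start=1):
            months.extend([m] * length)
            days.extend(range(1, length + 1))
    return np.array(months, dtype=np.int16), np.array(days, dtype=np.int16)


_CYCLE_MONTH, _CYCLE_DAY = _build_cycle()
CYCLE_DAYS = len(_CYCLE_MONTH)  # 1461


# ---------------------------------------------------------------------------
# configuration


def _default_weights() -> tuple[float, ...]:
    total = sum(datasets.VERSION_COUNTS)
    return tuple(c / total for c in datasets.VERSION_COUNTS)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated survey.

    Defaults reproduce the published study: n = 1,206 returned
    questionnaires, version weights at the observed version
    distribution, true prevalences at the study's combined estimates
    (14.4% physical, 18.8% cognitive), honest responding, and item
    nonresponse at the observed rates (33/1206 answered neither
    question, 9/1206 only the first).
    """

    n_respondents: int = datasets.N_RETURNED
    pi_physical: float = 0.144
    pi_cognitive: float = 0.188
    cheating_prob_by_design: dict = field(
        default_factory=lambda: {"one_third": 0.0, "two_thirds": 0.0}
    )
    nonresponse_none: float = datasets.N_NO_ANSWER / datasets.N_RETURNED
    nonresponse_second_only: float = datasets.N_FIRST_ONLY / datasets.N_RETURNED
    version_weights: tuple[float, ...] = field(default_factory=_default_weights)
    share_birthday: bool = False
    neutral_same_birthday: bool = False
    include_truth: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = [
            self.pi_physical, self.pi_cognitive,
            self.nonresponse_none, self.nonresponse_second_only,
            *self.cheating_prob_by_design.values(), *self.version_weights,
        ]
        if any(not 0 <= q <= 1 for q in probs):
            raise ValueError("invalid config: all probabilities must lie in [0, 1]")
        if abs(sum(self.version_weights) - 1.0) > 1e-9 or len(self.version_weights) != 8:
            raise ValueError("invalid config: version_weights must be 8 values summing to 1")
        if self.n_respondents < 1:
            raise ValueError("invalid config: n_respondents must be positive")


# ---------------------------------------------------------------------------
# simulation


def _simulate_question(
    rng: np.random.Generator,
    item_is_physical: np.ndarray,
    variant_is_two_thirds: np.ndarray,
    carrier_physical: np.ndarray,
    carrier_cognitive: np.ndarray,
    cheat_prob: dict,
    day_index: np.ndarray,
    neutral_day_index: np.ndarray,
) -> np.ndarray:
    """Boolean "yes" answers for one question position (vectorized)."""
    day = _CYCLE_DAY[day_index]
    month = _CYCLE_MONTH[neutral_day_index]
    first_sens_day = np.where(
        variant_is_two_thirds,
        SENSITIVE_FIRST_DAY["two_thirds"],
        SENSITIVE_FIRST_DAY["one_third"],
    )
    sensitive_branch = day >= first_sens_day
    neutral_yes = month <= 6

    carrier = np.where(item_is_physical, carrier_physical, carrier_cognitive)
    cheat_p = np.where(
        variant_is_two_thirds, cheat_prob["two_thirds"], cheat_prob["one_third"]
    )
    cheats = rng.random(len(day)) < cheat_p
    sensitive_yes = carrier & ~cheats
    return np.where(sensitive_branch, sensitive_yes, neutral_yes)


def simulate_survey(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one survey; returns one row per respondent.

    Columns: ``id, version, answer_first, answer_second, gender, age,
    semester, field`` with answers in {"yes", "no", ""} ("" = item
    nonresponse).  With ``config.include_truth`` the latent truth
    statuses, day indices and branch indicators are appended (columns
    that would not exist in real data).  Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    version = rng.choice(np.arange(1, 9), size=n, p=np.asarray(config.version_weights))
    first_item_physical = np.isin(version, (5, 6, 7, 8))
    p_first_two_thirds = np.isin(version, (1, 3, 5, 7))
    p_second_two_thirds = np.isin(version, (3, 4, 7, 8))

    carrier_physical = rng.random(n) < config.pi_physical
    carrier_cognitive = rng.random(n) < config.pi_cognitive

    day_first = rng.integers(0, CYCLE_DAYS, size=n)
    day_second = day_first if config.share_birthday else rng.integers(0, CYCLE_DAYS, size=n)
    if config.neutral_same_birthday:
        neutral_first, neutral_second = day_first, day_second
    else:
        neutral_first = rng.integers(0, CYCLE_DAYS, size=n)
        neutral_second = rng.integers(0, CYCLE_DAYS, size=n)

    yes_first = _simulate_question(
        rng, first_item_physical, p_first_two_thirds,
        carrier_physical, carrier_cognitive,
        config.cheating_prob_by_design, day_first, neutral_first,
    )
    yes_second = _simulate_question(
        rng, ~first_item_physical, p_second_two_thirds,
        carrier_physical, carrier_cognitive,
        config.cheating_prob_by_design, day_second, neutral_second,
    )

    u = rng.random(n)
    answered_none = u < config.nonresponse_none
    answered_first_only = ~answered_none & (
        u < config.nonresponse_none + config.nonresponse_second_only
    )

    answer_first = np.where(yes_first, "yes", "no")
    answer_second = np.where(yes_second, "yes", "no")
    answer_first = np.where(answered_none, "", answer_first)
    answer_second = np.where(answered_none | answered_first_only, "", answer_second)

    gender_p = datasets.GENDER_COUNTS["female"] / sum(datasets.GENDER_COUNTS.values())
    age = np.clip(
        np.rint(rng.normal(datasets.AGE_MEAN, datasets.AGE_SD, size=n)),
        *datasets.AGE_RANGE,
    ).astype(int)
    semester = np.clip(
        np.rint(rng.normal(datasets.SEMESTER_MEAN, datasets.SEMESTER_SD, size=n)),
        *datasets.SEMESTER_RANGE,
    ).astype(int)
    fields = list(datasets.FIELD_COUNTS)
    field_w = np.array(list(datasets.FIELD_COUNTS.values()), dtype=float)
    field_w /= field_w.sum()

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "version": version,
            "answer_first": answer_first,
            "answer_second": answer_second,
            "gender": np.where(rng.random(n) < gender_p, "female", "male"),
            "age": age,
            "semester": semester,
            "field": rng.choice(fields, size=n, p=field_w),
        }
    )
    if config.include_truth:
        table["is_user_physical"] = carrier_physical
        table["is_user_cognitive"] = carrier_cognitive
        table["birthday_day_index_first"] = day_first + 1
        table["birthday_day_index_second"] = day_second + 1
    return table


def aggregate_counts(table: pd.DataFrame) -> list[SurveyCounts]:
    """Pool answers by item and design variant into four count pairs.

    Question order and version are collapsed; missing answers ("" or
    NaN) are excluded, so each item's total equals the number of
    respondents who answered that item.
    """
    if len(table) == 0:
        raise ValueError("empty respondent table")
    version = table["version"].to_numpy()
    tallies: dict[tuple[str, str], list[int]] = {
        (item, variant): [0, 0]
        for item in ("physical", "cognitive")
        for variant in ("one_third", "two_thirds")
    }
    for position, answers in (
        ("first", table["answer_first"]), ("second", table["answer_second"])
    ):
        ans = answers.fillna("").astype(str).str.strip().str.lower().to_numpy()
        for v, spec in VERSIONS.items():
            item = spec.first_item if position == "first" else spec.second_item
            variant = spec.p_first if position == "first" else spec.p_second
            mask = version == v
            tallies[(item, variant)][0] += int(np.sum(mask & (ans == "yes")))
            tallies[(item, variant)][1] += int(np.sum(mask & (ans == "no")))
    return [
        SurveyCounts(item=item, design=birthday_design(variant), yes=yes, no=no)
        for (item, variant), (yes, no) in tallies.items()
    ]


FIXTURE_SEED = 20180515


def fixture_study() -> tuple[pd.DataFrame, SimulationConfig]:
    """A canned seed-fixed synthetic study mirroring the published one.

    n = 1,206 respondents, version weights at the observed version
    distribution, honest responding, true prevalences at the study's
    combined estimates, observed nonresponse rates.  Reruns are
    byte-identical; intended for documentation and integration tests.
    """
    config = SimulationConfig(seed=FIXTURE_SEED)
    return simulate_survey(config), config
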