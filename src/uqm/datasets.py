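"""Published constants of the university-student doping survey.

The study distributed eight counterbalanced questionnaire versions of
two UQM questions (12-month physical and cognitive doping) to 1,206
responding students, with birthday-randomizer designs p ≈ 1/3 and
p ≈ 2/3.  The aggregated yes/no counts per item and design, the
version distribution, and the demographic margins printed in the
article are collected here as package data: they are the inputs the
analyses in this package reproduce and the populations the synthetic
generator emulates.
"""

from __future__ import annotations

from .design import birthday_design
from .estimation import SurveyCounts

#: Aggregated yes/no counts per item x randomization design.
_COUNTS = {
    ("physical", "one_third"): (233, 345),
    ("physical", "two_thirds"): (147, 444),
    ("cognitive", "one_third"): (238, 352),
    ("cognitive", "two_thirds"): (164, 414),
}


def doping_study_counts() -> list[SurveyCounts]:
    """The four observed (item, design) yes/no count pairs."""
    out = []
    for (item, variant), (yes, no) in _COUNTS.items():
        out.append(SurveyCounts(item=item, design=birthday_design(variant), yes=yes, no=no))
    return out


def study_condition(item: str, variant: str) -> SurveyCounts:
    """Counts for one item ("physical"/"cognitive") and design variant."""
    yes, no = _COUNTS[(item, variant)]
    return SurveyCounts(item=item, design=birthday_design(variant), yes=yes, no=no)


#: Returned questionnaires per version (versions 1..8).
VERSION_COUNTS: tuple[int, ...] = (154, 149, 159, 153, 151, 150, 153, 137)

#: Total returned questionnaires.
N_RETURNED: int = 1206

#: Respondents answering neither UQM question, and first question only.
N_NO_ANSWER: int = 33
N_FIRST_ONLY: int = 9

#: Demographic margins (counts among those reporting).
GENDER_COUNTS = {"female": 675, "male": 491}
AGE_MEAN, AGE_SD, AGE_RANGE = 21.9, 3.1, (16, 64)
SEMESTER_MEAN, SEMESTER_SD, SEMESTER_RANGE = 3.3, 2.2, (1, 20)
FIELD_COUNTS = {
    "economics_law": 376,
    "medicine_psychology_natural_sciences": 242,
    "languages_education": 235,
    "culture_sciences": 224,
    "sports_science": 81,
}
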