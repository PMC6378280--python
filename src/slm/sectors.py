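"""Affective-area profiling: five-sector development scores and recommendation
sector selection.

Each of the five sectors (affective-relational, productivity, sociocultural,
organic, spiritual) receives a development score on [0, 100]: 100 means no
inadequacy in any answer of that sector, 0 means maximal inadequacy in all.
One recommendation always targets the affective-relational sector (the
relationship precedes the individual); a complementary recommendation
targets the most recessive — least developed — of the remaining four, with
ties broken by Maslow's hierarchy of needs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .bank import AnswerSheet, QuestionBank, SECTORS, score_answer


class AgeBand(enum.Enum):
    """The six chronological age ranges used throughout the assessment."""

    B0_7 = (0, 7)
    B8_12 = (8, 12)
    B13_19 = (13, 19)
    B20_24 = (20, 24)
    B25_32 = (25, 32)
    B33_PLUS = (33, None)

    @property
    def lower(self) -> int:
        return self.value[0]

    @property
    def upper(self) -> int | None:
        return self.value[1]

    @property
    def label(self) -> str:
        return self.name.lower()


def map_age_band(age_years: int) -> AgeBand:
    """Map a chronological age to its unique band (last band open above)."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    for band in AgeBand:
        lo, hi = band.value
        if age_years >= lo and (hi is None or age_years <= hi):
            return band
    raise AssertionError("age bands partition the non-negative integers")


# Maslow priority, ascending: later entries are the more basic needs and win
# ties for the complementary recommendation.
MASLOW_ASCENDING = (
    "spiritual",
    "sociocultural",
    "affective_relational",
    "productivity",
    "organic",
)


@dataclass
class SectorProfile:
    development: dict[str, float]  # sector -> score in [0, 100]
    age_band: AgeBand
    recommended_sectors: tuple[str, str]


def select_recommendation_sectors(
    development: dict[str, float],
    priority: tuple[str, ...] = MASLOW_ASCENDING,
) -> tuple[str, str]:
    """Pick the two recommendation sectors.

    The first is always affective-relational.  The second is the most
    recessive (lowest development) of the other four sectors; when several
    tie at the minimum, the one with higher Maslow priority (closer to the
    basic-needs end of ``priority``) wins.
    """
    missing = set(SECTORS) - set(development)
    if missing:
        raise ValueError(f"development scores missing for sectors: {sorted(missing)}")
    candidates = [s for s in SECTORS if s != "affective_relational"]
    lowest = min(development[s] for s in candidates)
    tied = [s for s in candidates if development[s] == lowest]
    second = max(tied, key=priority.index)
    return ("affective_relational", second)


def score_sectors(bank: QuestionBank, answers: AnswerSheet) -> SectorProfile:
    """Score the five affective sectors from a complete affective group.

    development(s) = 100 * (1 - sum of inadequacy over s / max attainable).
    """
    answers.require_complete(bank, "affective")
    development: dict[str, float] = {}
    for sector in SECTORS:
        questions = bank.subscale("affective", sector)
        max_total = sum(q.max_score() for q in questions)
        if max_total <= 0:
            raise ValueError(
                f"sector {sector}: zero maximum attainable inadequacy "
                "(no questions or degenerate score maps)"
            )
        total = sum(score_answer(q, answers.likert_answers[q.id]) for q in questions)
        development[sector] = 100.0 * (1.0 - total / max_total)
    return SectorProfile(
        development=development,
        age_band=map_age_band(answers.age_years),
        recommended_sectors=select_recommendation_sectors(development),
    )


def sector_radar(profile: SectorProfile) -> pd.DataFrame:
    """One row per sector (sector, development) for radar-chart plotting."""
    return pd.DataFrame(
        {"sector": list(SECTORS), "development": [profile.development[s] for s in SECTORS]}
    )
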