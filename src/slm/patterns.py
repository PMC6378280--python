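"""Differentiation-of-self via fuzzy cognitive-interaction patterns.

Instead of a single deterministic 0-100 differentiation score, each
respondent receives three simultaneous degrees of pertinence in [0, 1] —
adaptation (accommodating to avoid pain), reaction (struggling to regain
wellbeing), creativity (generating new meanings and solutions).  The
degrees are compared against age-banded healthy intervals: a healthy
evaluation lies inside [inferior, superior]; the limits depend on the
respondent's chronological age band.

Degrees are computed by normalised-sum aggregation of the per-question
inadequacy scores, optionally passed through a per-pattern piecewise-linear
membership calibration curve (identity by default).  The three degrees are
deliberately NOT normalised across patterns: the patterns are evaluated
simultaneously, not exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bank import AnswerSheet, PATTERNS, QuestionBank, score_answer
from .sectors import AgeBand, map_age_band

Interval = tuple[float, float]

# Calibration curve: sequence of (x, y) knots on [0,1]x[0,1]; evaluated by
# linear interpolation. None means the identity.
Calibration = Sequence[tuple[float, float]] | None


@dataclass
class HealthyIntervalTable:
    """(pattern, age band) -> [inferior, superior] healthy interval."""

    cells: dict[tuple[str, AgeBand], Interval]

    def __post_init__(self) -> None:
        for pattern in PATTERNS:
            for band in AgeBand:
                if (pattern, band) not in self.cells:
                    raise ValueError(f"interval table missing cell ({pattern}, {band.label})")
        for key, (lo, hi) in self.cells.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"malformed interval {key}: [{lo}, {hi}]")

    def interval(self, pattern: str, band: AgeBand) -> Interval:
        return self.cells[(pattern, band)]


def default_interval_table() -> HealthyIntervalTable:
    """Placeholder clinical calibration, every cell overridable via config.

    Adaptation and reaction bands shift downward with age (symbiotic
    accommodation is healthy in a young child, not in an adult); the
    creativity band rises with age.  These are reference values for a table
    that in practice is calibrated by the clinic, not computed.
    """
    bands = list(AgeBand)
    adaptation = [(0.40, 0.90), (0.35, 0.80), (0.30, 0.70), (0.25, 0.65), (0.20, 0.60), (0.15, 0.55)]
    reaction = [(0.35, 0.85), (0.30, 0.75), (0.30, 0.70), (0.25, 0.65), (0.20, 0.60), (0.15, 0.55)]
    creativity = [(0.05, 0.50), (0.10, 0.55), (0.15, 0.60), (0.20, 0.65), (0.25, 0.70), (0.30, 0.75)]
    cells: dict[tuple[str, AgeBand], Interval] = {}
    for pattern, rows in (("adaptation", adaptation), ("reaction", reaction), ("creativity", creativity)):
        for band, interval in zip(bands, rows):
            cells[(pattern, band)] = interval
    return HealthyIntervalTable(cells)


def load_interval_table(path: str | Path) -> HealthyIntervalTable:
    """Load a YAML/JSON table: {pattern: {band_label: [inferior, superior]}}."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    cells: dict[tuple[str, AgeBand], Interval] = {}
    for pattern, rows in doc.items():
        for band_label, pair in rows.items():
            band = AgeBand[band_label.upper()]
            cells[(pattern, band)] = (float(pair[0]), float(pair[1]))
    return HealthyIntervalTable(cells)


def save_interval_table(table: HealthyIntervalTable, path: str | Path) -> None:
    doc: dict[str, dict[str, list[float]]] = {}
    for (pattern, band), (lo, hi) in table.cells.items():
        doc.setdefault(pattern, {})[band.label] = [lo, hi]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class PatternMembership:
    degrees: dict[str, float]  # pattern -> degree in [0, 1]
    age_band: AgeBand
    classifications: dict[str, str]  # pattern -> below | inside | above
    healthy_interval: dict[str, Interval] = field(default_factory=dict)


def apply_calibration(raw: float, calibration: Calibration) -> float:
    if calibration is None:
        return raw
    pts = sorted(calibration)
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    return float(np.clip(np.interp(raw, xs, ys), 0.0, 1.0))


def pattern_degree(
    bank: QuestionBank,
    answers: AnswerSheet,
    pattern: str,
    calibration: Calibration = None,
) -> float:
    """Fuzzy degree of pertinence to one cognitive-interaction pattern.

    Raw degree = sum of inadequacy over the pattern's questions divided by
    the maximum attainable sum, then passed through the calibration curve.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    questions = bank.subscale("differentiation", pattern)
    missing = [q.id for q in questions if q.id not in answers.likert_answers]
    if missing:
        from .bank import IncompleteGroupError

        raise IncompleteGroupError(f"differentiation/{pattern}", missing)
    max_total = sum(q.max_score() for q in questions)
    if max_total <= 0:
        raise ValueError(f"pattern {pattern}: zero maximum attainable inadequacy")
    total = sum(score_answer(q, answers.likert_answers[q.id]) for q in questions)
    return apply_calibration(total / max_total, calibration)


def classify_pattern(degree: float, interval: Interval) -> str:
    """below / inside / above relative to the healthy interval (closed ends)."""
    lo, hi = interval
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"malformed interval [{lo}, {hi}]")
    if degree < lo:
        return "below"
    if degree <= hi:
        return "inside"
    return "above"


def evaluate_differentiation(
    bank: QuestionBank,
    answers: AnswerSheet,
    table: HealthyIntervalTable | None = None,
    calibrations: Mapping[str, Calibration] | None = None,
) -> PatternMembership:
    """Compute all three pattern degrees and classify against age-banded limits."""
    table = table if table is not None else default_interval_table()
    calibrations = calibrations or {}
    band = map_age_band(answers.age_years)
    degrees: dict[str, float] = {}
    classifications: dict[str, str] = {}
    intervals: dict[str, Interval] = {}
    for pattern in PATTERNS:
        degree = pattern_degree(bank, answers, pattern, calibrations.get(pattern))
        interval = table.interval(pattern, band)
        degrees[pattern] = degree
        intervals[pattern] = interval
        classifications[pattern] = classify_pattern(degree, interval)
    return PatternMembership(
        degrees=degrees,
        age_band=band,
        classifications=classifications,
        healthy_interval=intervals,
    )


def legacy_bowen_score(membership: PatternMembership) -> float:
    """Convenience 0-100 differentiation score derived from the fuzzy degrees.

    score = 100 * (creativity + (1 - adaptation) + (1 - reaction)) / 3.
    This deterministic summary is NOT part of the fuzzy assessment proper;
    it is offered for continuity with the classical 0-100 differentiation
    scale (low = fused egos) and is flagged as a derived convenience.
    """
    d = membership.degrees
    score = 100.0 * (d["creativity"] + (1.0 - d["adaptation"]) + (1.0 - d["reaction"])) / 3.0
    return float(min(100.0, max(0.0, score)))


def pattern_radar(membership: PatternMembership) -> pd.DataFrame:
    """Rows (pattern, degree, inferior, superior) for radar-chart plotting."""
    rows = []
    for pattern in PATTERNS:
        lo, hi = membership.healthy_interval[pattern]
        rows.append(
            {
                "pattern": pattern,
                "degree": membership.degrees[pattern],
                "inferior": lo,
                "superior": hi,
            }
        )
    return pd.DataFrame(rows)
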