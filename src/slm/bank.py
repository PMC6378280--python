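"""Question-bank data model: the five-group Likert instrument and answer sheets.

The instrument is a bank of 140 questions organised into five assessment
groups (affective areas, genogram intake, differentiation-of-self patterns,
awareness/redefinition, intervention intake).  Likert questions offer five
exclusive options indexed 0..4; each (question, option) pair carries an
*inadequacy score* — a non-negative real expressing how inadequate that
answer is judged to be.  Genogram-group questions collect structured family
records instead of Likert indices.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

GROUPS = ("affective", "genogram", "differentiation", "awareness", "interveneer")

SECTORS = (
    "affective_relational",
    "productivity",
    "sociocultural",
    "organic",
    "spiritual",
)

PATTERNS = ("adaptation", "reaction", "creativity")

LIKERT_OPTIONS = (0, 1, 2, 3, 4)


class BankValidationError(ValueError):
    """Raised when a bank file or object violates the instrument schema."""


class IncompleteGroupError(ValueError):
    """Raised when an operation requires a fully answered question group."""

    def __init__(self, group: str, missing: Iterable[str]):
        self.group = group
        self.missing = sorted(missing)
        super().__init__(
            f"group '{group}' is incomplete; missing answers for: "
            + ", ".join(self.missing)
        )


def default_score_map(keying: str) -> dict[int, float]:
    """Identity inadequacy map on the 0-4 index, reversed for positive keying.

    Negative keying: agreeing more (higher index) is more inadequate, score = k.
    Positive keying: agreeing more is healthier, score = 4 - k.
    """
    if keying == "negative":
        return {k: float(k) for k in LIKERT_OPTIONS}
    if keying == "positive":
        return {k: float(4 - k) for k in LIKERT_OPTIONS}
    raise ValueError(f"unknown keying: {keying!r}")


@dataclass(frozen=True)
class Question:
    id: str
    group: str
    text: str
    subscale: str | None = None
    response_kind: str = "likert"
    keying: str = "negative"
    score_map: Mapping[int, float] | None = None

    def effective_score_map(self) -> Mapping[int, float]:
        if self.response_kind != "likert":
            raise ValueError(f"question {self.id} is not a Likert question")
        return self.score_map if self.score_map is not None else default_score_map(self.keying)

    def max_score(self) -> float:
        return max(self.effective_score_map().values())


@dataclass
class QuestionBank:
    questions: list[Question]
    version: str = "reference-0.1"
    advice_interval: int = 10

    def __post_init__(self) -> None:
        self._by_id = {q.id: q for q in self.questions}

    def __len__(self) -> int:
        return len(self.questions)

    def __getitem__(self, qid: str) -> Question:
        return self._by_id[qid]

    def __contains__(self, qid: str) -> bool:
        return qid in self._by_id

    def group(self, name: str) -> list[Question]:
        return [q for q in self.questions if q.group == name]

    def subscale(self, group: str, subscale: str) -> list[Question]:
        return [q for q in self.questions if q.group == group and q.subscale == subscale]


@dataclass
class AnswerSheet:
    respondent_id: str
    age_years: int
    likert_answers: dict[str, int] = field(default_factory=dict)
    structured_answers: dict[str, Any] = field(default_factory=dict)

    def missing(self, bank: QuestionBank, group: str) -> list[str]:
        out = []
        for q in bank.group(group):
            answered = (
                q.id in self.structured_answers
                if q.response_kind == "structured"
                else q.id in self.likert_answers
            )
            if not answered:
                out.append(q.id)
        return out

    def is_complete(self, bank: QuestionBank, group: str) -> bool:
        return not self.missing(bank, group)

    def require_complete(self, bank: QuestionBank, group: str) -> None:
        missing = self.missing(bank, group)
        if missing:
            raise IncompleteGroupError(group, missing)


@dataclass
class ValidationReport:
    findings: list[str]
    group_counts: dict[str, int]
    subscale_counts: dict[str, int]
    total: int

    @property
    def is_valid(self) -> bool:
        return not self.findings


# Reference structural expectations for the shipped instrument.
REFERENCE_GROUP_SIZES = {
    "affective": 29,
    "genogram": 12,
    "differentiation": 57,
    "awareness": 33,
    "interveneer": 9,
}
REFERENCE_PATTERN_SIZES = {"adaptation": 17, "reaction": 21, "creativity": 19}
REFERENCE_TOTAL = 140


def validate_bank(bank: QuestionBank, reference_sizes: bool = False) -> ValidationReport:
    """Check every instrument invariant; the report lists each violation.

    With ``reference_sizes=True`` the group/pattern counts are additionally
    checked against the shipped reference instrument (140 questions).
    """
    findings: list[str] = []
    seen: set[str] = set()
    group_counts = {g: 0 for g in GROUPS}
    subscale_counts: dict[str, int] = {}

    for q in bank.questions:
        if q.id in seen:
            findings.append(f"duplicate question id: {q.id}")
        seen.add(q.id)
        if q.group not in GROUPS:
            findings.append(f"question {q.id}: unknown group {q.group!r}")
            continue
        group_counts[q.group] += 1
        if q.subscale is not None:
            subscale_counts[q.subscale] = subscale_counts.get(q.subscale, 0) + 1

        if q.group == "genogram":
            if q.response_kind != "structured":
                findings.append(f"question {q.id}: genogram questions must be structured")
            if q.score_map is not None:
                findings.append(f"question {q.id}: structured question must not carry score_map")
            continue

        if q.response_kind != "likert":
            findings.append(f"question {q.id}: non-genogram questions must be likert")
            continue
        smap = q.score_map if q.score_map is not None else default_score_map(q.keying)
        if set(smap) != set(LIKERT_OPTIONS):
            findings.append(
                f"question {q.id}: score_map must cover options 0..4, got {sorted(smap)}"
            )
        elif any(v < 0 for v in smap.values()):
            findings.append(f"question {q.id}: negative inadequacy score")
        if q.group == "affective" and q.subscale not in SECTORS:
            findings.append(f"question {q.id}: affective question needs a sector subscale")
        if q.group == "differentiation" and q.subscale not in PATTERNS:
            findings.append(f"question {q.id}: differentiation question needs a pattern subscale")

    if bank.advice_interval < 1:
        findings.append(f"advice_interval must be >= 1, got {bank.advice_interval}")

    if reference_sizes:
        for g, n in REFERENCE_GROUP_SIZES.items():
            if group_counts[g] != n:
                findings.append(f"group {g}: expected {n} questions, found {group_counts[g]}")
        for p, n in REFERENCE_PATTERN_SIZES.items():
            if subscale_counts.get(p, 0) != n:
                findings.append(
                    f"pattern {p}: expected {n} questions, found {subscale_counts.get(p, 0)}"
                )
        if len(bank.questions) != REFERENCE_TOTAL:
            findings.append(f"expected {REFERENCE_TOTAL} questions, found {len(bank.questions)}")

    return ValidationReport(
        findings=findings,
        group_counts=group_counts,
        subscale_counts=subscale_counts,
        total=len(bank.questions),
    )


def score_answer(question: Question, option: int) -> float:
    """Inadequacy score of one Likert answer.

    With the default map, negative keying gives score = option and positive
    keying gives score = 4 - option; banks may override per question.
    """
    if question.response_kind != "likert":
        raise ValueError(f"question {question.id} does not take Likert answers")
    if option not in LIKERT_OPTIONS:
        raise ValueError(f"option {option} out of range 0..4 for question {question.id}")
    return float(question.effective_score_map()[option])


def is_advice_checkpoint(progress: int, interval: int) -> bool:
    """True when the respondent has just earned a gamified advice reward.

    A checkpoint fires each time `interval` further questions have been
    answered (progress 10, 20, ... at the default interval of 10).
    """
    if interval < 1:
        raise ValueError(f"interval must be >= 1, got {interval}")
    if progress < 0:
        raise ValueError(f"progress must be >= 0, got {progress}")
    return progress > 0 and progress % interval == 0


# ---------------------------------------------------------------------------
# serialisation

def bank_to_dict(bank: QuestionBank) -> dict[str, Any]:
    return {
        "version": bank.version,
        "advice_interval": bank.advice_interval,
        "questions": [
            {
                "id": q.id,
                "group": q.group,
                "subscale": q.subscale,
                "text": q.text,
                "response_kind": q.response_kind,
                "keying": q.keying,
                "score_map": (
                    None if q.score_map is None else {int(k): float(v) for k, v in q.score_map.items()}
                ),
            }
            for q in bank.questions
        ],
    }


def bank_from_dict(doc: Mapping[str, Any]) -> QuestionBank:
    try:
        questions = []
        for item in doc["questions"]:
            smap = item.get("score_map")
            if smap is not None:
                smap = {int(k): float(v) for k, v in smap.items()}
            questions.append(
                Question(
                    id=str(item["id"]),
                    group=str(item["group"]),
                    subscale=item.get("subscale"),
                    text=str(item.get("text", "")),
                    response_kind=str(item.get("response_kind", "likert")),
                    keying=str(item.get("keying", "negative")),
                    score_map=smap,
                )
            )
        bank = QuestionBank(
            questions=questions,
            version=str(doc.get("version", "unversioned")),
            advice_interval=int(doc.get("advice_interval", 10)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise BankValidationError(f"malformed bank document: {exc}") from exc
    report = validate_bank(bank)
    if not report.is_valid:
        raise BankValidationError("invalid bank: " + "; ".join(report.findings))
    return bank


def load_bank(path: str | Path) -> QuestionBank:
    """Load and validate a YAML or JSON question-bank file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise BankValidationError(f"{path}: bank file must be a mapping")
    return bank_from_dict(doc)


def save_bank(bank: QuestionBank, path: str | Path) -> None:
    path = Path(path)
    doc = bank_to_dict(bank)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def answers_to_dict(sheet: AnswerSheet) -> dict[str, Any]:
    return {
        "respondent_id": sheet.respondent_id,
        "age_years": sheet.age_years,
        "likert_answers": dict(sheet.likert_answers),
        "structured_answers": dict(sheet.structured_answers),
    }


def answers_from_dict(doc: Mapping[str, Any]) -> AnswerSheet:
    return AnswerSheet(
        respondent_id=str(doc["respondent_id"]),
        age_years=int(doc["age_years"]),
        likert_answers={str(k): int(v) for k, v in dict(doc.get("likert_answers", {})).items()},
        structured_answers=dict(doc.get("structured_answers", {})),
    )


def load_answers(path: str | Path) -> AnswerSheet:
    """Load an answer sheet from a single JSON/YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return answers_from_dict(doc)


def save_answers(sheet: AnswerSheet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(answers_to_dict(sheet), fh, indent=2, sort_keys=True)


def load_answers_csv(csv_path: str | Path, sidecar_path: str | Path) -> AnswerSheet:
    """Load Likert answers from CSV (columns question_id, option) plus a JSON
    sidecar carrying respondent_id, age_years and structured genogram answers."""
    with open(sidecar_path, "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    likert: dict[str, int] = {}
    with open(csv_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            likert[str(row["question_id"])] = int(row["option"])
    return AnswerSheet(
        respondent_id=str(sidecar["respondent_id"]),
        age_years=int(sidecar["age_years"]),
        likert_answers=likert,
        structured_answers=dict(sidecar.get("structured_answers", {})),
    )
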