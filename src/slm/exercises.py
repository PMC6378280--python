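"""Intervention-exercise assignment: the customized homework of the final stage.

Each of the nine assessed items (affective area, the three
cognitive-interaction patterns, relationship, differentiation of self,
autonomy, assertiveness, self-esteem) has one corresponding exercise in the
catalog.  An exercise is assigned exactly when the inference closure
contains a relevance fact for its item, so every assignment is auditable
back to a derived fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .inference import Fact

CATALOG_ITEMS = (
    "affective_area",
    "pattern_adaptation",
    "pattern_reaction",
    "pattern_creativity",
    "relationship",
    "differentiation_of_self",
    "autonomy",
    "assertiveness",
    "self_esteem",
)


class CatalogError(ValueError):
    """Raised when the exercise catalog does not cover every assessed item."""


@dataclass(frozen=True)
class ExerciseCatalogEntry:
    item: str
    exercise_id: str
    description: str


@dataclass
class ExerciseCatalog:
    entries: dict[str, ExerciseCatalogEntry]

    def __post_init__(self) -> None:
        missing = [item for item in CATALOG_ITEMS if item not in self.entries]
        if missing:
            raise CatalogError(f"catalog missing entries for items: {missing}")

    def entry(self, item: str) -> ExerciseCatalogEntry:
        return self.entries[item]


def default_catalog() -> ExerciseCatalog:
    """Reference catalog with placeholder exercise descriptions (one per item)."""
    descriptions = {
        "affective_area": "Daily practice strengthening the least developed affective area.",
        "pattern_adaptation": "Notice one accommodation made to avoid discomfort; try the alternative.",
        "pattern_reaction": "Log each struggle response and rehearse a non-reactive reply.",
        "pattern_creativity": "Generate three alternative meanings for one difficult situation.",
        "relationship": "Schedule one genuine exchange with a significant other and reflect on it.",
        "differentiation_of_self": "Identify one opinion held only to please others; state your own.",
        "autonomy": "Complete one everyday task without seeking anyone's approval.",
        "assertiveness": "Say no once this week where you would usually comply.",
        "self_esteem": "Write down one personal accomplishment each evening.",
    }
    return ExerciseCatalog(
        entries={
            item: ExerciseCatalogEntry(
                item=item, exercise_id=f"ex_{item}", description=descriptions[item]
            )
            for item in CATALOG_ITEMS
        }
    )


@dataclass
class ExercisePlan:
    respondent_id: str
    # ordered (item, exercise_id, rationale fact) triples
    assigned: list[tuple[str, str, Fact]] = field(default_factory=list)

    def items(self) -> list[str]:
        return [item for item, _, _ in self.assigned]


def assign_exercises(
    closure: Iterable[Fact],
    catalog: ExerciseCatalog,
    respondent_id: str = "",
) -> ExercisePlan:
    """Assign one exercise per item whose relevance fact is in the closure.

    Order follows the catalog item order; each assignment carries the
    ``exercise_relevant(<item>)`` fact that justifies it.
    """
    closure_set = set(closure)
    plan = ExercisePlan(respondent_id=respondent_id)
    for item in CATALOG_ITEMS:
        fact = Fact("exercise_relevant", (item,))
        if fact in closure_set:
            entry = catalog.entry(item)
            plan.assigned.append((item, entry.exercise_id, fact))
    return plan


def catalog_to_dict(catalog: ExerciseCatalog) -> dict[str, Any]:
    return {
        "entries": [
            {
                "item": e.item,
                "exercise_id": e.exercise_id,
                "description": e.description,
            }
            for e in (catalog.entries[item] for item in CATALOG_ITEMS)
        ]
    }


def catalog_from_dict(doc: Mapping[str, Any]) -> ExerciseCatalog:
    return ExerciseCatalog(
        entries={
            str(rec["item"]): ExerciseCatalogEntry(
                item=str(rec["item"]),
                exercise_id=str(rec["exercise_id"]),
                description=str(rec.get("description", "")),
            )
            for rec in doc["entries"]
        }
    )


def load_catalog(path: str | Path) -> ExerciseCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        return catalog_from_dict(yaml.safe_load(fh))


def save_catalog(catalog: ExerciseCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(catalog_to_dict(catalog), fh, sort_keys=False)
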