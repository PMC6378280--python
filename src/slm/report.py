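"""Pipeline orchestration: run the full assessment and assemble the report.

The three method stages map onto five question groups executed in order
(affective -> genogram -> differentiation -> awareness -> interveneer).
Each incomplete group is marked pending rather than fatal.  Crisp facts
from the completed stages are pooled, closed once under the knowledge base,
rendered into advice, and turned into the exercise plan.  The report is a
plain JSON-serialisable structure: identical inputs and versions yield a
byte-identical document, and every recommendation carries the closure fact
it came from.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

from .bank import AnswerSheet, QuestionBank, is_advice_checkpoint
from .exercises import ExerciseCatalog, assign_exercises, default_catalog
from .genogram import build_genogram, genogram_to_dot, genogram_to_json_dict
from .inference import Fact, KnowledgeBase, classify_maturity, derive_recommendations, forward_chain
from .kb import default_knowledge_base
from .patterns import (
    HealthyIntervalTable,
    default_interval_table,
    evaluate_differentiation,
    legacy_bowen_score,
    pattern_radar,
)
from .sectors import score_sectors, sector_radar

logger = logging.getLogger("slm")

DISCLAIMER = (
    "This report is decision support for a qualified professional. The method "
    "is not curative; it assists patient and psychologist and does not replace "
    "therapy sessions or clinical judgment."
)

ADVICE_STREAM_TEXTS = (
    "Well done — keep going. Answer as honestly as you can; there are no wrong answers.",
    "Notice which questions were hardest to answer: they often point to what matters most.",
    "Take a short breath before continuing; accuracy matters more than speed.",
    "You are building a picture that will help your therapist help you.",
)


@dataclass
class AssessmentConfig:
    """Tunable clinical calibration, hashed into the report provenance."""

    interval_table: HealthyIntervalTable = field(default_factory=default_interval_table)
    maturity_thresholds: dict[str, float] = field(default_factory=dict)
    awareness_partition: dict[str, list[str]] | None = None
    calibrations: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def canonical_dict(self) -> dict[str, Any]:
        return {
            "interval_table": {
                f"{pattern}:{band.label}": list(interval)
                for (pattern, band), interval in sorted(
                    self.interval_table.cells.items(), key=lambda kv: (kv[0][0], kv[0][1].name)
                )
            },
            "maturity_thresholds": dict(sorted(self.maturity_thresholds.items())),
            "awareness_partition": self.awareness_partition,
            "calibrations": {k: [list(p) for p in v] for k, v in sorted(self.calibrations.items())},
        }

    def hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def collect_facts(
    bank: QuestionBank,
    answers: AnswerSheet,
    stages: Mapping[str, Any],
) -> set[Fact]:
    """Pool the crisp facts produced by every completed stage."""
    facts: set[Fact] = set()
    for group in ("affective", "genogram", "differentiation", "awareness", "interveneer"):
        if answers.is_complete(bank, group):
            facts.add(Fact("stage_complete", (group,)))
    facts.add(Fact("age_band", (stages["age_band"],)))
    profile = stages.get("sector_profile")
    if profile is not None:
        facts.add(Fact("recessive_sector", (profile.recommended_sectors[1],)))
    membership = stages.get("pattern_membership")
    if membership is not None:
        for pattern, classification in membership.classifications.items():
            facts.add(Fact(f"pattern_{classification}", (pattern,)))
    deficits = stages.get("deficits")
    if deficits is not None:
        facts |= deficits
    return facts


def advice_stream(bank: QuestionBank, answers: AnswerSheet) -> list[dict[str, Any]]:
    """The gamified advice checkpoints earned while answering.

    In this batch implementation the stream is emitted as an ordered report
    section: one short advice per `advice_interval` answered questions.
    """
    answered = len(answers.likert_answers) + len(answers.structured_answers)
    stream = []
    for progress in range(1, answered + 1):
        if is_advice_checkpoint(progress, bank.advice_interval):
            idx = (progress // bank.advice_interval - 1) % len(ADVICE_STREAM_TEXTS)
            stream.append({"after_answers": progress, "text": ADVICE_STREAM_TEXTS[idx]})
    return stream


def run_assessment(
    bank: QuestionBank,
    answers: AnswerSheet,
    kb: KnowledgeBase | None = None,
    config: AssessmentConfig | None = None,
    catalog: ExerciseCatalog | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the full pipeline and return the therapist report as a dict.

    Stages degrade gracefully: any incomplete question group is reported as
    pending and contributes no facts; the affective group is the only one
    most deployments treat as mandatory, but even it may be pending.
    """
    kb = kb if kb is not None else default_knowledge_base()
    config = config if config is not None else AssessmentConfig()
    catalog = catalog if catalog is not None else default_catalog()

    from .sectors import map_age_band

    stages: dict[str, Any] = {"age_band": map_age_band(answers.age_years).label}
    pending: list[str] = []
    report: dict[str, Any] = {
        "respondent": {"id": answers.respondent_id, "age_years": answers.age_years,
                       "age_band": stages["age_band"]},
        "disclaimer": DISCLAIMER,
    }

    if answers.is_complete(bank, "affective"):
        profile = score_sectors(bank, answers)
        stages["sector_profile"] = profile
        report["affective"] = {
            "development": {s: profile.development[s] for s in sorted(profile.development)},
            "recommended_sectors": list(profile.recommended_sectors),
            "radar": sector_radar(profile).to_dict(orient="records"),
        }
        logger.info("stage affective: recessive sector %s", profile.recommended_sectors[1])
    else:
        pending.append("affective")

    if answers.is_complete(bank, "genogram"):
        genogram = build_genogram(answers.structured_answers)
        report["genogram"] = {
            "graph": genogram_to_json_dict(genogram),
            "dot": genogram_to_dot(genogram),
        }
        logger.info("stage genogram: %d persons, %d unions",
                    len(genogram.persons), len(genogram.unions))
    else:
        pending.append("genogram")

    if answers.is_complete(bank, "differentiation"):
        membership = evaluate_differentiation(
            bank, answers, config.interval_table,
            {k: v for k, v in config.calibrations.items()} or None,
        )
        stages["pattern_membership"] = membership
        report["differentiation"] = {
            "degrees": {p: membership.degrees[p] for p in sorted(membership.degrees)},
            "classifications": dict(sorted(membership.classifications.items())),
            "healthy_interval": {
                p: list(membership.healthy_interval[p]) for p in sorted(membership.healthy_interval)
            },
            "legacy_bowen_score": legacy_bowen_score(membership),
            "legacy_bowen_score_note": "derived convenience summary, not part of the fuzzy assessment",
            "radar": pattern_radar(membership).to_dict(orient="records"),
        }
        logger.info("stage differentiation: %s", membership.classifications)
    else:
        pending.append("differentiation")

    if answers.is_complete(bank, "awareness"):
        deficits = classify_maturity(
            bank, answers, config.awareness_partition, config.maturity_thresholds
        )
        stages["deficits"] = deficits
        report["awareness"] = {"deficits": sorted(f.args[0] for f in deficits)}
        logger.info("stage awareness: %d deficits", len(deficits))
    else:
        pending.append("awareness")

    if answers.is_complete(bank, "interveneer"):
        report["interveneer_answers"] = {
            q.id: answers.likert_answers[q.id] for q in bank.group("interveneer")
        }
    else:
        pending.append("interveneer")

    facts = collect_facts(bank, answers, stages)
    closure = forward_chain(kb, facts)
    rendered, unrendered = derive_recommendations(closure, kb.templates)
    plan = assign_exercises(closure, catalog, answers.respondent_id)

    report["facts"] = sorted(str(f) for f in facts)
    report["closure"] = sorted(str(f) for f in closure)
    report["recommendations"] = [
        {"stage": r.stage, "template_id": r.template_id, "fact": str(r.fact), "text": r.text}
        for r in rendered
    ]
    report["unrendered_facts"] = [str(f) for f in unrendered]
    report["exercise_plan"] = [
        {
            "item": item,
            "exercise_id": exercise_id,
            "rationale": str(fact),
            "description": catalog.entry(item).description,
        }
        for item, exercise_id, fact in plan.assigned
    ]
    report["advice_stream"] = advice_stream(bank, answers)
    report["pending_stages"] = pending
    report["provenance"] = {
        "bank_version": bank.version,
        "kb_version": kb.version,
        "config_hash": config.hash(),
        "seed": seed,
    }
    return report


def report_to_json(report: Mapping[str, Any]) -> str:
    """Canonical byte-deterministic JSON serialisation of a report."""
    return json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
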