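"""Reference instrument: a 140-question bank with the published group structure.

The original clinical question texts are unpublished; this bank reproduces
the instrument's *structure* exactly — 29 affective questions across five
sectors (the four adaptive-diagnostic sectors plus the added spiritual
sector), 12 structured genogram-intake questions, 57 differentiation
questions (17 adaptation, 21 reaction, 19 creativity), 33 awareness
questions over five constructs, and 9 intervention-intake questions —
with synthetic placeholder texts.  Every third Likert question is
positively keyed so both keying directions are exercised.
"""

from __future__ import annotations

from .bank import Question, QuestionBank

# Sector allocation of the 29 affective questions (5 sectors summing to 29).
AFFECTIVE_SECTOR_SIZES = {
    "affective_relational": 6,
    "productivity": 6,
    "sociocultural": 6,
    "organic": 6,
    "spiritual": 5,
}

PATTERN_SIZES = {"adaptation": 17, "reaction": 21, "creativity": 19}

# Construct allocation of the 33 awareness questions.
AWARENESS_CONSTRUCT_SIZES = {
    "assertiveness": 7,
    "self_esteem": 7,
    "autonomy": 7,
    "relationship": 6,
    "differentiation": 6,
}
AWARENESS_CONSTRUCTS = tuple(AWARENESS_CONSTRUCT_SIZES)

# Ids and intake semantics of the 12 genogram questions.
GENOGRAM_QUESTION_IDS = (
    "gen_index_profile",
    "gen_partners",
    "gen_children",
    "gen_parents",
    "gen_parent_union",
    "gen_siblings",
    "gen_grandparents_maternal",
    "gen_grandparents_paternal",
    "gen_household",
    "gen_family_tags",
    "gen_deceased",
    "gen_extended_notes",
)

_GENOGRAM_TEXTS = {
    "gen_index_profile": "Your own profile: sex, and whether you are living.",
    "gen_partners": "List your current and former partners with the status of each union.",
    "gen_children": "List your children, and with which partner each was had.",
    "gen_parents": "Describe your mother and father (alive or deceased).",
    "gen_parent_union": "What is the status of your parents' union?",
    "gen_siblings": "List your siblings.",
    "gen_grandparents_maternal": "Describe your maternal grandparents.",
    "gen_grandparents_paternal": "Describe your paternal grandparents.",
    "gen_household": "Who do you currently live with?",
    "gen_family_tags": "Notable relational features in your family (e.g. symbiotic ties).",
    "gen_deceased": "Family members who have died and when.",
    "gen_extended_notes": "Anything else about your extended family worth noting.",
}


def _likert(qid: str, group: str, subscale: str | None, text: str, index: int) -> Question:
    # Alternate keying: every third item is positively keyed.
    keying = "positive" if index % 3 == 2 else "negative"
    return Question(
        id=qid,
        group=group,
        subscale=subscale,
        text=text,
        response_kind="likert",
        keying=keying,
    )


def build_reference_bank(version: str = "reference-0.1", advice_interval: int = 10) -> QuestionBank:
    """Construct the shipped 140-question reference instrument."""
    questions: list[Question] = []
    counter = 0

    for sector, n in AFFECTIVE_SECTOR_SIZES.items():
        for i in range(1, n + 1):
            questions.append(
                _likert(
                    f"aff_{sector}_{i:02d}",
                    "affective",
                    sector,
                    f"Placeholder statement {i} probing the {sector.replace('_', '-')} "
                    "affective sector (agreement scale 0-4).",
                    counter,
                )
            )
            counter += 1

    for qid in GENOGRAM_QUESTION_IDS:
        questions.append(
            Question(
                id=qid,
                group="genogram",
                subscale=None,
                text=_GENOGRAM_TEXTS[qid],
                response_kind="structured",
            )
        )

    for pattern, n in PATTERN_SIZES.items():
        for i in range(1, n + 1):
            questions.append(
                _likert(
                    f"dif_{pattern}_{i:02d}",
                    "differentiation",
                    pattern,
                    f"Placeholder statement {i} probing the cognitive-interaction "
                    f"pattern of {pattern} (agreement scale 0-4).",
                    counter,
                )
            )
            counter += 1

    for construct, n in AWARENESS_CONSTRUCT_SIZES.items():
        for i in range(1, n + 1):
            questions.append(
                _likert(
                    f"awa_{construct}_{i:02d}",
                    "awareness",
                    None,
                    f"Placeholder reflection {i} on {construct.replace('_', '-')} "
                    "(agreement scale 0-4).",
                    counter,
                )
            )
            counter += 1

    for i in range(1, 10):
        questions.append(
            _likert(
                f"int_{i:02d}",
                "interveneer",
                None,
                f"Placeholder intervention-intake question {i} (agreement scale 0-4).",
                counter,
            )
        )
        counter += 1

    return QuestionBank(questions=questions, version=version, advice_interval=advice_interval)


def awareness_partition(bank: QuestionBank) -> dict[str, list[str]]:
    """Partition the awareness group into its five constructs.

    The reference bank encodes the construct in the question id
    (``awa_<construct>_NN``); custom banks following the same convention are
    partitioned identically, others must supply an explicit partition.
    """
    partition: dict[str, list[str]] = {c: [] for c in AWARENESS_CONSTRUCTS}
    for q in bank.group("awareness"):
        stem = q.id
        if stem.startswith("awa_"):
            stem = stem[4:]
        construct = stem.rsplit("_", 1)[0]
        if construct not in partition:
            raise ValueError(
                f"cannot infer awareness construct from question id {q.id!r}; "
                "supply an explicit partition"
            )
        partition[construct].append(q.id)
    return partition
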