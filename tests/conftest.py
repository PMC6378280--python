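import pytest

from slm import Question, QuestionBank, build_reference_bank
from slm.reference import AWARENESS_CONSTRUCTS


@pytest.fixture(scope="session")
def reference_bank():
    return build_reference_bank()


def make_mini_bank() -> QuestionBank:
    """A small fully-negative-keyed bank (default identity score maps) so
    expected scores can be hand-summed in tests."""
    questions = []
    for sector in ("affective_relational", "productivity", "sociocultural", "organic", "spiritual"):
        for i in (1, 2):
            questions.append(
                Question(id=f"aff_{sector}_{i:02d}", group="affective", subscale=sector,
                         text=f"{sector} item {i}")
            )
    for qid in ("gen_index_profile", "gen_parents"):
        questions.append(
            Question(id=qid, group="genogram", text=qid, response_kind="structured")
        )
    for pattern in ("adaptation", "reaction", "creativity"):
        for i in (1, 2):
            questions.append(
                Question(id=f"dif_{pattern}_{i:02d}", group="differentiation",
                         subscale=pattern, text=f"{pattern} item {i}")
            )
    for construct in AWARENESS_CONSTRUCTS:
        questions.append(
            Question(id=f"awa_{construct}_01", group="awareness", text=f"{construct} item")
        )
    questions.append(Question(id="int_01", group="interveneer", text="intake item"))
    return QuestionBank(questions=questions, version="mini-test")


@pytest.fixture()
def mini_bank():
    return make_mini_bank()


def answer_all(bank: QuestionBank, option: int, groups=None) -> dict[str, int]:
    """Likert answers setting every question of the given groups to `option`."""
    return {
        q.id: option
        for q in bank.questions
        if q.response_kind == "likert" and (groups is None or q.group in groups)
    }


def best_answers(bank: QuestionBank) -> dict[str, int]:
    """The zero-inadequacy option for every Likert question, keying-aware."""
    return {
        q.id: min(q.effective_score_map(), key=lambda o: q.effective_score_map()[o])
        for q in bank.questions
        if q.response_kind == "likert"
    }


def worst_answers(bank: QuestionBank) -> dict[str, int]:
    return {
        q.id: max(q.effective_score_map(), key=lambda o: q.effective_score_map()[o])
        for q in bank.questions
        if q.response_kind == "likert"
    }
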