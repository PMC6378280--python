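"""Forward-chaining rule engine and natural-language recommendation rendering.

The classificatory core is a function-free Horn-clause (Datalog-style)
knowledge base with optional stratified negation-as-failure.  Assessment
facts (recessive sector, age band, pattern classifications, awareness
deficits) are ground atoms; rules derive recommendation atoms; a
string-rewriting step turns derived atoms into natural-language advice via
templates with named slots.

Terms starting with an uppercase letter are variables; everything else is a
constant symbol.  The closure is a least fixpoint: finitely many constants
guarantee termination.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .bank import AnswerSheet, QuestionBank, score_answer


class KnowledgeBaseError(ValueError):
    """Raised when a rule base violates range-restriction or stratification."""


_ATOM_RE = re.compile(r"^\s*(not\s+)?([a-z_][\w]*)\s*(?:\(([^()]*)\))?\s*$")


def _is_variable(term: str) -> bool:
    return bool(term) and term[0].isupper()


@dataclass(frozen=True)
class Fact:
    """A ground atom: predicate over constant symbols."""

    predicate: str
    args: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for a in self.args:
            if _is_variable(a):
                raise ValueError(f"fact {self.predicate}{self.args} is not ground")

    def __str__(self) -> str:
        if not self.args:
            return self.predicate
        return f"{self.predicate}({', '.join(self.args)})"


@dataclass(frozen=True)
class Literal:
    """A possibly-negated atom whose arguments may contain variables."""

    predicate: str
    args: tuple[str, ...] = ()
    negated: bool = False

    def variables(self) -> set[str]:
        return {a for a in self.args if _is_variable(a)}

    def __str__(self) -> str:
        prefix = "not " if self.negated else ""
        if not self.args:
            return prefix + self.predicate
        return f"{prefix}{self.predicate}({', '.join(self.args)})"


def parse_literal(text: str) -> Literal:
    m = _ATOM_RE.match(text)
    if not m:
        raise KnowledgeBaseError(f"cannot parse literal: {text!r}")
    negated, predicate, argstr = m.groups()
    args: tuple[str, ...] = ()
    if argstr is not None and argstr.strip():
        args = tuple(a.strip() for a in argstr.split(","))
        if any(not a for a in args):
            raise KnowledgeBaseError(f"empty argument in literal: {text!r}")
    return Literal(predicate=predicate, args=args, negated=bool(negated))


def parse_fact(text: str) -> Fact:
    lit = parse_literal(text)
    if lit.negated:
        raise ValueError(f"facts cannot be negated: {text!r}")
    return Fact(lit.predicate, lit.args)


@dataclass(frozen=True)
class Rule:
    """head :- body.  Range-restricted; negated literals only against lower strata."""

    id: str
    head: Literal
    body: tuple[Literal, ...]
    stratum: int = 0

    def __post_init__(self) -> None:
        if self.head.negated:
            raise KnowledgeBaseError(f"rule {self.id}: head cannot be negated")
        positive_vars: set[str] = set()
        for lit in self.body:
            if not lit.negated:
                positive_vars |= lit.variables()
        unbound = self.head.variables() - positive_vars
        if unbound:
            raise KnowledgeBaseError(
                f"rule {self.id} is not range-restricted: head variables "
                f"{sorted(unbound)} never appear in a positive body literal"
            )
        for lit in self.body:
            if lit.negated and (lit.variables() - positive_vars):
                raise KnowledgeBaseError(
                    f"rule {self.id}: negated literal {lit} has variables not bound "
                    "by a positive body literal"
                )
        if self.stratum < 0:
            raise KnowledgeBaseError(f"rule {self.id}: stratum must be non-negative")


@dataclass(frozen=True)
class RecommendationTemplate:
    """Rewrites a derived atom into natural language.

    ``trigger`` is an atom pattern such as ``recommend(Sector, Band, Trait)``;
    slots in ``text`` are the trigger's variable names lowercased, e.g.
    ``{sector}``.  Constants in rendered slots have underscores replaced by
    spaces.
    """

    id: str
    trigger: Literal
    text: str
    group: str = "general"

    def __post_init__(self) -> None:
        slots = set(re.findall(r"\{(\w+)\}", self.text))
        bound = {v.lower() for v in self.trigger.variables()}
        unbound = slots - bound
        if unbound:
            raise KnowledgeBaseError(
                f"template {self.id}: slots {sorted(unbound)} not bound by trigger"
            )


@dataclass
class KnowledgeBase:
    rules: list[Rule] = field(default_factory=list)
    templates: list[RecommendationTemplate] = field(default_factory=list)
    facts: list[Fact] = field(default_factory=list)
    version: str = "unversioned"

    def validate(self) -> None:
        seen_rules: set[str] = set()
        for rule in self.rules:
            if rule.id in seen_rules:
                raise KnowledgeBaseError(f"duplicate rule id: {rule.id}")
            seen_rules.add(rule.id)
        # Stratification: every rule defining a predicate that some rule
        # negates must sit at a strictly lower stratum than the negating rule.
        defining_strata: dict[str, set[int]] = {}
        for rule in self.rules:
            defining_strata.setdefault(rule.head.predicate, set()).add(rule.stratum)
        for rule in self.rules:
            for lit in rule.body:
                if not lit.negated:
                    continue
                for stratum in defining_strata.get(lit.predicate, set()):
                    if stratum >= rule.stratum:
                        raise KnowledgeBaseError(
                            f"stratification violation: rule {rule.id} (stratum "
                            f"{rule.stratum}) negates {lit.predicate}, which is "
                            f"defined at stratum {stratum}"
                        )
        seen_templates: set[str] = set()
        for tpl in self.templates:
            if tpl.id in seen_templates:
                raise KnowledgeBaseError(f"duplicate template id: {tpl.id}")
            seen_templates.add(tpl.id)


# ---------------------------------------------------------------------------
# forward chaining

Substitution = dict[str, str]


def _match_atom(lit: Literal, fact: Fact, subst: Substitution) -> Substitution | None:
    if lit.predicate != fact.predicate or len(lit.args) != len(fact.args):
        return None
    out = dict(subst)
    for term, value in zip(lit.args, fact.args):
        if _is_variable(term):
            if out.get(term, value) != value:
                return None
            out[term] = value
        elif term != value:
            return None
    return out


def _ground(lit: Literal, subst: Substitution) -> Fact:
    return Fact(lit.predicate, tuple(subst.get(a, a) for a in lit.args))


def _solutions(
    body: Sequence[Literal],
    facts_by_pred: Mapping[str, list[Fact]],
    subst: Substitution,
) -> Iterable[Substitution]:
    """Backtracking search over the positive literals; negation checked last
    (validation guarantees negated literals are ground once positives bind)."""
    if not body:
        yield subst
        return
    lit, rest = body[0], body[1:]
    if lit.negated:
        grounded = _ground(lit, subst)
        if grounded not in set(facts_by_pred.get(lit.predicate, [])):
            yield from _solutions(rest, facts_by_pred, subst)
        return
    for fact in facts_by_pred.get(lit.predicate, []):
        extended = _match_atom(lit, fact, subst)
        if extended is not None:
            yield from _solutions(rest, facts_by_pred, extended)


def _reorder_body(body: tuple[Literal, ...]) -> tuple[Literal, ...]:
    # Evaluate positive literals first so negated ones are ground when checked.
    return tuple(l for l in body if not l.negated) + tuple(l for l in body if l.negated)


def forward_chain(kb: KnowledgeBase | Sequence[Rule], facts: Iterable[Fact]) -> set[Fact]:
    """Least-fixpoint closure of the facts under the rules.

    Strata are evaluated in ascending order; within each stratum, naive
    bottom-up iteration to fixpoint.  Deterministic set semantics: rule
    order never affects the result.
    """
    if isinstance(kb, KnowledgeBase):
        kb.validate()
        rules = list(kb.rules)
        closure: set[Fact] = set(facts) | set(kb.facts)
    else:
        rules = list(kb)
        KnowledgeBase(rules=rules).validate()
        closure = set(facts)

    by_stratum: dict[int, list[Rule]] = {}
    for rule in rules:
        by_stratum.setdefault(rule.stratum, []).append(rule)

    for stratum in sorted(by_stratum):
        changed = True
        while changed:
            changed = False
            facts_by_pred: dict[str, list[Fact]] = {}
            for fact in closure:
                facts_by_pred.setdefault(fact.predicate, []).append(fact)
            new: set[Fact] = set()
            for rule in by_stratum[stratum]:
                body = _reorder_body(rule.body)
                for subst in _solutions(body, facts_by_pred, {}):
                    derived = _ground(rule.head, subst)
                    if derived not in closure:
                        new.add(derived)
            if new:
                closure |= new
                changed = True
    return closure


# ---------------------------------------------------------------------------
# awareness classification

DEFAULT_MATURITY_THRESHOLD = 0.5


def awareness_fractions(
    bank: QuestionBank,
    answers: AnswerSheet,
    partition: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Per-construct normalised inadequacy over the awareness group, in [0,1]."""
    answers.require_complete(bank, "awareness")
    if partition is None:
        from .reference import awareness_partition

        partition = awareness_partition(bank)
    fractions: dict[str, float] = {}
    for construct, qids in partition.items():
        questions = [bank[qid] for qid in qids]
        if not questions:
            raise ValueError(f"awareness construct {construct!r} has no questions")
        max_total = sum(q.max_score() for q in questions)
        total = sum(score_answer(q, answers.likert_answers[q.id]) for q in questions)
        fractions[construct] = total / max_total
    return fractions


def classify_maturity(
    bank: QuestionBank,
    answers: AnswerSheet,
    partition: Mapping[str, Sequence[str]] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> set[Fact]:
    """Threshold the awareness constructs into deficit facts.

    A construct whose normalised inadequacy meets or exceeds its threshold
    (default 0.5) yields ``deficit(<construct>)``; the resulting facts feed
    the recommendation rules and exercise assignment.
    """
    thresholds = thresholds or {}
    fractions = awareness_fractions(bank, answers, partition)
    deficits: set[Fact] = set()
    for construct, fraction in fractions.items():
        if fraction >= thresholds.get(construct, DEFAULT_MATURITY_THRESHOLD):
            deficits.add(Fact("deficit", (construct,)))
    return deficits


# ---------------------------------------------------------------------------
# rendering

STAGE_ORDER = ("affective", "genogram", "differentiation", "awareness", "interveneer", "general")


def _humanize(symbol: str) -> str:
    return symbol.replace("_", " ")


@dataclass
class RenderedAdvice:
    stage: str
    template_id: str
    fact: Fact
    text: str


def derive_recommendations(
    closure: Iterable[Fact],
    templates: Sequence[RecommendationTemplate],
) -> tuple[list[RenderedAdvice], list[Fact]]:
    """Render every recommendation fact that has a matching template.

    Returns the rendered advice, ordered by stage then template id then
    arguments (byte-deterministic), plus the recommendation-predicate facts
    left unrendered for lack of a template.
    """
    template_preds = {t.trigger.predicate for t in templates}
    rendered: list[RenderedAdvice] = []
    matched: set[Fact] = set()
    for tpl in templates:
        for fact in closure:
            subst = _match_atom(tpl.trigger, fact, {})
            if subst is None:
                continue
            slots = {var.lower(): _humanize(val) for var, val in subst.items()}
            rendered.append(
                RenderedAdvice(
                    stage=tpl.group,
                    template_id=tpl.id,
                    fact=fact,
                    text=tpl.text.format(**slots),
                )
            )
            matched.add(fact)
    rendered.sort(
        key=lambda r: (
            STAGE_ORDER.index(r.stage) if r.stage in STAGE_ORDER else len(STAGE_ORDER),
            r.template_id,
            r.fact.args,
        )
    )
    unrendered = sorted(
        (f for f in closure if f.predicate in template_preds and f not in matched),
        key=str,
    )
    return rendered, unrendered


# ---------------------------------------------------------------------------
# serialisation

def kb_to_dict(kb: KnowledgeBase) -> dict[str, Any]:
    return {
        "version": kb.version,
        "facts": [str(f) for f in kb.facts],
        "rules": [
            {
                "id": r.id,
                "if": [str(l) for l in r.body],
                "then": str(r.head),
                "stratum": r.stratum,
            }
            for r in kb.rules
        ],
        "templates": [
            {"id": t.id, "trigger": str(t.trigger), "text": t.text, "group": t.group}
            for t in kb.templates
        ],
    }


def kb_from_dict(doc: Mapping[str, Any]) -> KnowledgeBase:
    rules = [
        Rule(
            id=str(rec["id"]),
            head=parse_literal(str(rec["then"])),
            body=tuple(parse_literal(str(l)) for l in rec.get("if", [])),
            stratum=int(rec.get("stratum", 0)),
        )
        for rec in doc.get("rules", [])
    ]
    templates = [
        RecommendationTemplate(
            id=str(rec["id"]),
            trigger=parse_literal(str(rec["trigger"])),
            text=str(rec["text"]),
            group=str(rec.get("group", "general")),
        )
        for rec in doc.get("templates", [])
    ]
    facts = [parse_fact(str(f)) for f in doc.get("facts", [])]
    kb = KnowledgeBase(
        rules=rules,
        templates=templates,
        facts=facts,
        version=str(doc.get("version", "unversioned")),
    )
    kb.validate()
    return kb


def load_kb(path: str | Path) -> KnowledgeBase:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise KnowledgeBaseError(f"{path}: knowledge base must be a mapping")
    return kb_from_dict(doc)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(kb_to_dict(kb), fh, sort_keys=False)
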