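"""Forward chaining: closure correctness against a brute-force grounding
oracle, stratified negation, awareness classification, template rendering."""

import itertools
import random

import pytest

from slm import (
    AnswerSheet,
    Fact,
    KnowledgeBase,
    KnowledgeBaseError,
    RecommendationTemplate,
    Rule,
    classify_maturity,
    derive_recommendations,
    forward_chain,
    parse_fact,
    parse_literal,
)
from slm.inference import kb_from_dict, kb_to_dict
from slm.kb import default_knowledge_base

from conftest import answer_all, best_answers


def rule(rid, body, head, stratum=0):
    return Rule(
        id=rid,
        head=parse_literal(head),
        body=tuple(parse_literal(b) for b in body),
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# independent oracle: enumerate all ground instantiations, iterate to fixpoint

def grounding_oracle(rules, facts):
    """Naive fixpoint over the fully grounded program (positive rules only)."""
    constants = set()
    for f in facts:
        constants |= set(f.args)
    for r in rules:
        for lit in (r.head, *r.body):
            constants |= {a for a in lit.args if not a[0].isupper()}
    constants = sorted(constants) or ["_"]

    ground_rules = []
    for r in rules:
        variables = sorted(
            {a for lit in (r.head, *r.body) for a in lit.args if a[0].isupper()}
        )
        for values in itertools.product(constants, repeat=len(variables)):
            subst = dict(zip(variables, values))
            body = [
                Fact(l.predicate, tuple(subst.get(a, a) for a in l.args)) for l in r.body
            ]
            head = Fact(r.head.predicate, tuple(subst.get(a, a) for a in r.head.args))
            ground_rules.append((body, head))

    closure = set(facts)
    changed = True
    while changed:
        changed = False
        for body, head in ground_rules:
            if head not in closure and all(b in closure for b in body):
                closure.add(head)
                changed = True
    return closure


def random_kb(rng: random.Random, max_rules=10, max_constants=8):
    predicates = [f"p{i}" for i in range(rng.randint(1, 6))]
    arities = {p: rng.randint(0, 2) for p in predicates}
    constants = [f"c{i}" for i in range(rng.randint(1, max_constants))]
    variables = ["X", "Y"]

    def atom(allow_vars):
        p = rng.choice(predicates)
        pool = constants + (variables if allow_vars else [])
        return p, tuple(rng.choice(pool) for _ in range(arities[p]))

    rules = []
    for i in range(rng.randint(0, max_rules)):
        body = []
        for _ in range(rng.randint(1, 3)):
            p, args = atom(allow_vars=True)
            body.append(parse_literal(f"{p}({', '.join(args)})" if args else p))
        bound = {a for l in body for a in l.args if a[0].isupper()}
        p = rng.choice(predicates)
        head_args = tuple(
            rng.choice(sorted(bound) if bound and rng.random() < 0.5 else constants)
            for _ in range(arities[p])
        )
        head = parse_literal(f"{p}({', '.join(head_args)})" if head_args else p)
        rules.append(Rule(id=f"r{i}", head=head, body=tuple(body)))

    facts = set()
    for _ in range(rng.randint(1, 8)):
        p, args = atom(allow_vars=False)
        facts.add(Fact(p, args))
    return rules, facts


class TestForwardChain:
    def test_no_rules_identity(self):
        facts = {parse_fact("a(k)"), parse_fact("b(k, j)")}
        assert forward_chain([], facts) == facts

    def test_chain_closure(self):
        rules = [rule("r1", ["a(X)"], "b(X)"), rule("r2", ["b(X)"], "c(X)")]
        closure = forward_chain(rules, {parse_fact("a(k)")})
        assert closure == {parse_fact("a(k)"), parse_fact("b(k)"), parse_fact("c(k)")}

    def test_join_rule(self):
        rules = [rule("r1", ["edge(X, Y)", "edge(Y, Z)"], "path(X, Z)")]
        closure = forward_chain(rules, {parse_fact("edge(a, b)"), parse_fact("edge(b, c)")})
        assert parse_fact("path(a, c)") in closure
        assert parse_fact("path(a, b)") not in closure

    @pytest.mark.parametrize("seed", range(60))
    def test_closure_matches_grounding_oracle(self, seed):
        rng = random.Random(seed)
        rules, facts = random_kb(rng)
        assert forward_chain(rules, facts) == grounding_oracle(rules, facts)

    def test_monotone_in_facts(self):
        rules = [rule("r1", ["a(X)"], "b(X)")]
        small = forward_chain(rules, {parse_fact("a(k)")})
        large = forward_chain(rules, {parse_fact("a(k)"), parse_fact("a(j)")})
        assert small <= large

    def test_idempotent(self):
        rules = [rule("r1", ["a(X)"], "b(X)"), rule("r2", ["b(X)", "a(X)"], "c(X)")]
        once = forward_chain(rules, {parse_fact("a(k)")})
        assert forward_chain(rules, once) == once

    def test_rule_order_irrelevant(self):
        rules = [rule("r1", ["a(X)"], "b(X)"), rule("r2", ["b(X)"], "c(X)")]
        facts = {parse_fact("a(k)")}
        assert forward_chain(rules, facts) == forward_chain(list(reversed(rules)), facts)

    def test_range_restriction_rejected(self):
        with pytest.raises(KnowledgeBaseError, match="range-restricted"):
            rule("bad", ["a(X)"], "b(Y)")

    def test_stratification_violation_rejected(self):
        rules = [
            rule("r1", ["a(X)"], "b(X)"),
            rule("r2", ["a(X)", "not b(X)"], "c(X)", stratum=0),
        ]
        with pytest.raises(KnowledgeBaseError, match="[Ss]tratification"):
            forward_chain(rules, set())

    def test_stratified_negation(self):
        rules = [
            rule("r1", ["a(X)"], "b(X)"),
            rule("r2", ["a(X)", "not b(X)"], "c(X)", stratum=1),
            rule("r3", ["node(X)", "not flagged(X)"], "clean(X)", stratum=1),
        ]
        facts = {parse_fact("a(k)"), parse_fact("node(n)"), parse_fact("node(m)"),
                 parse_fact("flagged(m)")}
        closure = forward_chain(rules, facts)
        assert parse_fact("c(k)") not in closure  # b(k) derived at stratum 0
        assert parse_fact("clean(n)") in closure
        assert parse_fact("clean(m)") not in closure

    def test_negated_head_rejected(self):
        with pytest.raises(KnowledgeBaseError):
            rule("bad", ["a(X)"], "not b(X)")


class TestMaturityClassification:
    def test_all_best_gives_no_deficits(self, mini_bank):
        sheet = AnswerSheet("r", 30, likert_answers=best_answers(mini_bank))
        assert classify_maturity(mini_bank, sheet) == set()

    def test_threshold_crossing_constructs_flagged(self, mini_bank):
        answers = best_answers(mini_bank)
        for construct in ("assertiveness", "self_esteem", "autonomy"):
            answers[f"awa_{construct}_01"] = 4
        sheet = AnswerSheet("r", 30, likert_answers=answers)
        deficits = classify_maturity(mini_bank, sheet)
        assert deficits == {
            Fact("deficit", ("assertiveness",)),
            Fact("deficit", ("self_esteem",)),
            Fact("deficit", ("autonomy",)),
        }

    def test_relationship_vs_differentiation_discrimination(self, mini_bank):
        """Two sheets differing only on those construct items flag differently."""
        base = best_answers(mini_bank)
        rel = dict(base, awa_relationship_01=4)
        dif = dict(base, awa_differentiation_01=4)
        assert classify_maturity(mini_bank, AnswerSheet("r", 30, likert_answers=rel)) == {
            Fact("deficit", ("relationship",))
        }
        assert classify_maturity(mini_bank, AnswerSheet("r", 30, likert_answers=dif)) == {
            Fact("deficit", ("differentiation",))
        }

    def test_incomplete_group_raises(self, mini_bank):
        answers = best_answers(mini_bank)
        del answers["awa_autonomy_01"]
        with pytest.raises(ValueError):
            classify_maturity(mini_bank, AnswerSheet("r", 30, likert_answers=answers))

    def test_custom_threshold(self, mini_bank):
        answers = best_answers(mini_bank)
        answers["awa_autonomy_01"] = 1  # fraction 0.25
        sheet = AnswerSheet("r", 30, likert_answers=answers)
        assert classify_maturity(mini_bank, sheet) == set()
        deficits = classify_maturity(mini_bank, sheet, thresholds={"autonomy": 0.2})
        assert deficits == {Fact("deficit", ("autonomy",))}


class TestRendering:
    def test_printed_advice_reproduced(self):
        kb = default_knowledge_base()
        closure = {parse_fact("recommend(sociocultural, b33_plus, assertiveness)")}
        rendered, unrendered = derive_recommendations(closure, kb.templates)
        assert len(rendered) == 1
        assert "assertiveness" in rendered[0].text
        assert "sociocultural" in rendered[0].text
        assert unrendered == []

    def test_empty_closure_renders_nothing(self):
        kb = default_knowledge_base()
        rendered, unrendered = derive_recommendations(set(), kb.templates)
        assert rendered == [] and unrendered == []

    def test_rendering_deterministic(self):
        kb = default_knowledge_base()
        closure = {
            parse_fact("awareness_comment(autonomy)"),
            parse_fact("awareness_comment(self_esteem)"),
            parse_fact("pattern_comment(adaptation, above)"),
            parse_fact("recommend_sector(affective_relational)"),
        }
        first = [(r.template_id, r.text) for r in derive_recommendations(closure, kb.templates)[0]]
        second = [(r.template_id, r.text) for r in derive_recommendations(closure, kb.templates)[0]]
        assert first == second
        stages = [r.stage for r in derive_recommendations(closure, kb.templates)[0]]
        assert stages == sorted(stages, key=["affective", "genogram", "differentiation",
                                             "awareness", "interveneer", "general"].index)

    def test_fact_without_template_reported_unrendered(self):
        templates = [
            RecommendationTemplate(
                id="t", trigger=parse_literal("advice(X)"), text="{x}", group="general"
            )
        ]
        closure = {parse_fact("advice(a)"), parse_fact("other(b)")}
        rendered, unrendered = derive_recommendations(closure, templates)
        assert [r.fact for r in rendered] == [parse_fact("advice(a)")]
        assert unrendered == []  # other/1 has no template predicate registered

    def test_template_with_unbound_slot_rejected(self):
        with pytest.raises(KnowledgeBaseError):
            RecommendationTemplate(
                id="bad", trigger=parse_literal("advice(X)"), text="{x} {y}", group="general"
            )


class TestKbSerialisation:
    def test_default_kb_round_trips_through_yaml_dict(self):
        kb = default_knowledge_base()
        doc = kb_to_dict(kb)
        rebuilt = kb_from_dict(doc)
        assert kb_to_dict(rebuilt) == doc

    def test_default_kb_validates(self):
        default_knowledge_base().validate()

    def test_duplicate_rule_id_rejected(self):
        kb = KnowledgeBase(rules=[rule("r", ["a(X)"], "b(X)"), rule("r", ["b(X)"], "c(X)")])
        with pytest.raises(KnowledgeBaseError, match="duplicate"):
            kb.validate()
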