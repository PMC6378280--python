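"""Reference knowledge base: the shipped rule set and advice templates.

The rules reproduce the assessment behaviours the method prescribes: an
affective-relational advice is always produced once the affective group is
complete; a complementary advice targets the recessive sector; personalised
advice combines the recessive sector, the respondent's age band and each
awareness deficit; pattern classifications outside the healthy band produce
comments and mark the corresponding intervention exercise as relevant.
Rule and template content is data — clinics edit the YAML, not the engine.
"""

from __future__ import annotations

from .inference import KnowledgeBase, RecommendationTemplate, Rule, parse_literal


def _rule(rid: str, body: list[str], head: str, stratum: int = 0) -> Rule:
    return Rule(
        id=rid,
        head=parse_literal(head),
        body=tuple(parse_literal(b) for b in body),
        stratum=stratum,
    )


def _template(tid: str, trigger: str, text: str, group: str) -> RecommendationTemplate:
    return RecommendationTemplate(
        id=tid, trigger=parse_literal(trigger), text=text, group=group
    )


def default_knowledge_base(version: str = "kb-reference-0.1") -> KnowledgeBase:
    rules = [
        # Affective stage: always one affective-relational advice, plus the
        # recessive-sector advice.
        _rule("r_affective_always", ["stage_complete(affective)"],
              "recommend_sector(affective_relational)"),
        _rule("r_recessive_sector", ["recessive_sector(S)"], "recommend_complement(S)"),
        # Personalised advice: recessive sector x age band x core deficit.
        _rule("r_personal_assertiveness",
              ["recessive_sector(S)", "age_band(B)", "deficit(assertiveness)"],
              "recommend(S, B, assertiveness)"),
        _rule("r_personal_self_esteem",
              ["recessive_sector(S)", "age_band(B)", "deficit(self_esteem)"],
              "recommend(S, B, self_esteem)"),
        _rule("r_personal_autonomy",
              ["recessive_sector(S)", "age_band(B)", "deficit(autonomy)"],
              "recommend(S, B, autonomy)"),
        # Awareness comments for every deficit construct.
        _rule("r_awareness_comment", ["deficit(T)"], "awareness_comment(T)"),
        # Pattern comments when a degree leaves the healthy band.
        _rule("r_pattern_above", ["pattern_above(P)"], "pattern_comment(P, above)"),
        _rule("r_pattern_below", ["pattern_below(P)"], "pattern_comment(P, below)"),
        # Therapist-facing stereotype notes for an adult presenting an
        # accommodate-and-struggle profile.
        _rule("r_stereotype_adult",
              ["pattern_above(adaptation)", "pattern_above(reaction)", "age_band(b33_plus)"],
              "stereotype(adolescent_like)"),
        _rule("r_stereotype_young_adult",
              ["pattern_above(adaptation)", "pattern_above(reaction)", "age_band(b25_32)"],
              "stereotype(overindulged_child_like)"),
        # Exercise relevance: one catalog item per assessed feature.
        _rule("r_ex_affective", ["recessive_sector(S)"], "exercise_relevant(affective_area)"),
        _rule("r_ex_adapt_above", ["pattern_above(adaptation)"],
              "exercise_relevant(pattern_adaptation)"),
        _rule("r_ex_adapt_below", ["pattern_below(adaptation)"],
              "exercise_relevant(pattern_adaptation)"),
        _rule("r_ex_react_above", ["pattern_above(reaction)"],
              "exercise_relevant(pattern_reaction)"),
        _rule("r_ex_react_below", ["pattern_below(reaction)"],
              "exercise_relevant(pattern_reaction)"),
        _rule("r_ex_creat_above", ["pattern_above(creativity)"],
              "exercise_relevant(pattern_creativity)"),
        _rule("r_ex_creat_below", ["pattern_below(creativity)"],
              "exercise_relevant(pattern_creativity)"),
        _rule("r_ex_relationship", ["deficit(relationship)"],
              "exercise_relevant(relationship)"),
        _rule("r_ex_differentiation", ["deficit(differentiation)"],
              "exercise_relevant(differentiation_of_self)"),
        _rule("r_ex_autonomy", ["deficit(autonomy)"], "exercise_relevant(autonomy)"),
        _rule("r_ex_assertiveness", ["deficit(assertiveness)"],
              "exercise_relevant(assertiveness)"),
        _rule("r_ex_self_esteem", ["deficit(self_esteem)"],
              "exercise_relevant(self_esteem)"),
    ]

    templates = [
        _template(
            "t_sector_affective_relational",
            "recommend_sector(affective_relational)",
            "Invest in the quality of your closest bonds: the relationship precedes "
            "the individual, and strengthening it sustains every other area of life.",
            "affective",
        ),
        _template(
            "t_sector_complement",
            "recommend_complement(Sector)",
            "Your {sector} area is currently the least developed. Give it deliberate "
            "attention this week and notice what small change it invites.",
            "affective",
        ),
        _template(
            "t_personalised",
            "recommend(Sector, Band, Trait)",
            "Your lack of {trait} may be interfering on your {sector} activities. "
            "Strengthen the quality of your personal and professional projects by "
            "investing in and expanding your options of leisure and pleasure.",
            "affective",
        ),
        _template(
            "t_awareness_comment",
            "awareness_comment(Trait)",
            "Reflect on your {trait}: becoming aware of the defence mechanisms at "
            "work here is the first step towards redefining them.",
            "awareness",
        ),
        _template(
            "t_pattern_comment",
            "pattern_comment(Pattern, Direction)",
            "Your degree of {pattern} lies {direction} the healthy range for your "
            "age. Observe when this pattern appears and what triggers it.",
            "differentiation",
        ),
        _template(
            "t_stereotype",
            "stereotype(Label)",
            "Therapist note: the combined pattern profile suggests an {label} "
            "functioning relative to chronological age.",
            "differentiation",
        ),
    ]

    kb = KnowledgeBase(rules=rules, templates=templates, version=version)
    kb.validate()
    return kb
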