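# systemic-linking

Computer-aided assessment for Brief Psychotherapy: a library and CLI (`slm`)
that scores a 140-question Likert instrument, profiles five affective-area
sectors, evaluates fuzzy cognitive-interaction patterns against age-banded
healthy limits, builds a multigenerational genogram, and derives
recommendations and intervention exercises by forward-chaining rule
inference with natural-language templates. A synthetic-respondent simulator
makes every stage testable without clinical data.

It is decision support for a qualified professional — the output report is
explicitly non-curative and assists, never replaces, the psychotherapist.

## The assessment model

The instrument has 140 questions in five groups: **affective** (29, split
over the sectors affective-relational, productivity, sociocultural, organic
and spiritual), **genogram** intake (12, structured family records),
**differentiation** (57: 17 adaptation, 21 reaction, 19 creativity),
**awareness/redefinition** (33, over five constructs) and **interveneer**
intake (9). Likert questions offer five exclusive options *k* ∈ {0..4}; each
(question, option) pair carries a non-negative *inadequacy score* s(q, k)
(by default s = k for negatively keyed items and s = 4 − k for positively
keyed ones; banks may override per question).

**Affective sectors.** Each sector's development is

  D(s) = 100 · (1 − Σ_q s(q, a_q) / Σ_q max_k s(q, k)) ∈ [0, 100].

One recommendation always targets the affective-relational sector; a
complementary one targets the most recessive (lowest-D) of the other four,
ties broken by Maslow's hierarchy (ascending priority: spiritual <
sociocultural < affective-relational < productivity < organic; the more
basic-needs sector wins).

**Differentiation of self.** Instead of a single deterministic 0–100 score,
three simultaneous fuzzy degrees of pertinence μ_p ∈ [0, 1] (adaptation,
reaction, creativity) are computed by normalised-sum aggregation, optionally
through a piecewise-linear membership calibration. Each degree is
classified **below / inside / above** a healthy interval [inferior,
superior] that depends on the respondent's age band (0–7, 8–12, 13–19,
20–24, 25–32, 33+). A legacy 0–100 summary,
100·(μ_c + (1−μ_a) + (1−μ_r))/3, is exported for continuity with the
classical scale and flagged as a derived convenience.

**Inference.** Crisp facts from the completed stages —
`recessive_sector(·)`, `age_band(·)`, `pattern_above/below/inside(·)`,
`deficit(·)` from thresholding the awareness constructs — are closed under
a function-free Horn-clause knowledge base (Datalog-style, with stratified
negation supported). Derived atoms are rewritten into advice text by
templates with named slots, and each of the nine intervention-exercise
catalog items is assigned exactly when its relevance fact is derived, so
every output is auditable back to the answers.

## Worked example

```python
from slm import (build_reference_bank, run_assessment,
                 simulate_respondent, subject_a_profile)

bank = build_reference_bank()                      # 140-question instrument
sheet = simulate_respondent(subject_a_profile(), bank)  # 37-year-old fixture
report = run_assessment(bank, sheet)

report["affective"]["development"]
# {'affective_relational': 50.0, 'organic': 75.0, 'productivity': 50.0,
#  'sociocultural': 25.0, 'spiritual': 50.0}
report["affective"]["recommended_sectors"]
# ['affective_relational', 'sociocultural']   <- sociocultural is recessive
report["differentiation"]["classifications"]
# {'adaptation': 'above', 'creativity': 'below', 'reaction': 'above'}
report["awareness"]["deficits"]
# ['assertiveness', 'autonomy', 'relationship', 'self_esteem']
report["recommendations"][0]["text"]
# 'Your lack of assertiveness may be interfering on your sociocultural
#  activities. Strengthen the quality of your personal and professional
#  projects by investing in and expanding your options of leisure and pleasure.'
```

The sector scores read directly off the latent fixture: the sociocultural
trait (inadequacy fraction 0.8, quantised to 0.75 on the Likert grid) gives
development 25 — the least developed sector — so the complementary advice
targets it. Adaptation and reaction degrees (1.0 and 0.75) exceed the 33+
healthy bands, creativity (0.25) falls below, and the four thresholded
awareness constructs become deficit facts that drive the advice texts and
the eight-item exercise plan.

The same pipeline from the shell:

```bash
slm export-bank bank.yaml
slm validate-bank bank.yaml
slm simulate --n 1 --noise 0.5 --seed 42 --bank bank.yaml --out-dir sims/
slm run --bank bank.yaml --answers sims/sim_0000.json --out report.json
slm genogram sims/sim_0000.json --format dot
slm recover --n 200 --noise 0.5 --seed 42
```

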