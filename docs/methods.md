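# Methods

## Scope and design stance

The package implements a computer-aided assessment pipeline for Brief
Psychotherapy: instrument scoring, five-sector affective profiling, fuzzy
cognitive-interaction-pattern evaluation, genogram construction, rule-based
recommendation inference with template rendering, and intervention-exercise
assignment. The clinical *content* — question texts, healthy-interval
numbers, rule and template wording, exercise descriptions — is data, shipped
as clearly labelled reference placeholders and overridable via YAML. The
*algorithms* — scoring, selection, classification, inference, rendering,
assignment — are the tested surface.

## Instrument and scoring

Likert questions have five exclusive options (0..4). Each question carries
an inadequacy score map; the default is the identity on the option index for
negatively keyed items and its reverse (4 − k) for positively keyed items —
the simplest monotone map consistent with a symmetric agreement scale.
Clinics encode professional judgment by overriding the map per question
(e.g. `{0:0, 1:1, 2:3, 3:6, 4:10}` for a steeply penalised item); every
aggregation below normalises by the maximum attainable sum, so overrides
change weights, not ranges.

The reference bank reproduces the published instrument structure exactly
(140 questions: 29 affective across five sectors 6/6/6/6/5, 12 structured
genogram intake, 57 differentiation as 17/21/19, 33 awareness across
constructs 7/7/7/6/6, 9 interveneer) with placeholder English texts, since
the original clinical texts are unpublished. Every third Likert item is
positively keyed so both keying directions are exercised in all tests.

Gamified advice checkpoints fire every `advice_interval` answered questions
(default 10 → 14 checkpoints over a full 140-answer run, a steady reward
cadence). In this batch implementation the advice stream is a report
section, ordered by checkpoint, rather than an interactive prompt.

## Affective sectors and recommendation selection

Sector development is 100·(1 − inadequacy fraction), so 100 = fully
developed and "lower value = least developed". Selection returns the pair
(affective-relational, most recessive of the remaining four). Tie-break
among equally recessive sectors uses the Maslow ascending priority
(spiritual < sociocultural < affective-relational < productivity < organic)
with the **higher-priority (more basic-needs) sector winning** — the
hierarchy addresses basic needs first. The direction is a genuine design
choice (only the ordering itself is prescribed); it is configurable through
the `priority` argument.

## Fuzzy pattern evaluation

Each pattern degree is the normalised inadequacy sum over its subscale,
optionally passed through a per-pattern piecewise-linear calibration curve
(`numpy.interp` over (x, y) knots; identity by default). This is a
degenerate fuzzy-membership system chosen for monotonicity and
reproducibility; richer trapezoidal memberships are expressible purely as
calibration data, never code changes. The three degrees are evaluated
simultaneously and deliberately not normalised across patterns — all three
can be 1.

Classification compares each degree with an age-banded healthy interval;
both endpoints classify as *inside* (closed interval: deterministic and
testable). The six age bands are [0,7], [8,12], [13,19], [20,24], [25,32],
[33,∞). The shipped interval table is a **placeholder calibration**:
adaptation/reaction bands shift downward with age (symbiotic accommodation
is healthy in a young child, not in an adult) and the creativity band rises
with age. Every cell is overridable via YAML; the table is clinical
calibration, not algorithm. Chronological age drives the lookup; emotional
age has no estimator here, so adult-with-adolescent-pattern readings are
expressed as knowledge-base rules over the classification facts (e.g. the
stereotype note), not as arithmetic.

The legacy 0–100 score, 100·(creativity + (1−adaptation) + (1−reaction))/3,
is a convenience bridge to the classical deterministic differentiation
scale (low = fused egos). It is affine in each degree, hence attains exactly
[0, 100] at the cube corners, and is flagged in the report as a derived
summary outside the fuzzy assessment proper.

## Genogram

The 12 structured intake answers (index profile, partners with union
status, children per union, parents, parental union status, siblings,
grandparents per side, household, relational tags, deceased, notes) build a
three-generation graph: persons, unions (married/divorced/remarried/
partnered) and union→child offspring links. Invariants enforced at build
and load: index person present, no dangling references, at most one parent
union (≤ 2 parents) per child, acyclic parentage (checked via the directed
parent→child graph). Exports: DOT (square = male, circle = female,
× = deceased, union edges labelled with status) and JSON that round-trips
to an identical genogram. No automated pattern detection is performed over
the graph; interpretation belongs to the therapist.

## Rule engine

The classificatory logic is function-free Horn clauses with optional
stratified negation-as-failure — the minimal dialect that supports the
described behaviour while guaranteeing termination (finite Herbrand base
over the assessment constants). Terms beginning with an uppercase letter
are variables. Loading rejects non-range-restricted rules (every head
variable, and every variable in a negated literal, must occur in a positive
body literal) and stratification violations (a rule may negate only
predicates defined at strictly lower strata). Evaluation is naive bottom-up
fixpoint per stratum — knowledge bases here hold tens of rules and at most
hundreds of ground atoms, so no semi-naive evaluation or indexing is
warranted. Correctness is checked in tests against an independent
brute-force oracle that grounds every rule over all constants and iterates.

Awareness classification thresholds each construct's inadequacy fraction
into a `deficit(construct)` fact; the default threshold is 0.5 (the
midpoint of the normalised scale), overridable per construct in config.

Template rendering matches trigger patterns against closure atoms, fills
slots with the bound constants (underscores become spaces) and orders the
output by stage, template id, then arguments — byte-deterministic. Atoms of
template-bearing predicates that lack a matching template are reported
unrendered rather than dropped silently.

The reference knowledge base is negation-free: the described behaviours
(always-affective-relational advice, recessive-sector advice, personalised
sector x age-band x deficit advice, pattern comments, exercise relevance)
need only positive rules. Negation support exists for custom rule bases and
is tested separately.

## Synthetic respondents

A respondent is a latent trait in [0, 1] per subscale (five sectors, three
patterns, five awareness constructs, one interveneer scalar), an age, a
family template and an ordinal noise level. The ideal answer to a question
is the option whose inadequacy fraction is closest to the subscale trait;
noise is a rounded, clamped Gaussian on the 0–4 option scale (the simplest
ordinal-noise model with a controllable sd; logit-ordinal models are out of
scope). All randomness flows from the profile seed.

Consequences the tests rely on: with zero noise, scoring inverts simulation
exactly up to Likert quantisation — the recovered value is the trait
snapped to the 5-level grid, so the mean absolute error is bounded by half
the grid step (0.125) and rank correlations sit near but below 1 because of
grid ties. The recovery experiment (uniform traits, n = 200, noise sd 0.5)
yields rank correlations ≥ 0.9 for every subscale with its 5–21 questions.

The generator emulates *internally consistent* respondents: one trait per
subscale, independent items, symmetric noise. It does not emulate response
styles (acquiescence, central tendency), item-level difficulty variation,
correlated traits or real prevalence — so passing recovery tests
demonstrates that the scoring stack inverts its own generative model, not
that the instrument is clinically valid.

The two fixture profiles mirror the documented case presentations
qualitatively: a 37-year-old (sociocultural most recessive; adaptation 0.9
and reaction 0.8, both above the 33+ bands; creativity low; deficits in
assertiveness, self-esteem, autonomy and relationship; divorced with two
children, remarried) and a 27-year-old (same sector and pattern shape;
differentiation deficit instead of relationship; single, no children, with
a symbiotic maternal tie). The numeric trait values are this package's
choice — the source case descriptions are qualitative — fixed once here.

## Pipeline and report

`run_assessment` executes the stages in order, marks incomplete groups
pending (never fatal), pools crisp facts, runs a **single** inference pass
over the union (monotone forward chaining makes this equivalent to staged
passes for the reference rules), renders advice, assigns exercises and
attaches radar-chart exports for the sector and pattern profiles.
The report is canonical JSON (sorted keys): identical inputs and versions
give byte-identical documents, and provenance records bank version, KB
version, a 16-hex-digit SHA-256 prefix of the canonical config, and the
seed if any. A non-curative disclaimer is a mandatory field. Every
recommendation and exercise carries the closure fact that produced it,
giving a full audit chain from output to answers.

## Problem sizes and numerical choices

Default experiment sizes: 200 respondents for parameter recovery, 500
random knowledge bases (≤ 10 rules, ≤ 8 constants, ≤ 2-ary predicates) for
the closure-oracle comparison — large enough for stable statistics, small
enough that the full suite runs in seconds on one CPU. Ties in the ideal-
option search break toward the lower option index; degrees and scores are
clamped to their documented ranges; interval endpoints classify as inside.

## Known limitations

- All shipped clinical content (question texts, interval limits, thresholds,
  advice wording, exercise descriptions) is placeholder reference data, not
  validated clinical material.
- No emotional-age estimator; interval lookup uses chronological age only.
- Exercise relevance is purely rule-derived; no clustering or learning
  component is included.
- No fuzzy reasoning inside the rule engine: fuzziness is resolved to crisp
  classification facts before inference; no probabilistic reasoning or
  free-text understanding.
- The genogram supports three generations; deeper ancestries require schema
  extension.
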