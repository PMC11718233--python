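# Methods

This note documents the models, conventions and design choices behind
`keeperllm`: a pipeline that extracts standardized patient profiles
from OMOP CDM-shaped structured data, serializes them into staged
prompts, adjudicates case status through a pluggable text-completion
backend, and estimates phenotype-algorithm operating characteristics
against gold and silver standards.

## Problem setting

A *phenotype algorithm* identifies patients with a condition in coded
healthcare data (here: the first-occurrence skeleton — the earliest
event matching a concept set defines membership and the index date).
Validating such an algorithm traditionally requires manual chart
review, which is expensive and usually yields only PPV. Profile review
replaces charts with a standardized extract of structured data; pairing
it with an automated adjudicator makes it cheap enough to annotate an
over-inclusive *high-sensitivity cohort*, from which both PPV and
sensitivity of any phenotype algorithm can be estimated.

## Profile extraction

Extraction is configured per disease as a list of categories from a
closed enum (clinical presentation, disease history, preliminary
diagnosis, diagnostic procedures, differential diagnoses, treatment,
follow-up care, complications, comorbidities, risk factors). Each
category is a concept set (OHDSI expression shape, expanded through the
reflexively closed `concept_ancestor` table), a set of domains, and a
day-offset window anchored at the index date.

Window conventions, chosen once and applied everywhere:

* offsets are signed days relative to index; day 0 is the index day;
* bounds are inclusive at both ends; "within 30 days before index" is
  `[-30, 0]`;
* "at any point prior" is `(-inf, -1]` — strictly prior, so a history
  category never double-counts the index-day diagnosis, which belongs
  to presentation/preliminary-diagnosis categories.

Duplicate `(concept, date)` rows are collapsed into a single item with
an occurrence count, since claims sources repeat one line per billing
row. Measurements without a numeric result are emitted as "ordered,
result not recorded", mirroring claims sources where most laboratory
orders lack result values. Item order is deterministic: category order
as configured, then date, then concept name.

The shipped rheumatoid-arthritis and osteoporosis configurations are
**illustrative**: they exercise every mechanism against the synthetic
toy vocabulary but are not clinically validated concept sets.

## Prompt construction

Profiles are rendered into fixed display groups (e.g. disease history,
symptoms, comorbidities and risk factors merge into "Diagnoses recorded
prior to the visit"); empty groups render an explicit "none recorded"
line so the adjudicator sees the absence of evidence, not an absence of
sections. Rendering uses relative days rather than calendar dates so
prompt bytes are invariant across synthetic regenerations; calendar
rendering is a flag. No person identifier ever appears in prompt text.

The system prompt grows cumulatively over six variants: a bare yes/no
instruction (always demanding a final `Summary` section), then discuss
evidence for/against, write a clinical narrative, a reminder that a
diagnosis code alone is insufficient, guidance on handling uncertainty,
and finally a few-shot variant whose system text equals the previous
one but which prepends two worked example exchanges (one positive, one
negative, both fabricated — no simulated or real patient behind them).
Cumulative composition makes variant monotonicity (every earlier
instruction appears verbatim in later variants) true by construction.

## Backends and parsing

Backends implement `complete(messages, params) -> text` at temperature
0 with bounded exponential-backoff retries and an explicit
context-limit error. The HTTP backend speaks one neutral
chat-completions request shape (stdlib HTTP, no provider SDK); a replay
backend serves recorded transcripts byte-for-byte for offline
regression against any real model.

The **mock backend** is a deterministic rule-based adjudicator: it
parses the canonical rendering out of the main prompt and answers yes
iff at least `min_support_categories` (default 2) supporting display
groups are non-empty — prior diagnoses, treatments, post-visit care;
neither the index diagnosis itself nor bare laboratory orders count as
support — and, with the default differential veto, differential items
do not outnumber supporting items. It exists to make every downstream
stage testable offline with verdicts that move sensibly with planted
signal; it is not a model of LLM behavior, and reproducing any
published LLM's accuracy is out of scope.

Response parsing is deliberately conservative and total: the text after
the last `summary` header (case-insensitive) is scanned for whole-word
yes/no; both or neither present yields *indeterminate*, which is
interpreted as 'no' for metrics (while being tallied separately in
reports); without a summary header the final 200 characters are scanned
under the same rule. Negation phrases are not interpreted.

## Evaluation

For binary adjudicators AUC is the mean of sensitivity and specificity.
Confidence intervals are exact Clopper–Pearson by default (Wilson on
request) via `statsmodels`, with boundary cases pinned to exactly 0
and 1. Leave-one-out majority votes require a complete review block of
at least three reviewers; an even split resolves to negative (the same
conservative convention as indeterminate verdicts) and is recorded per
person. Display rounding is half-away-from-zero at one decimal for
percentages and two for AUC; machine outputs keep full precision. Note
that a printed AUC can differ by one ulp of display precision from the
mean of the *printed* rates when that mean is an exact tie (e.g.
81.9%/83.1% averaging 0.825), because displayed values are rounded from
unrounded rates.

Operating characteristics of a phenotype algorithm against a silver
standard are PPV = tp/n_flagged and sensitivity = tp/n_silver_pos with
binomial CIs; empty denominators are errors, never silent zeros.

## Synthetic populations

Real claims/EHR sources cannot be redistributed, so the generator
plants known structure in a toy vocabulary (one diagnosis root with
descendant codes plus symptom/comorbidity/treatment/differential/
laboratory concepts and an unrelated background pool):

* true cases (Bernoulli at `prevalence`) receive a descendant
  diagnosis at the index date; each symptom independently with
  probability 0.8 at 1–30 days before; each treatment with 0.8 at 0–90
  days after; each comorbidity with 0.4 at 31–1800 days before; each
  laboratory test with 0.6 around index. Planting windows align with
  the default extraction windows so extraction finds the signal.
* non-cases receive a spurious isolated diagnosis code with
  probability 0.05, and with probability 0.10 a differential diagnosis
  plus its own treatment, a shared symptom and a rule-out laboratory
  order — realistic false-positive bait for the adjudicator and
  realistic non-case entrants for the high-sensitivity cohort.
* everyone accrues Poisson(3) unrelated background events; laboratory
  orders carry a numeric result with probability 0.3, the recording
  rate typical of claims sources.

Defaults were chosen once as plausible for a sparse claims extract of a
chronic inflammatory disease; treatments may fall on the index day
itself (day-0 prescriptions are clinically real). One global seed
drives a per-person derived stream `(seed, person_id)`, so identical
parameters give byte-identical written stores and growing the
population never reshuffles existing persons. The exact selection
heuristic behind "challenging" development cases is not modelled; the
differential/spurious probabilities are the corresponding knobs.

What the generator does **not** emulate: enrollment spans and visit
structure, code churn and miscoding beyond the spurious/differential
paths, inter-annotator disagreement, and any real database's marginals.
Passing tests therefore demonstrate mechanical and statistical
correctness of the pipeline, not clinical performance on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at the sizes
the statistics need and no more: development-style evaluations at
2,000 persons; interval-coverage checks across 200 seeded replicates of
2,000 persons (background event rate lowered to 0.5 there, since
background noise does not enter cohort membership or truth labels); the
high-sensitivity demonstration samples 25,000 of ~46,000 eligible
persons from a 180,000-person population. Clopper–Pearson coverage is
checked over 2,000 seeded draws per probability at n=50. Oracle
equivalence checks use ≥1,000 randomized small instances per operation
against brute-force reimplementations (graph reachability, min-date
scans, triple filters, vote tallies, word-level parsing).

Tie-breaks are fixed and documented: same-day events order by
(domain, concept_id); first-occurrence index ties break to the smallest
concept id; high-sensitivity index is the earliest union event (the
index for non-diagnosis entrants is otherwise undefined). Degenerate
inputs fail fast: empty concept sets, inverted windows, incomplete
review matrices, roster mismatches and empty metric denominators are
all explicit errors. Run manifests deliberately contain no wall-clock
fields so reruns at a fixed seed are byte-identical.

## Known limitations

* The first-occurrence skeleton cannot express full OHDSI cohort logic
  (inclusion windows, washout, nested criteria).
* The mock adjudicator's verdicts are rule-based; sensitivity analyses
  of prompt wording against it measure plumbing, not language models.
* Planted cases are always coded, so the sensitivity of a
  diagnosis-based algorithm against planted truth is exactly 1; its CI
  coverage check is correspondingly one-sided.
* Majority-vote handling of ties follows a fixed negative convention;
  alternative tie policies are not implemented.
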