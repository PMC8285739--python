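# Methods

This note documents the model of the extraction problem, every tunable that
matters, what the synthetic corpus does and does not emulate, and the design
choices made where the design was genuinely open.

## The extraction model

A Gleason score is a triple (P, S, T): primary pattern P ∈ [3,5] (the most
prevalent histologic grade in the specimen), secondary pattern S ∈ [3,5]
(second most prevalent), total T = P + S ∈ [6,10]. Totals below 6 are
considered benign and are out of scope. When a specimen's grade composition
is known (e.g. 15% grade 3, 55% grade 4, 30% grade 5), P is the most
prevalent grade and S the second most prevalent (here P=4, S=5); a
single-grade specimen has S = P, and an exact prevalence tie is awarded to
the higher, more aggressive grade.

Extraction is deliberately rule-based: the target vocabulary is tiny, the
surface variation is finite, and every decision must be auditable for a
human reviewer. There is no trained component anywhere in the pipeline.

### Mention parsing

Mentions anchor on case-insensitive whole-token lexicon hits ("Gleason",
"GS"). Around each anchor a window of **60 characters after, then 30
before** is scanned (both truncated at a sentence boundary, period +
whitespace, and at a neighboring anchor). Those widths cover every surface
form in the supported grammars with slack for interleaved words
("Gleason score was ..."), while staying short enough that an unrelated
number two clauses away is not captured; both are keyword arguments on
`parse_components`/`extract_mentions`.

Grammar precedence is `P+S=T` > `T (P+S)` > `P+S` > labeled component >
lone total, so fully specified forms always beat partial ones. The
parenthesized form is tried before bare `P+S` because the latter is a
substring of the former. The labeled-component grammar (a qualifier
"primary"/"secondary"/"total" immediately before the anchor plus a lone
digit after it) is what makes "Primary GS was 4" parse as P=4 with S and T
absent. A lone integer is only accepted as a total when it lies in 6–10 and
is not glued to `/ % - . +` digits — this rejects dates ("7/2020"),
percentages, and hyphenated ranges ("Gleason 6-7", a documented
non-feature).

Two rules are absolute: digits are read verbatim (never clamped into
range), and derivation via P+S=T happens only when exactly two components
were read — a lone total is left incomplete rather than split into a
guessed (P, S). Validation then labels each completed triple *valid*
(in-range and consistent), *inaccurate* (out of range, or all-read with
P+S ≠ T), or *incomplete*.

### Specimen classification

Pathology notes are classified once per note, before extraction, because a
pathology report describes a single specimen; clinical notes are extracted
first and each mention classified from its own context, because one clinic
note can cite both a biopsy and a prostatectomy score.

Cues carry priority tiers (tier 1: "prostatectomy", "RRP", "RALP", "PNBx",
"needle biopsy", "core biopsy", ...; tier 2: generic terms like "biopsy",
"Bx", "pathologic stage"). For a clinical mention, cues are collected in a
window centered on the anchor with radii **150, then 500, then the whole
note** — the first radius spans a clause or two on either side, the second
a paragraph; both are config-exposed (`windows:` in the YAML config) since
no principled constants exist. The first non-empty window decides: lowest
tier wins, ties break by midpoint-to-midpoint character distance, and a
dead heat between a surgery and a biopsy cue at the same tier and distance
returns *unclassified* rather than a guess. Later windows can never
override an earlier hit.

Unclassified mentions are retained and attached to both of the patient's
tasks; if such a mention is a task's only valid evidence the task is
escalated (reason `unclassified_specimen`) — a fourth triage reason added
because silently dropping evidence would corrupt the maximum rule, and
none of the other three reasons can describe the situation.

### Triage and aggregation

The triage unit is the (patient, specimen-type) task, two per patient —
this is what makes workload and accuracy bookkeeping well-defined even for
patients with zero relevant notes (their tasks resolve to `not_found`,
uncomplicated). Reasons:

* `inaccurate` — any mention with an arithmetic/range violation;
* `incomplete` — some mention is partial **and** no valid mention supplies
  the task. The downgrade-on-redundancy rule is deliberate: clinic notes
  casually restate "Gleason 7" constantly, and escalating every such task
  would destroy the workload advantage the triage exists to provide;
* `conflicting` — two valid mentions from different notes disagree.
  Full triples are compared by default (so 3+4=7 vs 4+3=7 conflicts —
  the component order is clinically meaningful); a `totals` mode relaxes
  this to T-only comparison via config;
* `unclassified_specimen` — as above.

Aggregation takes the maximum valid mention by total T; ties break toward
the higher primary pattern (4+3 over 3+4, the more aggressive reading —
a documented convention, since either choice is defensible), then
deterministic first-seen order. Complicated tasks still carry this draft
aggregate into the work queue so the reviewer starts from the machine's
best guess.

## Synthetic corpus

The generator exists so that the full pipeline — including failure modes —
is exercisable with zero real patient data. Per patient it samples a biopsy
score (always) and a surgery score (probability 0.56, matching the cohort
prevalence of extractable surgery scores), renders them into pathology
reports and clinical notes from a YAML template bank covering all supported
grammars plus score-free distractor notes, and emits per-task gold labels.
Scores come from Dirichlet-sampled grade compositions pushed through the
composition→(P,S) rule, with the biopsy distribution skewed lower than
surgery; with probability `p_upgrade` (default 0.9) a surgery total below
the biopsy total is resampled upward, emulating pathologic upgrading. Note
volumes are Poisson with means 18.2 clinical and 3.6 pathology notes per
patient, the cohort averages the tool is sized for; the task complication
rate defaults to 4.85% with the three corruption kinds split uniformly
(only the aggregate rate is known for real cohorts).

Corruptions are injected per task, not per note: `inaccurate_sum` perturbs
a rendered total by ±1; `missing_component` rewrites the task's only
score-bearing note down to "primary Gleason pattern P" and suppresses the
task's other score notes; `cross_note_conflict` adds a second note
asserting a different valid triple. Seeding uses one master seed with
per-patient substreams (`default_rng([seed, patient_index])`), so editing
one patient's draw logic cannot cascade into another's.

What the generator does **not** emulate: real formatting noise (OCR
artifacts, tables, templated headers), section structure, negation
("no Gleason upgrade"), tertiary patterns, Grade Groups, or non-prostate
pathology. Passing the round-trip and recall suites therefore demonstrates
internal consistency of the pipeline under its own grammar assumptions —
not field accuracy on an arbitrary EHR, for which the config escape
hatches (lexicon, windows, templates) exist.

## Evaluation

NLP correctness is exact triple equality against gold (`not_found` matches
`not_found`; 4+3=7 vs 3+4=7 is an error). Three allocation strategies are
compared: human-alone, NLP-alone, and NLP-assisted (NLP on uncomplicated
tasks, human on complicated ones; the human workload fraction is the
complicated fraction). Human extraction, when not supplied, is **simulated**
with a per-stratum Bernoulli error model defaulting to 10/381 on
uncomplicated and 0/19 on complicated tasks — observed chart-review rates,
clearly a simulation and not a claim about any annotator pool.

Accuracies are printed as percentages rounded half-away-from-zero to one
decimal (95.25 → 95.3). The Fisher exact test is computed by full
hypergeometric enumeration: with margins fixed, the two-sided p-value sums
the point masses of all tables whose probability does not exceed the
observed table's, with a 1e-7 relative tolerance guarding floating-point
ties on "as extreme"; the implementation is cross-checked against an
independent library routine in the tests. Wall-clock throughput is not an
evaluation surface (hardware-dependent); the CLI reports counts and
fractions only.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 30–200 synthetic patients
(60–400 tasks, roughly 600–4400 notes), enough for the binomial
flagged-fraction check at the default rates while keeping the whole suite
fast. Extraction and evaluation are fully deterministic; the only
randomness is in corpus generation and the simulated human, both strictly
seed-driven (a seed is mandatory, never wall-clock).

## Known limitations

* The bundled lexicon is a reconstruction of standard clinical vocabulary,
  not an institution-specific expert list; real deployments should extend
  it via config.
* No section segmentation or negation handling; a cue in a "past medical
  history" list is as good as one in the assessment.
* Hyphenated score ranges and percentage-composition prose are not parsed
  from notes (composition logic exists only in the generator's gold-label
  helper).
* Temporal reasoning is out of scope: aggregation is by maximum, never by
  most recent, and same-day duplicate notes are not merged.
* Recomputed Fisher p-values depend on the exact 2×2 construction and are
  reported descriptively, not asserted against external references.
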