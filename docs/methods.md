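# Methods

This note documents the models, conventions and design choices behind
`notepheno`, in the order the pipeline applies them.

## Text normalization

Notes are tokenized by whitespace, typographic punctuation is mapped to
ASCII (curly quotes, en/em dashes, ellipses), letters are lower-cased,
and leading/trailing punctuation is stripped from each token. Tokens are
restricted to `[a-z0-9.-]`. Two clinically motivated exceptions:

- internal hyphens and periods in alphanumerics are retained ("x-ray",
  "3.5"), and slash shorthand whose parts are ≤2 characters or contain a
  digit stays one token with the slash standardized to a hyphen
  ("s/p" → `s-p`, "120/80" → `120-80`); other slashes separate tokens
  ("and/or" → `and`, `or`). This keeps clinical shorthand searchable
  while splitting ordinary alternations.
- runs of `.`/`-` collapse to a single character.

Every token records a 0-based half-open character span into the raw
text; normalizing the raw slice under a span reproduces the token (a
property-tested invariant), so any downstream artifact can be traced to
source characters.

Two parallel streams are kept per note. The *filtered* stream removes a
shipped ~25-word stop list (function words only; `of`, `with`, `for`,
negation words etc. are not in it) and is what search patterns match
against. The *full* stream keeps everything and is what contexts and cue
matching use — cue phrases like "no evidence of" contain stop words and
must stay intact. A `StopwordPolicy` carries a `protected` set that
always survives removal (negation/uncertainty words by default) and can
be extended with a library's cue vocabulary.

## Search patterns and matching

A condition's terms compile into exact-token literals, explicit roots
with prefix semantics (`delir*`), and multiword literals. The stemmer is
a deterministic pure-deletion suffix stripper (longest suffix first,
minimum remaining length 3), so `stem(x)` is always a prefix of `x`;
explicit roots are the primary mechanism and the stemmer only needs
consistency, not linguistic correctness.

Matching is greedy left-to-right with longest-match-wins
(multiword ≻ single token); after a match of length L scanning resumes
after it, so multiword matches are never double-counted. Ties between a
literal and a stem at the same position are irrelevant (both have
length 1 and produce the same instance).

Each match becomes an *instance* carrying 12 tokens of full-stream
context per side — wide enough to hold every shipped cue phrase with
margin. Instances are sorted by (patient, note, position) and serialized
as one metadata line plus a CSV table, so the intermediate database is
plain text and diffable; a corpus content hash detects staleness on
reload (a warning, not an error, since re-searching is cheap via the
relevant-note cache, which provably reproduces full-corpus results).

## Cue rules and precedence

A rule is a normalized cue token sequence with a side (`before`/`after`/
`either`), a maximum token gap to the match (default 5 — cue phrases are
adjacent in practice; 5 tolerates interleaved note-bloat text), a
category, and a scope (`general` vs `project`). Cues may contain a
`<term>` placeholder for collocation rules ("`<term>` xray").

When several rules fire the winner is chosen by, in order:

1. different-meaning placeholder rules win outright — a collocation
   redefines the entity itself;
2. smallest cue-to-match token distance;
3. longest cue;
4. category order negated ≻ under-evaluation ≻ historical ≻ acute ≻
   different-meaning (non-placeholder) — conservative, biased toward
   "absent" outcomes and hence against false-positive phenotypes;
5. lexicographically smallest rule id (a pure determinism tie-break).

Sentence boundaries are deliberately not enforced: the normalized stream
has unreliable punctuation, so the gap is the sole scope limiter. The
precedence order and gap are the two genuinely open design points here;
both are documented, deterministic, and validated against a brute-force
(rule × position) enumeration oracle in the tests.

## Review workflow

Uncategorized instances are grouped by identical context windows of
half-width k, with the matched term collapsed to `<term>` so synonyms
group together; groups are presented largest-first. The default widening
schedule is k = 3, 5, 8, 12 — short word groups first, roughly geometric
growth to minimize re-reading. Each decision labels the whole group and
is promoted to a rule: the shortest match-adjacent token run (either
side, growing length, before preferred) that does not fire on any other
pending group's window; if none distinguishes, the entire window becomes
a placeholder collocation rule with `max_gap = k`. After every decision
the grown library is re-applied to the remaining uncategorized set, so
the pending count is monotonically non-increasing — a tested invariant.

Decisions come from any callable `(group, k) → (category, scope) | None`;
the interactive prompt, scripted tables and recorded JSON-lines
transcripts all satisfy the same contract, which makes a session exactly
replayable: corpus + pattern + library + transcript determine every
output artifact byte for byte. Auto-categorization never overwrites an
already-assigned label (idempotence; manual decisions are final for the
run).

## Export semantics

Flags are per patient and condition: 1 iff at least one instance carries
a category in the configured `present_categories` — `{acute_present}`
by default (index-admission phenotype), plus `historical_chronic` for
the "ever" preset. Negated, different-meaning, under-evaluation and
(optionally) uncategorized instances map to absent; under-evaluation is
kept in the per-category support counts for auditability. Export refuses
to run with uncategorized instances unless explicitly told to map them
to absent. Screened pattern-negative patients are emitted with 0; column
order is key then conditions lexicographically, making files diffable.
Audit reports sample uniformly without replacement under a fixed seed.

## Evaluation

Sensitivity and specificity are binomial proportions; the default 95%
interval is the Wilson score interval, which is well behaved at the
boundary (k = m is common for note-extraction sensitivity). A
t-quantile normal-approximation interval (`t_normal`) is provided for
comparability with analyses built on SEM × t-quantile, and the exact
Clopper–Pearson interval as `exact`. At degenerate proportions the
mathematically exact bounds are substituted (upper = 1 when k = m,
lower = 0 when k = 0) to avoid floating-point fuzz; all bounds are
clipped to [0, 1]. A zero denominator raises rather than returning NaN.

Mean accuracy weights conditions equally (not pooled over patients):
the question it answers is accuracy "per study question", and it is the
only weighting consistent with the shipped benchmark's printed means.
`compare_means` is the pooled (equal-variance) two-sample t-test, with
Welch available via `equal_var=False`. Display rounding is two decimals.

Comparator false negatives on chronic-positive patients are tagged
`chronic_omission`; unknown chronic status yields `unreviewed` rather
than a silent guess.

## The synthetic generator

The generator emulates exactly the structure the pipeline is sensitive
to, with defaults chosen as a plausible single-admission ICU study:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 500 | typical screened-cohort order of magnitude |
| conditions | pneumonia (`pneumonia`, `pna`), delirium (`delir*`) | exercises synonyms, abbreviations and prefix roots |
| `prevalence` | 0.10 per condition | mid-range for ICU study conditions |
| `chronic_fraction` | 0.3 | minority of positives are historical |
| notes/patient | 3–7: one H&P, 1–5 progress, one discharge summary | the standard note-type inventory |
| `category_mix` | 0.45/0.20/0.15/0.10/0.10 over the five categories | positive patients mostly mention the condition affirmatively |
| `distractor_rate` | 0.4 | negatives carry occasional negated/worked-up/other-sense mentions |
| `bloat_factor` | 1.0 duplicated sentences/note | note bloat; never alters labels (separate RNG stream) |
| comparator error | fn 0.25, fp 0.07, chronic boost 0.20 | yields comparator sensitivity ≈ 1 − 0.25 − 0.3·0.2 = 0.69 and specificity ≈ 0.93, the regime of billing-code accuracy the benchmark table shows |

Every mention sentence places its cue phrase immediately adjacent to the
term, and filler sentences contain no cue words or condition terms, so
under the emitted cue inventory each instance's intended rule fires at
distance 0 and wins precedence — this is what makes exact recovery a
*construction*, not a statistical accident, and therefore a correctness
check of the whole chain. Comparator labels are gold labels flipped
independently per patient (miss probability `fn_rate` + boost if
chronic; false-alarm probability `fp_rate`), so comparator sensitivity
has the closed form 1 − fn − chronic_fraction · boost used by the
degradation check. What the generator does **not** model: misspellings,
section headers, templated review-of-systems negation lists, sentence
structure, multi-admission temporality — so passing tests certify the
machinery, not clinical-grade NLP performance.

## Problem sizes and numerical checks

The test suite and reproduction script use 60–500 patients for workflow
and recovery checks, 2,000 patients for the comparator-degradation
experiment (prevalence 0.25 there, giving ~1,000 gold positives so the
simulated sensitivity estimate has standard error ≈ 0.015 against its
±0.04 check band), and 2,000 replications at cohort size 150 for Wilson
coverage (exact binomial enumeration puts true coverage at 0.959/0.960/
0.968 for p = 0.5/0.9/0.98 with m = 150, inside the 93–97% band the
simulation asserts). All stochastic tests fix their seeds; the
reproduction script derives every stream from its `--seed` argument.

## Known limitations

- The default stop list and punctuation table are package choices; no
  standard list exists for clinical text, so both are small, shipped in
  the repo, and overridable.
- Cue side/gap semantics are approximations of linguistic scope; clear
  misclassifications are expected on real text and are exactly what the
  audit reports and review loop are for.
- The chronic-omission tag depends on an externally supplied
  chronic-status indicator; the package does not infer chronicity from
  text beyond the historical/chronic mention category.
- Per-condition confidence intervals from different sources can overlap
  while a paired analysis would still separate them; the t-test operates
  on per-condition point estimates and ignores within-condition
  sampling error.
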