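# notepheno

Rule-based phenotyping of free-text clinical notes: find every mention of
a condition in a note corpus, decide what each mention *means* in its
context, and turn the result into an analysis-ready dataset of
per-patient binary flags — with every flag traceable back to the exact
note text and rule that produced it.

## The problem

Most of the clinically rich content of an electronic medical record lives
in unstructured free text (history & physical exams, daily progress
notes, discharge summaries). Researchers who need a cohort — "all
patients with endocarditis", "everyone who had a pulmonary embolism this
admission" — usually fall back on administrative ICD codes, which are
assigned for billing, routinely omit chronic conditions, and miss
research-relevant cases. A mention of "pneumonia" in a note, on the
other hand, can mean five different things:

1. **acutely present** this admission ("admitted with pneumonia"),
2. **historical/chronic** ("history of pneumonia"),
3. **negated** ("no evidence of pneumonia"),
4. **under evaluation** ("suspected pneumonia"),
5. **a different sense of the term** ("decubitus xray" is an imaging
   view, not an ulcer; "lupus anticoagulant" is an antibody, not the
   disease).

`notepheno` implements the transparent, auditable alternative to both
manual chart review and black-box language models: a searchable
intermediate database of every mention with its context, a growing
cue-phrase library that classifies mentions automatically, a
keyword-in-context review workflow for whatever the library cannot yet
resolve, and a validation arm that scores any labeling source against a
gold standard.

## How it works

1. **search** — a condition is compiled into a pattern of exact-token
   synonyms ("pneumonia", "pna"), explicit roots with prefix semantics
   ("delir\*" covers delirium and delirious) and multiword literals
   ("central cord syndrome"). Notes are normalized (lower-case,
   punctuation standardized, stop words removed from the search stream
   only), and every non-overlapping longest match is stored with a
   12-token context window on each side. The set of relevant notes is
   cached, so re-searches touch only notes that can match.
2. **categorize** — each mention's context is scanned for cue phrases
   from the rule library. When several rules fire, the most specific
   wins: collocation rules that redefine the term itself ("⟨term⟩ xray")
   beat everything, then smallest cue-to-match distance, longest cue,
   and a conservative category order (negated ≻ under evaluation ≻
   historical ≻ acute).
3. **review** — remaining mentions are grouped by identical short
   context windows ("3 words before + term + 3 after"), largest group
   first, so one decision retires many mentions; windows widen on a
   schedule when short contexts are ambiguous. Every decision becomes a
   new library rule, project-scoped or general.
4. **export** — categories collapse to one 0/1 flag per patient and
   condition (by default only *acutely present* counts; an `--ever`
   preset adds *historical/chronic*; negated/ambiguous/different-sense
   map to absent). Screened but unmatched patients are emitted with 0 —
   they are the true-negative denominator.
5. **evaluate** — sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP)
   against a gold standard, with Wilson score 95% intervals (well
   behaved near 1, where note extraction lives), condition-weighted mean
   accuracies with SEM, pooled two-sample t-tests between two labeling
   sources, and a per-condition tally of *chronic omissions* —
   comparator false negatives caused by coders skipping chronic
   conditions.

A synthetic-corpus generator (`notepheno.synthgen`) produces multi-note
patients with known per-patient condition status, per-mention category,
note bloat and a configurable ICD-style comparator error model, so the
entire pipeline is testable without restricted clinical data.

## Worked example

```python
from notepheno import (
    SimConfig, generate, find_instances, compile_pattern,
    categorize_corpus, aggregate_patients, confusion, sens_spec,
)
from notepheno.reports_export import EVER_CONFIG, phenotype_frame, flags_from_frame

sim = generate(SimConfig(n_patients=300, seed=7), "study")

db = find_instances(sim.corpus, compile_pattern("pneumonia", ["pneumonia", "pna"]))
print(f"{len(db.instances)} mentions in {len(db.relevant_note_ids)} of {len(sim.corpus)} notes")

db, uncategorized = categorize_corpus(db, sim.library)
print(f"{len(uncategorized)} mentions left uncategorized")

flags = phenotype_frame(aggregate_patients(db, EVER_CONFIG, sim.patient_ids))
c = confusion(flags_from_frame(flags, "pneumonia"), sim.gold["pneumonia"])
sens, spec = sens_spec(c)
print(f"n={c.n}  tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}")
print(sens)
print(spec)
```

prints

```
181 mentions in 146 of 1510 notes
0 mentions left uncategorized
n=300  tp=26 fp=0 fn=0 tn=274
sensitivity=1.00 (0.87-1.00, 95% wilson)
specificity=1.00 (0.99-1.00, 95% wilson)
```

— the search found 181 mentions of "pneumonia"/"pna" across 146 notes,
the cue library classified all of them, and the exported patient flags
recover the generator's gold labels exactly (26 true positives, no
errors; the Wilson interval on 26/26 sensitivity still spans down to
0.87, a reminder of small-denominator uncertainty).

The same pipeline is available from the shell:

```
notepheno simulate --out study --seed 7 --n-patients 300
notepheno search --notes study/notes.csv --condition pneumonia \
    --terms "pneumonia,pna" --out db.csv
notepheno categorize --db db.csv --library study/cue_library.csv --out db.csv
notepheno export --db db.csv --notes study/notes.csv --ever --out flags.csv
notepheno eval --pred flags.csv --gold study/gold.csv
```

The evaluation arm also ships a per-condition accuracy benchmark
comparing ICD-9 codes and note extraction against chart review for 11
ICU conditions:

```python
from notepheno.benchmark import benchmark_table
from notepheno.evaluate import mean_accuracy, compare_means

t = benchmark_table()
icd = mean_accuracy(t["icd9_sensitivity"]); note = mean_accuracy(t["note_sensitivity"])
tstat, p = compare_means(t["icd9_sensitivity"], t["note_sensitivity"])
print(f"ICD-9 mean sensitivity  {icd.mean:.2f} (SEM {icd.sem:.3f})")
print(f"note  mean sensitivity  {note.mean:.2f} (SEM {note.sem:.3f})")
print(f"pooled t = {tstat:.2f}, two-sided p = {p:.4f}")
```

```
ICD-9 mean sensitivity  0.65 (SEM 0.076)
note  mean sensitivity  0.98 (SEM 0.010)
pooled t = -4.25, two-sided p = 0.0004
```

Billing codes miss a third of gold-positive patients on average; note
extraction misses 2%.

## Limitations

- Cue scope is a token-distance window, not sentence- or section-aware;
  no termination-token semantics (a deliberate simplification — the
  review workflow exists precisely to patch local misreadings).
- The synthetic generator validates mechanics, not linguistics: real
  notes have misspellings, section headers, templated negation lists and
  ambiguity the generator does not model, so perfect recovery there is a
  correctness check, not a clinical performance claim.
- No concept normalization (UMLS/SNOMED) and no de-identification;
  corpora are assumed already de-identified.
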