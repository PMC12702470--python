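"""Synthetic note corpora with known ground truth.

Real critical-care note corpora are access-restricted, so the pipeline is
validated on generated ones. The generator emulates the statistical
structure that matters to rule-based phenotyping — multi-note admissions
(history & physical, daily progress notes, discharge summary),
configurable condition prevalence, mentions in all five meaning
categories introduced by cue phrases from a declared inventory, synonyms
and abbreviations ("pna" for pneumonia) and explicit roots ("delir*" for
delirium/delirious), note bloat through duplicated sentences, and an
ICD-style comparator labeling derived from the gold labels by seeded
error flips with an extra false-negative boost for chronic conditions —
while making no attempt at realistic clinical language.

Everything is driven by one seed: the same configuration always produces
byte-identical output files. The truth log records every embedded
mention with its intended category and cue, and the cue inventory is
emitted as a ready-to-use rule library, so a search + categorize +
export run over the generated corpus can be scored against a perfectly
known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from notepheno import corpus_io
from notepheno.context_library import (
    PLACEHOLDER,
    CategoryLabel,
    PhraseRule,
    RuleLibrary,
    save_library,
)
from notepheno.corpus_io import NoteRecord
from notepheno.errors import ConfigurationError

# Mention sentence templates per category: (cue as stored in the emitted
# rule inventory, sentence template). The cue phrase is always adjacent
# to the term so the intended rule fires at distance zero.
_CUE_TEMPLATES: dict[CategoryLabel, list[tuple[str, str, str]]] = {
    # (cue, side, sentence template)
    CategoryLabel.ACUTE_PRESENT: [
        ("admitted with", "before", "admitted with {term}"),
        ("currently with", "before", "currently with {term}"),
        ("chief complaint", "before", "chief complaint {term}"),
    ],
    CategoryLabel.HISTORICAL_CHRONIC: [
        ("history of", "before", "history of {term}"),
        ("previous hospitalization for", "before", "previous hospitalization for {term}"),
    ],
    CategoryLabel.NEGATED: [
        ("no evidence of", "before", "no evidence of {term}"),
        ("negative for", "before", "negative for {term}"),
        ("without", "before", "exam without {term}"),
    ],
    CategoryLabel.UNDER_EVALUATION: [
        ("may have", "before", "patient may have {term}"),
        ("suspected", "before", "suspected {term}"),
        ("assessment for", "before", "assessment for {term}"),
    ],
    CategoryLabel.DIFFERENT_MEANING: [
        (f"{PLACEHOLDER} xray", "either", "{term} xray obtained"),
        (f"joint {PLACEHOLDER}", "either", "joint {term} performed"),
    ],
}

# Neutral filler sentences: contain no cue words and none of the default
# condition terms, so they can never trigger a rule near a mention.
_FILLERS = (
    "vital signs stable overnight",
    "continue current plan of care",
    "labs reviewed this morning",
    "family at bedside today",
    "tolerating diet well",
    "ambulating in hallway",
    "pain well controlled",
    "electrolytes repleted",
    "remains afebrile",
    "wound care performed daily",
    "physical therapy consulted",
    "social work following",
    "medication list reconciled",
    "overnight events reviewed",
)

_DISTRACTOR_CATEGORIES = (
    CategoryLabel.NEGATED,
    CategoryLabel.UNDER_EVALUATION,
    CategoryLabel.DIFFERENT_MEANING,
)


@dataclass(frozen=True)
class ConditionSpec:
    """One simulated condition: its search terms and epidemiology."""

    name: str
    terms: tuple[str, ...]  # search-spec terms; "*" marks explicit roots
    surface_forms: tuple[str, ...] = ()  # words actually written in notes
    prevalence: float = 0.10
    chronic_fraction: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(
                f"condition {self.name!r}: prevalence must be in (0, 1)"
            )
        if not 0.0 <= self.chronic_fraction <= 1.0:
            raise ConfigurationError(
                f"condition {self.name!r}: chronic_fraction must be in [0, 1]"
            )
        if not self.terms:
            raise ConfigurationError(f"condition {self.name!r}: no terms")
        if not self.surface_forms:
            object.__setattr__(
                self, "surface_forms",
                tuple(t.rstrip("*") for t in self.terms),
            )


@dataclass(frozen=True)
class ComparatorError:
    """Error model for the simulated ICD-style comparator labeling."""

    fn_rate: float = 0.25
    fp_rate: float = 0.07
    chronic_fn_boost: float = 0.20

    def __post_init__(self):
        for name in ("fn_rate", "fp_rate", "chronic_fn_boost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"comparator_error.{name} must be in [0, 1]")


def default_conditions() -> tuple[ConditionSpec, ConditionSpec]:
    """Two stock conditions exercising synonyms, abbreviations and roots."""
    return (
        ConditionSpec(
            name="pneumonia",
            terms=("pneumonia", "pna"),
            surface_forms=("pneumonia", "pna"),
        ),
        ConditionSpec(
            name="delirium",
            terms=("delir*",),
            surface_forms=("delirium", "delirious"),
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated study corpus."""

    n_patients: int = 500
    conditions: tuple[ConditionSpec, ...] = field(default_factory=default_conditions)
    notes_per_patient: tuple[int, int] = (3, 7)
    #: category probabilities for extra mentions in gold-positive patients
    category_mix: tuple[float, float, float, float, float] = (0.45, 0.20, 0.15, 0.10, 0.10)
    #: expected distractor mentions per condition in gold-negative patients
    distractor_rate: float = 0.4
    #: expected extra mentions per condition in gold-positive patients
    extra_mentions_mean: float = 1.5
    #: expected duplicated sentences appended per note (note bloat)
    bloat_factor: float = 1.0
    comparator_error: ComparatorError = field(default_factory=ComparatorError)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise ConfigurationError("notes_per_patient must be a valid (lo, hi) range")
        if abs(sum(self.category_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.category_mix):
            raise ConfigurationError("category_mix must be non-negative and sum to 1")
        for name in ("distractor_rate", "bloat_factor", "extra_mentions_mean"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ConfigurationError("condition names must be unique")


_MIX_ORDER = (
    CategoryLabel.ACUTE_PRESENT,
    CategoryLabel.HISTORICAL_CHRONIC,
    CategoryLabel.NEGATED,
    CategoryLabel.UNDER_EVALUATION,
    CategoryLabel.DIFFERENT_MEANING,
)


def cue_inventory(conditions: Sequence[ConditionSpec] | None = None) -> RuleLibrary:
    """The rule library matching every cue the generator can emit."""
    rules = []
    n = 0
    for cat in _MIX_ORDER:
        for cue, side, _ in _CUE_TEMPLATES[cat]:
            rules.append(
                PhraseRule(
                    rule_id=f"c{n:04d}",
                    cue=tuple(cue.split()),
                    side=side,
                    max_gap=5,
                    category=cat,
                    source="general",
                )
            )
            n += 1
    return RuleLibrary(rules=rules)


@dataclass
class SimResult:
    """Everything a generated study corpus consists of."""

    config: SimConfig
    corpus: list[NoteRecord]
    #: condition name -> patient id -> 0/1
    gold: dict[str, dict[str, int]]
    comparator: dict[str, dict[str, int]]
    chronic: dict[str, dict[str, int]]
    truth: list[dict]
    library: RuleLibrary
    notes_path: Optional[Path] = None
    gold_path: Optional[Path] = None
    comparator_path: Optional[Path] = None
    chronic_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    library_path: Optional[Path] = None

    @property
    def patient_ids(self) -> list[str]:
        return sorted({n.patient_id for n in self.corpus})


def _flags_frame(flags: dict[str, dict[str, int]], patients: list[str]) -> pd.DataFrame:
    cols = sorted(flags)
    rows = [
        {"patient_id": pid, **{c: flags[c][pid] for c in cols}} for pid in patients
    ]
    return pd.DataFrame(rows, columns=["patient_id", *cols])


def generate(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate a synthetic corpus with its labels, truth log and library.

    If ``outdir`` is given, all artifacts are written there as plain text
    (notes.csv, gold.csv, comparator.csv, chronic.csv, truth.jsonl,
    cue_library.csv). Output is fully determined by ``cfg`` including its
    seed.
    """
    # independent streams: bloat must never perturb the label/mention draws
    rng, rng_bloat = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    n_fill = len(_FILLERS)
    gold: dict[str, dict[str, int]] = {c.name: {} for c in cfg.conditions}
    comparator: dict[str, dict[str, int]] = {c.name: {} for c in cfg.conditions}
    chronic: dict[str, dict[str, int]] = {c.name: {} for c in cfg.conditions}
    truth: list[dict] = []
    corpus: list[NoteRecord] = []
    lo, hi = cfg.notes_per_patient
    err = cfg.comparator_error

    for p in range(cfg.n_patients):
        pid = f"P{p:05d}"
        n_notes = int(rng.integers(lo, hi + 1))
        note_types = (
            ["history_physical"]
            + ["progress"] * max(0, n_notes - 2)
            + (["discharge_summary"] if n_notes > 1 else [])
        )
        # base filler sentences per note
        sentences: list[list[str]] = [
            [_FILLERS[j] for j in rng.integers(0, n_fill, size=int(rng.integers(3, 7)))]
            for _ in range(n_notes)
        ]
        note_ids = [f"{pid}-N{j}" for j in range(n_notes)]

        def place_mention(cond: ConditionSpec, category: CategoryLabel, note_idx: int) -> None:
            term = cond.surface_forms[int(rng.integers(0, len(cond.surface_forms)))]
            tpls = _CUE_TEMPLATES[category]
            cue, _, tpl = tpls[int(rng.integers(0, len(tpls)))]
            sent = tpl.format(term=term)
            pos = int(rng.integers(0, len(sentences[note_idx]) + 1))
            sentences[note_idx].insert(pos, sent)
            truth.append(
                {
                    "patient_id": pid,
                    "note_id": note_ids[note_idx],
                    "condition": cond.name,
                    "term": term,
                    "category": category.value,
                    "cue": cue,
                }
            )

        for cond in cfg.conditions:
            is_pos = bool(rng.random() < cond.prevalence)
            gold[cond.name][pid] = int(is_pos)
            is_chronic = bool(is_pos and rng.random() < cond.chronic_fraction)
            chronic[cond.name][pid] = int(is_chronic)
            if is_pos:
                # guaranteed defining mention in the H&P or discharge summary
                anchor = 0 if (n_notes == 1 or rng.random() < 0.5) else n_notes - 1
                primary = (
                    CategoryLabel.HISTORICAL_CHRONIC
                    if is_chronic
                    else CategoryLabel.ACUTE_PRESENT
                )
                place_mention(cond, primary, anchor)
                for _ in range(int(rng.poisson(cfg.extra_mentions_mean))):
                    cat = _MIX_ORDER[
                        int(rng.choice(len(_MIX_ORDER), p=cfg.category_mix))
                    ]
                    place_mention(cond, cat, int(rng.integers(0, n_notes)))
            else:
                for _ in range(int(rng.poisson(cfg.distractor_rate))):
                    cat = _DISTRACTOR_CATEGORIES[
                        int(rng.integers(0, len(_DISTRACTOR_CATEGORIES)))
                    ]
                    place_mention(cond, cat, int(rng.integers(0, n_notes)))
            # comparator flips: chronic positives get the extra miss rate
            if is_pos:
                miss = err.fn_rate + (err.chronic_fn_boost if is_chronic else 0.0)
                comparator[cond.name][pid] = int(rng.random() >= miss)
            else:
                comparator[cond.name][pid] = int(rng.random() < err.fp_rate)

        # note bloat: duplicate existing sentences (never changes the truth;
        # drawn from its own stream so bloat_factor cannot perturb labels)
        for j in range(n_notes):
            for _ in range(int(rng_bloat.poisson(cfg.bloat_factor))):
                src = int(rng_bloat.integers(0, len(sentences[j])))
                sentences[j].append(sentences[j][src])

        for j in range(n_notes):
            text = ". ".join(sentences[j]) + "."
            corpus.append(
                NoteRecord.build(
                    patient_id=pid,
                    note_id=note_ids[j],
                    raw_text=text,
                    note_type=note_types[j],
                    chart_time=f"2101-01-{(j % 28) + 1:02d}T08:00:00",
                )
            )

    result = SimResult(
        config=cfg,
        corpus=corpus,
        gold=gold,
        comparator=comparator,
        chronic=chronic,
        truth=truth,
        library=cue_inventory(cfg.conditions),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        patients = result.patient_ids
        result.notes_path = outdir / "notes.csv"
        corpus_io.write_notes(corpus, result.notes_path)
        for name, flags in (
            ("gold", gold), ("comparator", comparator), ("chronic", chronic),
        ):
            path = outdir / f"{name}.csv"
            _flags_frame(flags, patients).to_csv(path, index=False, lineterminator="\n")
            setattr(result, f"{name}_path", path)
        result.truth_path = outdir / "truth.jsonl"
        with open(result.truth_path, "w", encoding="utf-8") as fh:
            for rec in truth:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        result.library_path = outdir / "cue_library.csv"
        save_library(result.library, result.library_path)
    return result
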