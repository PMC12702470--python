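"""The cue-phrase rule library: what a mention means in its context.

Every located mention of a condition term is assigned one of five meaning
categories by scanning its surrounding tokens for cue phrases:

1. ``ACUTE_PRESENT``      — condition acutely present this admission
   ("currently with", "admitted with", "chief complaint");
2. ``HISTORICAL_CHRONIC`` — history of / chronic condition
   ("history of", "previous hospitalization for", "as a child");
3. ``NEGATED``            — explicitly absent
   ("no evidence of", "negative for", "doubt", "without");
4. ``UNDER_EVALUATION``   — being worked up
   ("may have", "suspected", "assessment for");
5. ``DIFFERENT_MEANING``  — the term means something else here
   ("decubitus xray" is a radiographic position, not an ulcer;
   "lupus anticoagulant" is a lab antibody, not the disease).

The library is a persistent, append-mostly knowledge base: it ships with a
starter set of general-purpose cues and grows with every review session.
Rules may contain the placeholder token ``<term>`` standing for the
matched term itself, which expresses collocation rules like
``<term> xray``.

Precedence when several rules fire on one mention (most specific wins,
biased against false positives):

1. ``DIFFERENT_MEANING`` placeholder rules win outright — a collocation
   redefines the entity itself;
2. smallest token distance between cue and match;
3. longest cue;
4. category order NEGATED > UNDER_EVALUATION > HISTORICAL_CHRONIC >
   ACUTE_PRESENT > DIFFERENT_MEANING (non-placeholder);
5. lexicographically smallest rule id.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import TYPE_CHECKING, Optional

from notepheno.corpus_io import tokenize
from notepheno.errors import FormatError

if TYPE_CHECKING:  # pragma: no cover
    from notepheno.search import Instance

#: placeholder token standing for the matched term inside a cue
PLACEHOLDER = "<term>"


class CategoryLabel(str, enum.Enum):
    """The five meaning categories plus the unresolved state."""

    ACUTE_PRESENT = "acute_present"
    HISTORICAL_CHRONIC = "historical_chronic"
    NEGATED = "negated"
    UNDER_EVALUATION = "under_evaluation"
    DIFFERENT_MEANING = "different_meaning"
    UNCATEGORIZED = "uncategorized"


#: the five assignable categories (everything except UNCATEGORIZED)
ASSIGNABLE = tuple(c for c in CategoryLabel if c is not CategoryLabel.UNCATEGORIZED)

# rank used at precedence step 4; lower wins (conservative ordering)
_CATEGORY_RANK = {
    CategoryLabel.NEGATED: 0,
    CategoryLabel.UNDER_EVALUATION: 1,
    CategoryLabel.HISTORICAL_CHRONIC: 2,
    CategoryLabel.ACUTE_PRESENT: 3,
    CategoryLabel.DIFFERENT_MEANING: 4,
}


def _parse_cue(text: str) -> tuple[str, ...]:
    """Normalize a cue string to its token sequence, preserving ``<term>``."""
    out: list[str] = []
    for word in text.split():
        if word == PLACEHOLDER:
            out.append(PLACEHOLDER)
        else:
            out.extend(tok for tok, _ in tokenize(word))
    return tuple(out)


@dataclass(frozen=True)
class PhraseRule:
    """One cue phrase mapped to a category.

    ``side`` locates the cue relative to the match (ignored for placeholder
    rules, whose position is fixed by ``<term>`` itself); ``max_gap`` is
    the maximum number of tokens allowed between cue and match.
    """

    rule_id: str
    cue: tuple[str, ...]
    category: CategoryLabel
    side: str = "before"  # before | after | either
    max_gap: int = 5
    source: str = "general"  # general | project
    created_from: Optional[str] = None

    def __post_init__(self):
        if not self.cue:
            raise FormatError(f"rule {self.rule_id!r}: empty cue")
        if sum(1 for t in self.cue if t == PLACEHOLDER) > 1:
            raise FormatError(f"rule {self.rule_id!r}: more than one placeholder")
        if self.max_gap < 0:
            raise FormatError(f"rule {self.rule_id!r}: negative max_gap")
        if self.side not in ("before", "after", "either"):
            raise FormatError(f"rule {self.rule_id!r}: bad side {self.side!r}")
        if self.category is CategoryLabel.UNCATEGORIZED:
            raise FormatError(f"rule {self.rule_id!r}: category may not be uncategorized")

    @property
    def has_placeholder(self) -> bool:
        return PLACEHOLDER in self.cue

    @property
    def signature(self) -> tuple:
        """Duplicate-detection key: same cue, side, gap and category."""
        return (self.cue, self.side, self.max_gap, self.category)


@dataclass
class RuleLibrary:
    """A collection of phrase rules with an append-only provenance log."""

    rules: list[PhraseRule] = field(default_factory=list)
    version: str = "1"
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate rule ids: {dupes}")

    def __len__(self) -> int:
        return len(self.rules)

    def _log(self, rule_id: str, action: str, project: Optional[str]) -> None:
        self.provenance.append(
            {
                "rule_id": rule_id,
                "action": action,
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "project": project,
            }
        )

    def add(self, rule: PhraseRule, project: Optional[str] = None) -> bool:
        """Insert ``rule``; duplicate signatures are logged no-ops.

        Returns True if the rule was actually added.
        """
        sigs = {r.signature for r in self.rules}
        if rule.signature in sigs:
            self._log(rule.rule_id, "duplicate-noop", project)
            return False
        if any(r.rule_id == rule.rule_id for r in self.rules):
            raise FormatError(f"rule id {rule.rule_id!r} already present")
        self.rules.append(rule)
        self._log(rule.rule_id, "add", project)
        return True

    def next_rule_id(self, prefix: str = "r") -> str:
        existing = {r.rule_id for r in self.rules}
        n = len(self.rules)
        while f"{prefix}{n:04d}" in existing:
            n += 1
        return f"{prefix}{n:04d}"


# ---------------------------------------------------------------------------
# persistence

_COLUMNS = ("rule_id", "cue", "side", "max_gap", "category", "source", "created_from")


def save_library(lib: RuleLibrary, path: str | Path) -> None:
    """Write the library as delimited text, one rule per row."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in lib.rules:
            writer.writerow(
                [
                    r.rule_id,
                    " ".join(r.cue),
                    r.side,
                    r.max_gap,
                    r.category.value,
                    r.source,
                    r.created_from or "",
                ]
            )


def load_library(path: str | Path) -> RuleLibrary:
    """Read a library file, validating every rule."""
    rules: list[PhraseRule] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                category = CategoryLabel(row["category"])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: unknown category {row['category']!r}"
                ) from None
            try:
                rule = PhraseRule(
                    rule_id=row["rule_id"],
                    cue=_parse_cue(row["cue"]),
                    side=row["side"] or "before",
                    max_gap=int(row["max_gap"]),
                    category=category,
                    source=row["source"] or "general",
                    created_from=row["created_from"] or None,
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            rules.append(rule)
    return RuleLibrary(rules=rules)


_STARTER = [
    # (cue, side, category)
    ("currently with", "before", CategoryLabel.ACUTE_PRESENT),
    ("admitted with", "before", CategoryLabel.ACUTE_PRESENT),
    ("chief complaint", "before", CategoryLabel.ACUTE_PRESENT),
    ("history of", "before", CategoryLabel.HISTORICAL_CHRONIC),
    ("previous hospitalization for", "before", CategoryLabel.HISTORICAL_CHRONIC),
    ("as a child", "after", CategoryLabel.HISTORICAL_CHRONIC),
    ("no evidence of", "before", CategoryLabel.NEGATED),
    ("negative for", "before", CategoryLabel.NEGATED),
    ("doubt", "before", CategoryLabel.NEGATED),
    ("without", "before", CategoryLabel.NEGATED),
    ("may have", "before", CategoryLabel.UNDER_EVALUATION),
    ("suspected", "before", CategoryLabel.UNDER_EVALUATION),
    ("assessment for", "before", CategoryLabel.UNDER_EVALUATION),
    (f"{PLACEHOLDER} xray", "either", CategoryLabel.DIFFERENT_MEANING),
    (f"{PLACEHOLDER} anticoagulant", "either", CategoryLabel.DIFFERENT_MEANING),
    (f"joint {PLACEHOLDER}", "either", CategoryLabel.DIFFERENT_MEANING),
]


def starter_library() -> RuleLibrary:
    """The shipped general-purpose starter library (16 rules)."""
    rules = [
        PhraseRule(
            rule_id=f"g{n:04d}",
            cue=_parse_cue(cue),
            side=side,
            category=cat,
            max_gap=5,
            source="general",
        )
        for n, (cue, side, cat) in enumerate(_STARTER)
    ]
    return RuleLibrary(rules=rules)


def cue_vocabulary(lib: RuleLibrary) -> frozenset[str]:
    """All non-placeholder words used in the library's cues (used to
    protect them from stop-word removal)."""
    return frozenset(t for r in lib.rules for t in r.cue if t != PLACEHOLDER)


# ---------------------------------------------------------------------------
# matching


def _find_subseq(hay: tuple[str, ...], needle: tuple[str, ...]) -> list[int]:
    """All start indices where ``needle`` occurs contiguously in ``hay``."""
    n, m = len(hay), len(needle)
    return [i for i in range(n - m + 1) if hay[i : i + m] == needle]


def rule_hits(rule: PhraseRule, left: tuple[str, ...], right: tuple[str, ...]) -> list[int]:
    """Distances at which ``rule`` fires for a match with the given
    left/right context token streams. Empty list = no fire.

    For ordinary rules the distance is the token count between the cue and
    the match on the permitted side. Placeholder rules match the window
    with the term collapsed to ``<term>``; their distance is 0.
    """
    if rule.has_placeholder:
        window = left + (PLACEHOLDER,) + right
        return [0] if _find_subseq(window, rule.cue) else []
    dists: list[int] = []
    m = len(rule.cue)
    if rule.side in ("before", "either"):
        for i in _find_subseq(left, rule.cue):
            gap = len(left) - (i + m)
            if gap <= rule.max_gap:
                dists.append(gap)
    if rule.side in ("after", "either"):
        for i in _find_subseq(right, rule.cue):
            if i <= rule.max_gap:
                dists.append(i)
    return dists


def match_rules(
    instance: "Instance", lib: RuleLibrary
) -> Optional[tuple[PhraseRule, CategoryLabel]]:
    """Best-matching rule for an instance, or ``None`` if no rule fires.

    Applies the precedence order documented in the module docstring.
    """
    left = tuple(instance.left_context)
    right = tuple(instance.right_context)
    best_key = None
    best: Optional[PhraseRule] = None
    for rule in lib.rules:
        dists = rule_hits(rule, left, right)
        if not dists:
            continue
        dm_placeholder = rule.has_placeholder and rule.category is CategoryLabel.DIFFERENT_MEANING
        key = (
            0 if dm_placeholder else 1,
            min(dists),
            -len(rule.cue),
            _CATEGORY_RANK[rule.category],
            rule.rule_id,
        )
        if best_key is None or key < best_key:
            best_key, best = key, rule
    if best is None:
        return None
    return best, best.category
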