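"""Categorization and the expanding-context review workflow.

After the search stage every mention is ``UNCATEGORIZED``. This module
first auto-categorizes everything the rule library already knows, then
drives the keyword-in-context review of the remainder: uncategorized
mentions sharing an identical context window of half-width *k* are
collapsed into one :class:`ReviewGroup`, the reviewer decides a category
per group (largest groups first, so one decision retires many mentions),
the window widens on a schedule when short contexts are ambiguous, and
every decision is promoted to a new library rule — so the library, and
with it the fraction of future searches resolved automatically, grows
with each project.

Decision sources are plain callables ``(group, k) -> (category, scope) |
None`` (None = abstain), so scripted transcripts, tests and an
interactive prompt all drive the identical engine, and a recorded
transcript replays to bit-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from notepheno.context_library import (
    ASSIGNABLE,
    PLACEHOLDER,
    CategoryLabel,
    PhraseRule,
    RuleLibrary,
    match_rules,
    rule_hits,
)
from notepheno.search import Instance, IntermediateDB

#: default expanding window schedule: short word groups first
DEFAULT_K_SCHEDULE = (3, 5, 8, 12)

DecisionSource = Callable[["ReviewGroup", int], Optional[tuple[CategoryLabel, str]]]


def categorize_corpus(
    db: IntermediateDB, lib: RuleLibrary
) -> tuple[IntermediateDB, list[str]]:
    """Auto-categorize every uncategorized instance the library can resolve.

    Instances that already carry a category are left untouched (manual
    decisions are never overwritten), which also makes the operation
    idempotent. Returns the database and the ids still uncategorized.
    """
    for inst in db.instances:
        if inst.category is not CategoryLabel.UNCATEGORIZED:
            continue
        hit = match_rules(inst, lib)
        if hit is not None:
            rule, category = hit
            inst.category = category
            inst.fired_rule_id = rule.rule_id
    return db, db.uncategorized_ids()


@dataclass
class ReviewGroup:
    """Uncategorized instances sharing one context window of half-width k.

    The matched term is collapsed to the ``<term>`` placeholder in the key
    so that synonym and abbreviation variants group together.
    """

    context_key: tuple[str, ...]
    member_instance_ids: frozenset[str]
    k: int

    @property
    def size(self) -> int:
        return len(self.member_instance_ids)

    def display(self) -> str:
        return " ".join(self.context_key)

    def split_key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(left tokens, right tokens) around the placeholder."""
        i = self.context_key.index(PLACEHOLDER)
        return self.context_key[:i], self.context_key[i + 1 :]


def _window_key(inst: Instance, k: int) -> tuple[str, ...]:
    left = tuple(inst.left_context[-k:]) if k else ()
    right = tuple(inst.right_context[:k]) if k else ()
    return left + (PLACEHOLDER,) + right


def review_groups(instances: Sequence[Instance], k: int) -> list[ReviewGroup]:
    """Partition uncategorized instances by identical k-window, largest first."""
    if k < 1:
        raise ValueError(f"window half-width must be >= 1, got {k}")
    buckets: dict[tuple[str, ...], set[str]] = {}
    for inst in instances:
        if inst.category is not CategoryLabel.UNCATEGORIZED:
            continue
        buckets.setdefault(_window_key(inst, k), set()).add(inst.instance_id)
    groups = [
        ReviewGroup(context_key=key, member_instance_ids=frozenset(ids), k=k)
        for key, ids in buckets.items()
    ]
    groups.sort(key=lambda g: (-g.size, g.context_key))
    return groups


def _derive_rule(
    group: ReviewGroup,
    category: CategoryLabel,
    scope: str,
    lib: RuleLibrary,
    other_keys: Iterable[tuple[tuple[str, ...], tuple[str, ...]]],
    condition_name: Optional[str],
) -> PhraseRule:
    """Promote a review decision to the smallest cue that still
    distinguishes this group from every other pending group.

    Candidates are the match-adjacent token runs of growing length on
    either side; if none is distinguishing, the full context window
    becomes a placeholder collocation rule.
    """
    left, right = group.split_key()
    others = list(other_keys)
    candidates: list[tuple[int, int, tuple[str, ...], str]] = []
    for L in range(1, len(left) + 1):
        candidates.append((L, 0, tuple(left[-L:]), "before"))
    for L in range(1, len(right) + 1):
        candidates.append((L, 1, tuple(right[:L]), "after"))
    candidates.sort(key=lambda c: (c[0], c[1]))
    rule_id = lib.next_rule_id("p" if scope == "project" else "g")
    for _, _, cue, side in candidates:
        probe = PhraseRule(
            rule_id=rule_id, cue=cue, side=side, max_gap=group.k,
            category=category, source=scope, created_from=condition_name,
        )
        if not any(rule_hits(probe, ol, orr) for ol, orr in others):
            return probe
    # no short cue separates this window from its neighbours: pin the
    # entire window as a collocation rule
    return PhraseRule(
        rule_id=rule_id,
        cue=left + (PLACEHOLDER,) + right,
        side="either",
        max_gap=group.k,
        category=category,
        source=scope,
        created_from=condition_name,
    )


def apply_assignment(
    db: IntermediateDB,
    lib: RuleLibrary,
    group: ReviewGroup,
    category: CategoryLabel,
    scope: str = "project",
) -> tuple[IntermediateDB, RuleLibrary, PhraseRule]:
    """Label every member of ``group`` and promote the decision to a rule.

    ``scope`` is ``project`` or ``general`` — the reviewer's judgment of
    whether the word group applies beyond the current search.
    """
    if category not in ASSIGNABLE:
        raise ValueError(f"cannot assign {category!r}; pick one of the five categories")
    if scope not in ("project", "general"):
        raise ValueError(f"scope must be project|general, got {scope!r}")
    pending = [i for i in db.instances if i.category is CategoryLabel.UNCATEGORIZED]
    other_keys = [
        g.split_key()
        for g in review_groups(pending, group.k)
        if g.context_key != group.context_key
    ]
    rule = _derive_rule(group, category, scope, lib, other_keys, db.condition_name)
    added = lib.add(rule, project=db.condition_name)
    if not added:  # duplicate signature: reuse the existing rule's id
        rule = next(r for r in lib.rules if r.signature == rule.signature)
    for inst in db.instances:
        if inst.instance_id in group.member_instance_ids:
            inst.category = category
            inst.fired_rule_id = rule.rule_id
    return db, lib, rule


@dataclass
class ScriptedDecisions:
    """Decision source backed by a context-key → (category, scope) table."""

    table: dict[str, tuple[CategoryLabel, str]]

    def __call__(
        self, group: ReviewGroup, k: int
    ) -> Optional[tuple[CategoryLabel, str]]:
        return self.table.get(group.display())


@dataclass
class SessionReport:
    """Outcome of one review session."""

    n_assigned: int
    unresolved_ids: list[str]
    transcript: list[dict] = field(default_factory=list)

    @property
    def fully_resolved(self) -> bool:
        return not self.unresolved_ids


def review_session(
    db: IntermediateDB,
    lib: RuleLibrary,
    decisions: DecisionSource,
    k_schedule: Sequence[int] = DEFAULT_K_SCHEDULE,
) -> SessionReport:
    """Run the complete review workflow until nothing is uncategorized or
    the decision source abstains at the widest window.

    After every decision the grown library is re-applied to the remaining
    uncategorized instances ("results are applied to the entire list"),
    so the pending set shrinks monotonically.
    """
    if list(k_schedule) != sorted(set(k_schedule)):
        raise ValueError("k_schedule must be strictly increasing")
    transcript: list[dict] = []
    n_assigned = 0
    for k in k_schedule:
        while True:
            pending = [
                i for i in db.instances if i.category is CategoryLabel.UNCATEGORIZED
            ]
            if not pending:
                return SessionReport(n_assigned, [], transcript)
            progressed = False
            for group in review_groups(pending, k):
                decision = decisions(group, k)
                if decision is None:
                    continue
                category, scope = decision
                apply_assignment(db, lib, group, category, scope)
                n_assigned += group.size
                transcript.append(
                    {
                        "context_key": group.display(),
                        "k": k,
                        "category": category.value,
                        "scope": scope,
                    }
                )
                categorize_corpus(db, lib)
                progressed = True
                break  # membership changed: regroup
            if not progressed:
                break  # widen the window
    return SessionReport(n_assigned, db.uncategorized_ids(), transcript)


# ---------------------------------------------------------------------------
# transcript persistence (JSON-lines; doubles as project provenance)


def save_transcript(entries: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")


def load_transcript(path: str | Path) -> ScriptedDecisions:
    """Load a transcript for replay as a scripted decision source."""
    table: dict[str, tuple[CategoryLabel, str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            table[rec["context_key"]] = (
                CategoryLabel(rec["category"]),
                rec.get("scope", "project"),
            )
    return ScriptedDecisions(table)
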