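"""Locate all mentions of a search pattern and build the intermediate database.

The first pipeline stage scans the stop-word-filtered token stream of every
note for the compiled pattern (greedy left-to-right, longest match wins,
non-overlapping) and records each hit together with a window of surrounding
tokens from the *full* normalized stream — the context that the cue-phrase
library will later interrogate. The result is a plain-text, fully
searchable intermediate database, and the set of notes containing at least
one hit doubles as a cache: re-searching only those notes reproduces the
identical result in a fraction of the time.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import csv

from notepheno.context_library import CategoryLabel
from notepheno.corpus_io import NoteRecord
from notepheno.errors import FormatError, StalenessWarning
from notepheno.textnorm import SearchPattern, matches, pattern_from_spec

#: default number of context tokens stored per side — wide enough to hold
#: every shipped cue phrase with margin
DEFAULT_WINDOW = 12


@dataclass
class Instance:
    """One located mention of a condition term with its context.

    ``match_token_start``/``match_token_len`` index into the note's full
    normalized token stream; contexts are slices of the same stream (so
    cue phrases containing stop words remain visible).
    """

    instance_id: str
    patient_id: str
    note_id: str
    note_type: str
    condition_name: str
    match_token_start: int
    match_token_len: int
    surface: str
    left_context: list[str] = field(default_factory=list)
    right_context: list[str] = field(default_factory=list)
    category: CategoryLabel = CategoryLabel.UNCATEGORIZED
    fired_rule_id: Optional[str] = None


@dataclass
class IntermediateDB:
    """All instances of one pattern across a corpus, plus cache metadata."""

    instances: list[Instance]
    pattern: SearchPattern
    corpus_fingerprint: str
    window: int = DEFAULT_WINDOW

    @property
    def relevant_note_ids(self) -> frozenset[str]:
        return frozenset(i.note_id for i in self.instances)

    @property
    def condition_name(self) -> str:
        return self.pattern.condition_name

    def uncategorized_ids(self) -> list[str]:
        return [
            i.instance_id
            for i in self.instances
            if i.category is CategoryLabel.UNCATEGORIZED
        ]


def corpus_fingerprint(corpus: Sequence[NoteRecord]) -> str:
    """Content hash of a corpus (note ids + raw text, order-independent)."""
    h = hashlib.sha256()
    for nid, text in sorted((n.note_id, n.raw_text) for n in corpus):
        h.update(nid.encode("utf-8"))
        h.update(b"\x1e")
        h.update(text.encode("utf-8"))
        h.update(b"\x1f")
    return h.hexdigest()


def find_instances(
    corpus: Sequence[NoteRecord],
    pattern: SearchPattern,
    window: int = DEFAULT_WINDOW,
) -> IntermediateDB:
    """Scan the corpus for ``pattern`` and return the intermediate database.

    Matching is greedy left-to-right on the filtered stream: after a match
    of length L at token i, scanning resumes at i+L, so multiword matches
    are never double-counted. Contexts truncate silently at note
    boundaries. All instances start ``UNCATEGORIZED``.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    out: list[Instance] = []
    for note in corpus:
        toks = note.norm_tokens
        i = 0
        while i < len(toks):
            L = matches(pattern, toks, i)
            if L == 0:
                i += 1
                continue
            f_start = note.kept_indices[i]
            f_end = note.kept_indices[i + L - 1]
            c_start = note.all_token_char_spans[f_start][0]
            c_end = note.all_token_char_spans[f_end][1]
            out.append(
                Instance(
                    instance_id=f"{note.note_id}:{f_start}",
                    patient_id=note.patient_id,
                    note_id=note.note_id,
                    note_type=note.note_type,
                    condition_name=pattern.condition_name,
                    match_token_start=f_start,
                    match_token_len=f_end - f_start + 1,
                    surface=note.raw_text[c_start:c_end],
                    left_context=note.all_tokens[max(0, f_start - window) : f_start],
                    right_context=note.all_tokens[f_end + 1 : f_end + 1 + window],
                )
            )
            i += L
    out.sort(key=lambda x: (x.patient_id, x.note_id, x.match_token_start))
    return IntermediateDB(
        instances=out,
        pattern=pattern,
        corpus_fingerprint=corpus_fingerprint(corpus),
        window=window,
    )


# ---------------------------------------------------------------------------
# plain-text persistence

_COLUMNS = (
    "instance_id", "patient_id", "note_id", "note_type", "condition",
    "start", "len", "surface", "left_context", "right_context",
    "category", "rule_id",
)


def save_intermediate(db: IntermediateDB, path: str | Path) -> None:
    """Serialize the database as one metadata line plus a CSV table.

    Deterministic: the same database always produces the same bytes.
    """
    meta = {
        "format": "notepheno-intermediate-v1",
        "fingerprint": db.corpus_fingerprint,
        "window": db.window,
        "pattern": db.pattern.to_spec(),
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("#meta " + json.dumps(meta, sort_keys=True) + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for x in db.instances:
            writer.writerow(
                [
                    x.instance_id, x.patient_id, x.note_id, x.note_type,
                    x.condition_name, x.match_token_start, x.match_token_len,
                    x.surface, " ".join(x.left_context), " ".join(x.right_context),
                    x.category.value, x.fired_rule_id or "",
                ]
            )


def load_intermediate(
    path: str | Path, corpus: Optional[Sequence[NoteRecord]] = None
) -> IntermediateDB:
    """Load a saved database; warn if ``corpus`` content has changed.

    A fingerprint mismatch is a :class:`StalenessWarning`, not an error —
    the workflow permits re-searching a modified corpus.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.startswith("#meta "):
            raise FormatError(f"{path}: missing #meta header line")
        try:
            meta = json.loads(first[len("#meta "):])
            pattern = pattern_from_spec(meta["pattern"])
        except (json.JSONDecodeError, KeyError) as exc:
            raise FormatError(f"{path}: bad metadata line: {exc}") from exc
        reader = csv.DictReader(fh)
        instances: list[Instance] = []
        for lineno, row in enumerate(reader, start=3):
            try:
                instances.append(
                    Instance(
                        instance_id=row["instance_id"],
                        patient_id=row["patient_id"],
                        note_id=row["note_id"],
                        note_type=row["note_type"],
                        condition_name=row["condition"],
                        match_token_start=int(row["start"]),
                        match_token_len=int(row["len"]),
                        surface=row["surface"],
                        left_context=row["left_context"].split(),
                        right_context=row["right_context"].split(),
                        category=CategoryLabel(row["category"]),
                        fired_rule_id=row["rule_id"] or None,
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    db = IntermediateDB(
        instances=instances,
        pattern=pattern,
        corpus_fingerprint=meta.get("fingerprint", ""),
        window=int(meta.get("window", DEFAULT_WINDOW)),
    )
    if corpus is not None:
        actual = corpus_fingerprint(corpus)
        if actual != db.corpus_fingerprint:
            warnings.warn(
                f"{path}: corpus content changed since this database was built; "
                "consider re-running the search",
                StalenessWarning,
                stacklevel=2,
            )
    return db


def restrict_corpus(
    corpus: Sequence[NoteRecord], note_ids: frozenset[str] | set[str]
) -> list[NoteRecord]:
    """The relevant-note cache: the subset of notes with ids in ``note_ids``."""
    return [n for n in corpus if n.note_id in note_ids]
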