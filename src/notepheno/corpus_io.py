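"""Note corpus I/O and text preprocessing.

Clinical note corpora arrive as delimited plain text, one row per note
(patient key, note id, note type, optional timestamp, free text). This
module reads and writes that format and applies the preprocessing every
downstream stage relies on: lower-casing, punctuation standardization,
tokenization with character offsets, and stop-word removal.

Two parallel token streams are kept for every note:

* the **full normalized stream** (``all_tokens``) — every surviving token,
  stop words included.  Cue phrases such as "no evidence of" contain stop
  words, so context extraction and cue matching run on this stream.
* the **filtered stream** (``norm_tokens``) — stop words removed.  Search
  patterns are matched on this stream.

Each filtered token records its index into the full stream
(``kept_indices``) so matches can be re-anchored in their full context.
"""

from __future__ import annotations

import csv
import re
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from notepheno.errors import ConfigurationError, CorpusIntegrityError

Span = tuple[int, int]

#: Default controlled vocabulary of note types.
NOTE_TYPES = ("history_physical", "progress", "discharge_summary", "other")

#: Words that carry negation/uncertainty meaning and must never be removed.
DEFAULT_PROTECTED = frozenset(
    {"no", "not", "without", "denies", "negative", "doubt"}
)

# Length-preserving map from typographic punctuation to ASCII, applied
# before any other normalization so spans keep their source alignment.
_CHAR_MAP = str.maketrans(
    {
        "‘": "'", "’": "'", "‚": "'", "′": "'",
        "“": '"', "”": '"', "„": '"',
        "‐": "-", "‑": "-", "‒": "-", "–": "-",
        "—": "-", "―": "-", "−": "-",
        "…": ".",
        " ": " ",
    }
)

_ALNUM = re.compile(r"[a-z0-9]")
_PUNCT_RUN = re.compile(r"[.\-]{2,}")


def default_stopwords() -> frozenset[str]:
    """The stop-word list shipped with the package (~25 function words)."""
    text = resources.files("notepheno").joinpath("data/stopwords.txt").read_text("utf-8")
    words = [ln.strip() for ln in text.splitlines()]
    return frozenset(w for w in words if w and not w.startswith("#"))


@dataclass(frozen=True)
class StopwordPolicy:
    """Which tokens to drop from the filtered search stream.

    ``protected`` always wins over ``stopwords``: a protected token is never
    removed even if it also appears in the stop-word set.
    """

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    protected: frozenset[str] = DEFAULT_PROTECTED

    @property
    def removal_set(self) -> frozenset[str]:
        return self.stopwords - self.protected

    def with_protected(self, extra: Iterable[str]) -> "StopwordPolicy":
        """Return a policy additionally protecting ``extra`` tokens.

        Used to guarantee that every word of every cue phrase in a rule
        library survives preprocessing.
        """
        return StopwordPolicy(self.stopwords, self.protected | frozenset(extra))


def _is_shorthand(mapped: str) -> bool:
    """True for slash shorthand like ``s/p``, ``b/l`` or ``120/80`` that
    should stay one token (with ``/`` standardized to ``-``)."""
    parts = mapped.split("/")
    if any(not p for p in parts):
        return False
    return all(len(p) <= 2 or any(c.isdigit() for c in p) for p in parts)


def _emit(mapped: str, lo: int, hi: int) -> tuple[str, Span] | None:
    """Trim ``mapped[lo:hi]`` to its alphanumeric core and normalize it."""
    while lo < hi and not _ALNUM.match(mapped[lo]):
        lo += 1
    while hi > lo and not _ALNUM.match(mapped[hi - 1]):
        hi -= 1
    if lo == hi:
        return None
    chars = []
    for c in mapped[lo:hi]:
        if c == "/":
            c = "-"
        if _ALNUM.match(c) or c in ".-":
            chars.append(c)
    tok = _PUNCT_RUN.sub(lambda m: m.group()[0], "".join(chars))
    return tok, (lo, hi)


def tokenize(raw_text: str) -> list[tuple[str, Span]]:
    """Split ``raw_text`` into normalized tokens with character spans.

    Tokens are lowercase, restricted to ``[a-z0-9.-]``, and each span is a
    0-based half-open offset range into ``raw_text`` such that normalizing
    the raw slice reproduces the token.
    """
    out: list[tuple[str, Span]] = []
    for m in re.finditer(r"\S+", raw_text):
        chunk_start = m.start()
        mapped = m.group().translate(_CHAR_MAP).lower()
        if "/" in mapped and not _is_shorthand(mapped.strip(".,;:!?()[]{}\"'")):
            pieces, pos = [], 0
            for part in mapped.split("/"):
                pieces.append((pos, pos + len(part)))
                pos += len(part) + 1
        else:
            pieces = [(0, len(mapped))]
        for lo, hi in pieces:
            emitted = _emit(mapped, lo, hi)
            if emitted is not None:
                tok, (s, e) = emitted
                out.append((tok, (chunk_start + s, chunk_start + e)))
    return out


def preprocess(
    raw_text: str, policy: StopwordPolicy | None = None
) -> tuple[list[str], list[Span]]:
    """Normalize ``raw_text`` into the filtered search stream.

    Returns the stop-word-filtered token list and, per token, the half-open
    character span of its source text. Total on any string; empty input
    yields ``([], [])``.
    """
    policy = policy or StopwordPolicy()
    removal = policy.removal_set
    toks, spans = [], []
    for tok, span in tokenize(raw_text):
        if tok in removal:
            continue
        toks.append(tok)
        spans.append(span)
    return toks, spans


@dataclass
class NoteRecord:
    """One clinical note, raw and in both normalized token streams."""

    patient_id: str
    note_id: str
    note_type: str = "other"
    chart_time: str | None = None
    raw_text: str = ""
    #: stop-word-filtered stream used for pattern search
    norm_tokens: list[str] = field(default_factory=list)
    token_char_spans: list[Span] = field(default_factory=list)
    #: full normalized stream used for contexts and cue matching
    all_tokens: list[str] = field(default_factory=list)
    all_token_char_spans: list[Span] = field(default_factory=list)
    #: index into ``all_tokens`` for each entry of ``norm_tokens``
    kept_indices: list[int] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        patient_id: str,
        note_id: str,
        raw_text: str,
        note_type: str = "other",
        chart_time: str | None = None,
        policy: StopwordPolicy | None = None,
    ) -> "NoteRecord":
        if not patient_id or not note_id:
            raise CorpusIntegrityError(
                f"patient_id and note_id must be non-empty (note_id={note_id!r})"
            )
        policy = policy or StopwordPolicy()
        removal = policy.removal_set
        all_toks, all_spans, toks, spans, kept = [], [], [], [], []
        for i, (tok, span) in enumerate(tokenize(raw_text)):
            all_toks.append(tok)
            all_spans.append(span)
            if tok not in removal:
                toks.append(tok)
                spans.append(span)
                kept.append(i)
        if note_type not in NOTE_TYPES:
            note_type = "other"
        return cls(
            patient_id=patient_id,
            note_id=note_id,
            note_type=note_type,
            chart_time=chart_time or None,
            raw_text=raw_text,
            norm_tokens=toks,
            token_char_spans=spans,
            all_tokens=all_toks,
            all_token_char_spans=all_spans,
            kept_indices=kept,
        )


@dataclass(frozen=True)
class ColumnMap:
    """Maps logical note fields to the columns of a delimited file."""

    patient_id: str = "patient_id"
    note_id: str = "note_id"
    note_type: str = "note_type"
    chart_time: str = "chart_time"
    text: str = "text"

    @property
    def required(self) -> tuple[str, str, str]:
        return (self.patient_id, self.note_id, self.text)


def read_notes(
    path: str | Path,
    columns: ColumnMap | None = None,
    delimiter: str = ",",
    policy: StopwordPolicy | None = None,
) -> list[NoteRecord]:
    """Read a delimited note file into preprocessed :class:`NoteRecord` rows.

    The file must have a header naming at least the patient, note-id and
    text columns of ``columns``; note-type and timestamp columns are
    optional. Embedded newlines in the text field are supported via
    standard quoting. Row order is preserved.
    """
    columns = columns or ColumnMap()
    policy = policy or StopwordPolicy()
    path = Path(path)
    records: list[NoteRecord] = []
    seen: set[str] = set()
    csv.field_size_limit(min(sys.maxsize, 2**31 - 1))
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in columns.required:
            if col not in header:
                raise ConfigurationError(
                    f"required column {col!r} missing from {path} (header: {header})"
                )
        for rownum, row in enumerate(reader, start=2):
            try:
                rec = NoteRecord.build(
                    patient_id=(row[columns.patient_id] or "").strip(),
                    note_id=(row[columns.note_id] or "").strip(),
                    raw_text=row[columns.text] or "",
                    note_type=(row.get(columns.note_type) or "other").strip(),
                    chart_time=(row.get(columns.chart_time) or "").strip() or None,
                    policy=policy,
                )
            except CorpusIntegrityError:
                raise
            except Exception as exc:  # pragma: no cover - row-level defence
                raise CorpusIntegrityError(f"unreadable row {rownum} in {path}: {exc}") from exc
            if rec.note_id in seen:
                raise CorpusIntegrityError(f"duplicate note_id {rec.note_id!r} (row {rownum})")
            seen.add(rec.note_id)
            records.append(rec)
    return records


def write_notes(
    records: Sequence[NoteRecord],
    path: str | Path,
    columns: ColumnMap | None = None,
    delimiter: str = ",",
) -> None:
    """Write records back to the delimited note format (raw text preserved)."""
    columns = columns or ColumnMap()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(
            [columns.patient_id, columns.note_id, columns.note_type, columns.chart_time, columns.text]
        )
        for r in records:
            writer.writerow([r.patient_id, r.note_id, r.note_type, r.chart_time or "", r.raw_text])
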