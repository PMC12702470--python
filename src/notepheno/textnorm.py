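"""Stemming, synonym grouping and search-pattern compilation.

A condition's search specification is a name plus a list of raw terms.
Terms come in three flavours:

* ``"pneumonia"``        — exact normalized token (a literal synonym);
* ``"delir*"``           — explicit root with prefix semantics, so one
  entry covers *delirium*, *delirious*, *delirium's* ...;
* ``"central cord syndrome"`` — multiword literal matched as a
  consecutive normalized token sequence.

The stemmer is a deterministic suffix stripper: it always returns a
prefix of its input, so stem equality implies shared-root candidacy and
nothing more. Explicit ``*`` roots are the primary mechanism; the
stemmer's job is consistency, not linguistic perfection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from notepheno.corpus_io import tokenize
from notepheno.errors import SpecificationError

# Suffixes stripped by `stem`, longest first. Pure deletion only (never
# substitution) so the prefix property stem(x) ⊑ x holds by construction.
_SUFFIXES = (
    "ousness", "iveness", "fulness",
    "ations", "ation", "ional", "ively",
    "ious", "itus", "itis", "ally",
    "ium", "ous", "ive", "ful", "ing", "ers",
    "ed", "es", "er", "ly",
    "s",
)
_MIN_STEM = 3


def stem(token: str) -> str:
    """Strip the longest applicable suffix, keeping at least 3 characters.

    ``stem("delirium") == stem("delirious") == "delir"``;
    ``stem("decubitus") == "decub"``; short tokens like ``"pna"`` are
    returned unchanged.
    """
    for suf in _SUFFIXES:
        if token.endswith(suf) and len(token) - len(suf) >= _MIN_STEM:
            return token[: -len(suf)]
    return token


_NAME_OK = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_ .\-]*$")


@dataclass(frozen=True)
class SearchPattern:
    """Compiled matchable form of a condition's term list."""

    condition_name: str
    stems: frozenset[str] = frozenset()
    literals: frozenset[str] = frozenset()
    multiword_literals: frozenset[tuple[str, ...]] = frozenset()

    def __post_init__(self):
        if not (self.stems or self.literals or self.multiword_literals):
            raise SpecificationError(
                f"pattern {self.condition_name!r} has no terms"
            )
        if not self.condition_name or not _NAME_OK.match(self.condition_name):
            raise SpecificationError(
                f"condition name {self.condition_name!r} is not a legal column name"
            )

    @property
    def max_len(self) -> int:
        return max((len(m) for m in self.multiword_literals), default=1)

    def to_spec(self) -> dict:
        """Round-trippable plain representation (see :func:`pattern_from_spec`)."""
        terms = sorted(s + "*" for s in self.stems)
        terms += sorted(self.literals)
        terms += sorted(" ".join(m) for m in self.multiword_literals)
        return {"name": self.condition_name, "terms": terms}


def _norm_term(term: str) -> list[str]:
    return [tok for tok, _ in tokenize(term)]


def compile_pattern(condition_name: str, terms: list[str]) -> SearchPattern:
    """Compile a raw term list into a :class:`SearchPattern`.

    Single-word terms ending in ``*`` become prefix stems; terms containing
    whitespace become multiword literals; everything else is an exact-token
    literal. All entries are normalized with the corpus tokenizer so they
    match the token streams downstream.
    """
    if not terms:
        raise SpecificationError(f"pattern {condition_name!r}: empty term list")
    stems, literals, multi = set(), set(), set()
    for term in terms:
        is_root = term.rstrip().endswith("*")
        toks = _norm_term(term.rstrip().rstrip("*"))
        if not toks:
            raise SpecificationError(
                f"pattern {condition_name!r}: term {term!r} normalizes to nothing"
            )
        if len(toks) > 1:
            multi.add(tuple(toks))
        elif is_root:
            stems.add(toks[0])
        else:
            literals.add(toks[0])
    return SearchPattern(
        condition_name=condition_name,
        stems=frozenset(stems),
        literals=frozenset(literals),
        multiword_literals=frozenset(multi),
    )


def pattern_from_spec(spec: dict) -> SearchPattern:
    """Inverse of :meth:`SearchPattern.to_spec`."""
    return compile_pattern(spec["name"], list(spec["terms"]))


def matches(pattern: SearchPattern, tokens: list[str], i: int) -> int:
    """Longest match length of ``pattern`` at token index ``i`` (0 = none).

    Multiword literals are tried longest-first and beat single-token
    matches; a stem matches any token it prefixes.
    """
    if not 0 <= i < len(tokens):
        raise IndexError(f"token index {i} out of range [0, {len(tokens)})")
    best = 0
    for m in pattern.multiword_literals:
        L = len(m)
        if L > best and tuple(tokens[i : i + L]) == m:
            best = L
    if best:
        return best
    tok = tokens[i]
    if tok in pattern.literals:
        return 1
    for s in pattern.stems:
        if tok.startswith(s):
            return 1
    return 0
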