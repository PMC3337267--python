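"""Term normalization, syntactic-head extraction and label inclusion.

The normalization pipeline splits camel-case expressions, treats
underscores and hyphens as separators, lowercases and tokenizes.  The
head heuristic picks the rightmost token of a label — or, for
prepositional phrases like ``professor of biology``, the rightmost token
of the segment before the first preposition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

#: Tokens treated as prepositions by :func:`extract_head` when no custom
#: set is supplied.
DEFAULT_PREPOSITIONS = frozenset(
    {"of", "in", "for", "by", "with", "at", "to", "from", "on"}
)

# lower/digit->upper boundary, plus acronym boundary (HTTPServer -> HTTP Server)
_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")
_STRIP_RE = re.compile(r"[^\w\s]", re.UNICODE)


class EmptyLabelError(ValueError):
    """Raised when a label has no alphanumeric content."""


class DegenerateLabelError(ValueError):
    """Raised when a label consists solely of prepositions."""


class Inclusion(str, Enum):
    IDENTICAL = "identical"
    A_INCLUDES_B = "a_includes_b"
    B_INCLUDES_A = "b_includes_a"
    NONE = "none"


@dataclass(frozen=True)
class NormalizedLabel:
    """A label after normalization: ordered lowercase tokens."""

    source_text: str
    tokens: tuple[str, ...]

    @property
    def rendering(self) -> str:
        """Space-joined tokens; normalizing this string is a fixpoint."""
        return " ".join(self.tokens)


def normalize(text: str) -> NormalizedLabel:
    """Normalize a class label or local name into lowercase tokens.

    Pipeline: camel-case splitting (including acronym boundaries),
    underscore/hyphen-to-space, punctuation stripping, whitespace
    collapsing, lowercasing, space tokenization.

    >>> normalize("AnatomicalStructure").tokens
    ('anatomical', 'structure')
    """
    if text is None or not text.strip():
        raise EmptyLabelError("empty or whitespace-only label")
    s = _CAMEL_RE.sub(" ", text)
    s = s.replace("_", " ").replace("-", " ")
    s = s.lower()  # before punctuation stripping, so lowering cannot
    s = _STRIP_RE.sub("", s)  # reintroduce strippable combining marks
    tokens = tuple(s.split())
    if not tokens:
        raise EmptyLabelError("label %r has no alphanumeric content" % text)
    return NormalizedLabel(source_text=text, tokens=tokens)


def extract_head(
    label: NormalizedLabel, preposition_set: frozenset[str] = DEFAULT_PREPOSITIONS
) -> str:
    """Extract the syntactic head token of a normalized label.

    If a preposition occurs (not label-initially), the head is the
    rightmost token of the segment before the first such occurrence
    ("professor of biology" -> "professor"); otherwise it is the
    rightmost token ("doctoral thesis" -> "thesis").
    """
    tokens = label.tokens
    if not tokens:
        raise EmptyLabelError("cannot extract head from empty label")
    if all(t in preposition_set for t in tokens):
        raise DegenerateLabelError(
            "label %r consists only of prepositions" % (label.source_text,)
        )
    for i, tok in enumerate(tokens):
        if tok in preposition_set and i > 0:
            return tokens[i - 1]
    # no usable preposition: rightmost non-preposition token
    for tok in reversed(tokens):
        if tok not in preposition_set:
            return tok
    raise DegenerateLabelError("unreachable")  # pragma: no cover


def label_inclusion(a: NormalizedLabel, b: NormalizedLabel) -> Inclusion:
    """Classify token-level inclusion between two normalized labels.

    Inclusion is contiguous-token-subsequence containment, not substring
    containment (so "male" is not included in "female").
    """
    if not a.tokens or not b.tokens:
        raise EmptyLabelError("inclusion undefined for empty labels")
    if a.tokens == b.tokens:
        return Inclusion.IDENTICAL
    if _contains(a.tokens, b.tokens):
        return Inclusion.A_INCLUDES_B
    if _contains(b.tokens, a.tokens):
        return Inclusion.B_INCLUDES_A
    return Inclusion.NONE


def _contains(longer: tuple[str, ...], shorter: tuple[str, ...]) -> bool:
    n, m = len(longer), len(shorter)
    if m >= n:
        return False
    return any(longer[i : i + m] == shorter for i in range(n - m + 1))


def load_preposition_set(path) -> frozenset[str]:
    """Load a preposition set from a plain-text file, one token per line."""
    with open(path, encoding="utf-8") as handle:
        return frozenset(
            line.strip().lower() for line in handle if line.strip()
        )
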