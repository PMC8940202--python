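"""Shared text normalization and string-similarity primitives.

Every stage that compares variable names (curation duplicate detection,
lexical and semantic matching) goes through the same normalization so that
``"Anti-La"``, ``"anti_la"`` and ``"ANTI LA"`` are one and the same term.
"""

from __future__ import annotations

import re

import edlib

# Separators that clinical exports use interchangeably inside variable names.
_SEPARATORS = re.compile(r"[_\-/]+")
# Anything that is neither word character nor whitespace is stripped.
_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize(term: str) -> list[str]:
    """Normalize a term to its token list.

    Lowercase; ``_``, ``-`` and ``/`` become spaces; remaining punctuation is
    stripped; whitespace is collapsed; the result is split on spaces.
    """
    s = str(term).lower()
    s = _SEPARATORS.sub(" ", s)
    s = _PUNCT.sub("", s)
    s = _WS.sub(" ", s).strip()
    return s.split(" ") if s else []


def normalized_form(term: str) -> str:
    """Space-joined normalized tokens (the canonical comparable form)."""
    return " ".join(normalize(term))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein edit distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def lexical_similarity(a: str, b: str) -> float:
    """Normalized-Levenshtein similarity of two terms, in [0, 1].

    Both terms are reduced to their space-joined normalized form first;
    the score is ``1 - d / max(len)``.  An empty normalized form scores 0.
    """
    fa, fb = normalized_form(a), normalized_form(b)
    if not fa or not fb:
        return 0.0
    if fa == fb:
        return 1.0
    return 1.0 - levenshtein(fa, fb) / max(len(fa), len(fb))


# Common binary encodings (case-insensitive), shared by curation's domain
# checks and harmonization's standardization transforms.
BINARY_POSITIVE = frozenset({"1", "yes", "y", "true", "present", "pos",
                             "positive"})
BINARY_NEGATIVE = frozenset({"0", "no", "n", "false", "absent", "neg",
                             "negative"})

# Cell values parsed as "missing" (case-insensitive), config-extensible.
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "null", "-"})


def is_missing(cell, extra_tokens: frozenset[str] | None = None) -> bool:
    """True if a table cell encodes a missing value."""
    if cell is None:
        return True
    if isinstance(cell, float) and cell != cell:  # NaN
        return True
    s = str(cell).strip().lower()
    if s in MISSING_TOKENS:
        return True
    return bool(extra_tokens) and s in extra_tokens


def parse_numeric(cell) -> float | None:
    """Parse a cell as a float, or None if it does not parse."""
    if cell is None:
        return None
    try:
        v = float(str(cell).strip())
    except (TypeError, ValueError):
        return None
    return None if v != v else v
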