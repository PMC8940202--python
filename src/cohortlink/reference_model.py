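"""Disease reference model, ontology view, and derived medical corpus.

A *reference model* is the gold standard for harmonization: the set of
terminologies that describe the domain knowledge of a disease, each with a
value domain (kind, unit, range or categories) and a position in a class
hierarchy.  The model is stored as a single JSON document, its hierarchy is
a forest of parent links, and the flat, synonym-enriched, machine-matchable
serialization of its terms is the *medical corpus* (also JSON) against which
cohort columns are matched.

Synonym enrichment is pluggable: any object with a ``synonyms(token)``
method can serve as the source, and the corpus is always buildable fully
offline with ``enrichment=None``.  A small built-in clinical vocabulary
(:data:`CLINICAL_SYNONYMS`) ships as the default offline source.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from ._text import normalize

VALID_KINDS = ("numeric", "categorical", "binary", "date")


class ReferenceModelError(ValueError):
    """Malformed reference-model document or broken hierarchy."""


@dataclass(frozen=True)
class ValueDomain:
    """Admissible values of one reference term.

    kind
        One of ``numeric``, ``categorical``, ``binary``, ``date``.
    unit
        Free-text unit label (numeric kinds), or empty.
    numeric_range
        Inclusive ``(low, high)`` bounds, numeric kind only.
    categories
        Ordered canonical category labels (categorical kind).  Binary terms
        are always coded ``0`` = absent, ``1`` = present.
    """

    kind: str
    unit: str = ""
    numeric_range: tuple[float, float] | None = None
    categories: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ReferenceModelError(f"unknown domain kind {self.kind!r}")
        if self.kind == "numeric":
            if self.numeric_range is not None:
                low, high = self.numeric_range
                if low > high:
                    raise ReferenceModelError(
                        f"numeric range low {low} > high {high}")
        if self.kind == "categorical":
            cats = self.categories
            if not cats or len(set(cats)) != len(cats):
                raise ReferenceModelError(
                    "categorical domain needs non-empty unique categories")
        if self.kind == "binary":
            object.__setattr__(self, "categories", ("0", "1"))

    def contains(self, value) -> bool:
        """Membership of a (string) cell value in this domain."""
        from ._text import parse_numeric
        if self.kind == "numeric":
            v = parse_numeric(value)
            if v is None:
                return False
            if self.numeric_range is None:
                return True
            low, high = self.numeric_range
            return low <= v <= high
        if self.kind == "binary":
            return str(value).strip() in ("0", "1")
        if self.kind == "categorical":
            return str(value).strip() in self.categories
        return True  # date kind: membership not enforced

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "unit": self.unit,
            "range": list(self.numeric_range) if self.numeric_range else None,
            "categories": list(self.categories) if self.categories else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValueDomain":
        try:
            kind = d["kind"]
        except KeyError as e:
            raise ReferenceModelError(f"domain missing key {e.args[0]!r}")
        rng = d.get("range")
        cats = d.get("categories")
        return cls(
            kind=kind,
            unit=d.get("unit", "") or "",
            numeric_range=tuple(rng) if rng else None,
            categories=tuple(cats) if cats else None,
        )


@dataclass(frozen=True)
class ReferenceTerm:
    """One terminology of the reference model."""

    name: str
    domain: ValueDomain
    description: str = ""
    parent: str | None = None


class ReferenceOntology:
    """The reference model viewed as a class hierarchy (a forest).

    Terms are kept in declaration order; parent links must be acyclic and
    point at declared terms, so every term is reachable from exactly one
    root.  ``relation`` names the single parent->child object property.
    """

    def __init__(self, terms: Iterable[ReferenceTerm], name: str = "",
                 version: str = "", relation: str = "has_subclass"):
        self.name = name
        self.version = version
        self.relation = relation
        self._terms: dict[str, ReferenceTerm] = {}
        for t in terms:
            if t.name in self._terms:
                raise ReferenceModelError(f"duplicate term name {t.name!r}")
            self._terms[t.name] = t
        self._validate()

    def _validate(self):
        for t in self._terms.values():
            if t.parent is not None and t.parent not in self._terms:
                raise ReferenceModelError(
                    f"term {t.name!r} references undefined parent {t.parent!r}")
        # cycle check via parent-chain walk
        for t in self._terms.values():
            seen, cur = [t.name], t.parent
            while cur is not None:
                if cur in seen:
                    cycle = seen[seen.index(cur):] + [cur]
                    raise ReferenceModelError(
                        "cyclic parent links: " + " -> ".join(cycle))
                seen.append(cur)
                cur = self._terms[cur].parent

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, name: str) -> bool:
        return name in self._terms

    def __getitem__(self, name: str) -> ReferenceTerm:
        return self._terms[name]

    @property
    def terms(self) -> list[ReferenceTerm]:
        return list(self._terms.values())

    @property
    def roots(self) -> list[ReferenceTerm]:
        return [t for t in self._terms.values() if t.parent is None]

    def children(self, name: str | None) -> list[ReferenceTerm]:
        return [t for t in self._terms.values() if t.parent == name]

    def class_path(self, name: str) -> list[str]:
        """Root-to-term list of class names."""
        path, cur = [], name
        while cur is not None:
            path.append(cur)
            cur = self._terms[cur].parent
        return path[::-1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "terms": [
                {
                    "name": t.name,
                    "description": t.description,
                    "parent": t.parent,
                    "domain": t.domain.to_dict(),
                }
                for t in self._terms.values()
            ],
        }


def _ontology_from_dict(doc: dict) -> ReferenceOntology:
    for key in ("name", "version", "terms"):
        if key not in doc:
            raise ReferenceModelError(f"reference model missing key {key!r}")
    terms = []
    for i, td in enumerate(doc["terms"]):
        try:
            name = td["name"]
            domain = ValueDomain.from_dict(td["domain"])
        except KeyError as e:
            raise ReferenceModelError(
                f"term #{i} missing key {e.args[0]!r}")
        terms.append(ReferenceTerm(
            name=name, domain=domain,
            description=td.get("description", ""),
            parent=td.get("parent"),
        ))
    return ReferenceOntology(terms, name=doc["name"], version=doc["version"])


def load_reference_model(path: str | Path) -> ReferenceOntology:
    """Load a reference model from its JSON document."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ReferenceModelError(f"malformed JSON in {path}: {e}") from e
    return _ontology_from_dict(doc)


def _canonical_dumps(doc: dict) -> str:
    # fixed formatting so save(load(x)) round-trips byte-identically
    return json.dumps(doc, indent=2, ensure_ascii=False,
                      separators=(",", ": ")) + "\n"


def save_reference_model(ont: ReferenceOntology, path: str | Path) -> None:
    Path(path).write_text(_canonical_dumps(ont.to_dict()), encoding="utf-8")


def extract_terminologies(
    ont: ReferenceOntology,
) -> list[tuple[str, ValueDomain, list[str]]]:
    """All terminologies with their range values and class hierarchy.

    Deterministic depth-first order: roots in declaration order, children in
    declaration order; one ``(name, domain, class_path)`` tuple per term.
    """
    out: list[tuple[str, ValueDomain, list[str]]] = []

    def visit(term: ReferenceTerm, path: list[str]):
        full = path + [term.name]
        out.append((term.name, term.domain, full))
        for child in ont.children(term.name):
            visit(child, full)

    for root in ont.roots:
        visit(root, [])
    return out


class SynonymSource(Protocol):
    """Anything that can propose synonyms for a single-word token."""

    def synonyms(self, token: str) -> list[str]: ...


class StaticSynonymSource:
    """Synonym source backed by a plain token -> synonyms mapping."""

    def __init__(self, table: dict[str, list[str]]):
        self._table = {k.lower(): list(v) for k, v in table.items()}

    def synonyms(self, token: str) -> list[str]:
        return list(self._table.get(token.lower(), []))


#: Built-in clinical vocabulary used as the default offline synonym source.
CLINICAL_SYNONYMS: dict[str, list[str]] = {
    "gender": ["sex"],
    "sex": ["gender"],
    "age": ["years"],
    "swelling": ["enlargement", "tumefaction"],
    "enlargement": ["swelling"],
    "lymphadenopathy": ["adenopathy"],
    "salivary": ["sialo"],
    "gland": ["glandular"],
    "dryness": ["siccα", "sicca", "xerostomia"],
    "fatigue": ["tiredness", "asthenia"],
    "lymphoma": ["nhl"],
    "purpura": ["petechiae"],
    "factor": ["rf"],
    "biopsy": ["histology"],
    "positive": ["present"],
    "negative": ["absent"],
}


@dataclass
class CorpusEntry:
    """One matchable corpus record for a reference term."""

    synonyms: list[str]
    tokens: list[str]
    class_path: list[str]
    domain: ValueDomain
    enriched: list[str] = field(default_factory=list)


class MedicalCorpus:
    """Flat, synonym-enriched serialization of a reference ontology.

    ``entries`` maps canonical term name to :class:`CorpusEntry`, in the
    ontology's depth-first term order (harmonized outputs reuse that order).
    """

    def __init__(self, entries: dict[str, CorpusEntry], source_model: str = ""):
        self.entries = dict(entries)
        self.source_model = source_model

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    @property
    def term_names(self) -> list[str]:
        return list(self.entries)

    def token_pool(self, name: str) -> set[str]:
        """All tokens of all synonym forms of a term (equality pool for
        semantic matching)."""
        pool: set[str] = set()
        e = self.entries[name]
        for syn in e.synonyms:
            pool.update(normalize(syn))
        return pool

    def to_dict(self) -> dict:
        return {
            "source_model": self.source_model,
            "entries": {
                name: {
                    "synonyms": e.synonyms,
                    "tokens": e.tokens,
                    "class_path": e.class_path,
                    "domain": e.domain.to_dict(),
                    "enriched": e.enriched,
                }
                for name, e in self.entries.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(_canonical_dumps(self.to_dict()),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "MedicalCorpus":
        with open(path, encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as e:
                raise ReferenceModelError(
                    f"malformed JSON in {path}: {e}") from e
        for key in ("source_model", "entries"):
            if key not in doc:
                raise ReferenceModelError(f"corpus missing key {key!r}")
        entries = {}
        for name, ed in doc["entries"].items():
            entries[name] = CorpusEntry(
                synonyms=list(ed["synonyms"]),
                tokens=list(ed["tokens"]),
                class_path=list(ed["class_path"]),
                domain=ValueDomain.from_dict(ed["domain"]),
                enriched=list(ed.get("enriched", [])),
            )
        return cls(entries, source_model=doc["source_model"])


def build_corpus(
    ont: ReferenceOntology,
    enrichment: SynonymSource | None = None,
) -> MedicalCorpus:
    """Define the medical corpus of an ontology (offline by default).

    Each term contributes one entry whose synonyms always include the
    canonical name itself and whose tokens are the normalized token
    sequence of the canonical name.  With an enrichment source, synonyms of
    each single-word token are appended and tagged with provenance; an
    enrichment source that fails is downgraded to a warning, never a hard
    failure.
    """
    entries: dict[str, CorpusEntry] = {}
    for name, domain, path in extract_terminologies(ont):
        tokens = normalize(name)
        synonyms = [name]
        enriched: list[str] = []
        if enrichment is not None:
            for tok in tokens:
                try:
                    extra = enrichment.synonyms(tok)
                except Exception as exc:  # source unavailable: stay offline
                    warnings.warn(
                        f"synonym source failed for token {tok!r} ({exc}); "
                        "building offline corpus entry")
                    extra = []
                for syn in extra:
                    if syn not in synonyms:
                        synonyms.append(syn)
                        enriched.append(syn)
        entries[name] = CorpusEntry(
            synonyms=synonyms, tokens=tokens, class_path=path,
            domain=domain, enriched=enriched)
    return MedicalCorpus(entries, source_model=ont.name)
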