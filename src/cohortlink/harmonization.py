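"""Terminology alignment of cohort columns to the medical corpus.

Two staged matchers link source columns to reference terms:

* **lexical matching** — normalized-Levenshtein similarity between the
  column name and each synonym form of a term; accepted greedily by
  descending score under an injectivity constraint (one column per term,
  one term per column).
* **semantic matching** — runs only on the residue of the lexical stage.
  The score is a token-level composite: each column token takes its best
  synonym-aware similarity to the term's token pool (equality or listed
  synonym scores 1, otherwise normalized Levenshtein), averaged over the
  column tokens and combined with a class-path bonus that rewards overlap
  with the term's ancestors in the ontology.

Accepted matches whose observed values violate the reference value domain
get a value transform: a category recode table, a binary presence/absence
recode, or a configured affine unit rescale.  The tool never guesses units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import pandas as pd

from ._text import BINARY_NEGATIVE as _BINARY_NEGATIVE
from ._text import BINARY_POSITIVE as _BINARY_POSITIVE
from ._text import is_missing, lexical_similarity, normalize
from .curation import CohortTable
from .reference_model import MedicalCorpus, ValueDomain


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizationConfig:
    lexical_threshold: float = 0.80
    semantic_threshold: float = 0.60
    token_weight: float = 0.8      # weight of the mean token score
    path_weight: float = 0.2       # weight of the class-path bonus
    recode_min_similarity: float = 0.5
    unknown_label: str = "unknown"
    # explicit unit conversions: source column name -> (scale, offset)
    unit_conversions: dict[str, tuple[float, float]] = field(
        default_factory=dict)
    binary_positive: tuple[str, ...] = tuple(sorted(_BINARY_POSITIVE))
    binary_negative: tuple[str, ...] = tuple(sorted(_BINARY_NEGATIVE))


@dataclass
class TermMatch:
    source_column: str
    reference_term: str
    score: float
    method: str          # "lexical" | "semantic"
    accepted: bool


@dataclass
class ValueTransform:
    kind: str                                  # identity | recode | binary | affine
    mapping: dict[str, str] | None = None      # recode/binary table
    scale: float = 1.0
    offset: float = 0.0

    def apply(self, value):
        if is_missing(value):
            return ""
        v = str(value).strip()
        if self.kind in ("recode", "binary"):
            return self.mapping.get(v, self.mapping.get(v.lower(), v))
        if self.kind == "affine":
            try:
                return float(v) * self.scale + self.offset
            except ValueError:
                return v
        return v


@dataclass
class HarmonizationMapping:
    cohort_id: str
    matches: list[TermMatch]
    transforms: dict[str, ValueTransform]       # reference term -> transform
    unmatched_source: list[str]
    unmatched_reference: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> dict[str, str]:
        """source column -> reference term, accepted matches only."""
        return {m.source_column: m.reference_term
                for m in self.matches if m.accepted}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CoverageReport:
    cohort_id: str
    n_reference_terms: int
    n_matched: int
    n_standardized: int
    lexical_threshold: float
    semantic_threshold: float

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_matched / self.n_reference_terms

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coverage_pct"] = self.coverage_pct
        return d


def _greedy_accept(scores: list[tuple[float, str, str]], threshold: float,
                   method: str) -> list[TermMatch]:
    """Greedy injective assignment by descending score; ties break
    lexicographically by (term, column)."""
    used_cols: set[str] = set()
    used_terms: set[str] = set()
    out = []
    for score, term, col in sorted(scores, key=lambda t: (-t[0], t[1], t[2])):
        if score < threshold:
            break
        if col in used_cols or term in used_terms:
            continue
        used_cols.add(col)
        used_terms.add(term)
        out.append(TermMatch(col, term, score, method, True))
    return out


def lexical_match(columns: Iterable[str], corpus: MedicalCorpus,
                  threshold: float = 0.80) -> list[TermMatch]:
    """Stage-(v) lexical alignment: best synonym-form similarity per
    (column, term) pair, greedy injective acceptance at ``threshold``."""
    scores = []
    for col in columns:
        for term, entry in corpus.entries.items():
            s = max(lexical_similarity(col, syn) for syn in entry.synonyms)
            if s > 0:
                scores.append((s, term, col))
    return _greedy_accept(scores, threshold, "lexical")


def semantic_score(column: str, term: str, corpus: MedicalCorpus,
                   config: HarmonizationConfig | None = None) -> float:
    """Token/synonym/class-path composite similarity in [0, 1]."""
    cfg = config or HarmonizationConfig()
    col_tokens = normalize(column)
    if not col_tokens:
        return 0.0
    entry = corpus.entries[term]
    pool = corpus.token_pool(term)
    token_scores = []
    for t in col_tokens:
        if t in pool:
            token_scores.append(1.0)
        else:
            token_scores.append(max(
                (lexical_similarity(t, u) for u in pool), default=0.0))
    mean_token = sum(token_scores) / len(token_scores)
    bonus = 0.0
    for ancestor in entry.class_path[:-1]:
        anc_tokens = set(normalize(ancestor))
        overlap = len(anc_tokens & set(col_tokens)) / len(col_tokens)
        bonus = max(bonus, overlap)
    return cfg.token_weight * mean_token + cfg.path_weight * bonus


def semantic_match(columns: Iterable[str], corpus: MedicalCorpus,
                   threshold: float = 0.60,
                   exclude_terms: set[str] | None = None,
                   config: HarmonizationConfig | None = None
                   ) -> list[TermMatch]:
    """Stage-(vi) semantic alignment on the residue of the lexical stage."""
    exclude = exclude_terms or set()
    scores = []
    for col in columns:
        for term in corpus.entries:
            if term in exclude:
                continue
            s = semantic_score(col, term, corpus, config)
            if s > 0:
                scores.append((s, term, col))
    return _greedy_accept(scores, threshold, "semantic")


def _binary_recode(values: set[str], cfg: HarmonizationConfig
                   ) -> tuple[dict[str, str] | None, list[str]]:
    pos = {v.lower() for v in cfg.binary_positive}
    neg = {v.lower() for v in cfg.binary_negative}
    mapping, warns = {}, []
    for v in values:
        lv = v.lower()
        if lv in pos:
            mapping[v] = "1"
        elif lv in neg:
            mapping[v] = "0"
        else:
            mapping[v] = cfg.unknown_label
            warns.append(f"binary value {v!r} not in lexicon")
    return mapping, warns


def build_transforms(accepted: list[TermMatch], table: CohortTable,
                     corpus: MedicalCorpus,
                     config: HarmonizationConfig | None = None
                     ) -> tuple[dict[str, ValueTransform], list[str]]:
    """Value standardization rules for each accepted match whose observed
    values violate the reference domain; identity otherwise."""
    cfg = config or HarmonizationConfig()
    transforms: dict[str, ValueTransform] = {}
    warnings: list[str] = []
    for m in accepted:
        domain: ValueDomain = corpus.entries[m.reference_term].domain
        col = table.df[m.source_column]
        observed = {str(v).strip() for v in col.to_numpy()
                    if not is_missing(v)}
        conforming = all(domain.contains(v) for v in observed)
        if m.source_column in cfg.unit_conversions:
            scale, offset = cfg.unit_conversions[m.source_column]
            transforms[m.reference_term] = ValueTransform(
                "affine", scale=scale, offset=offset)
            continue
        if conforming:
            transforms[m.reference_term] = ValueTransform("identity")
            continue
        if domain.kind == "binary":
            mapping, warns = _binary_recode(observed, cfg)
            transforms[m.reference_term] = ValueTransform("binary",
                                                          mapping=mapping)
            warnings += [f"{m.source_column}: {w}" for w in warns]
        elif domain.kind == "categorical":
            mapping = {}
            for v in observed:
                best = max(domain.categories,
                           key=lambda c: lexical_similarity(v, c))
                s = lexical_similarity(v, best)
                if s < cfg.recode_min_similarity:
                    mapping[v] = cfg.unknown_label
                    warnings.append(
                        f"{m.source_column}: category {v!r} has no reference "
                        f"counterpart (best {s:.2f})")
                else:
                    mapping[v] = best
            transforms[m.reference_term] = ValueTransform("recode",
                                                          mapping=mapping)
        else:
            transforms[m.reference_term] = ValueTransform("identity")
            warnings.append(
                f"{m.source_column}: values outside reference domain of "
                f"{m.reference_term!r} and no unit conversion configured")
    return transforms, warnings


def harmonize(table: CohortTable, corpus: MedicalCorpus,
              config: HarmonizationConfig | None = None):
    """Align one curated cohort to the corpus.

    Returns ``(harmonized table, mapping, coverage report)``.  The output
    table's columns are exactly the accepted reference terms, canonical
    names in the model's depth-first order, values passed through their
    standardization transforms.
    """
    cfg = config or HarmonizationConfig()
    columns = list(table.df.columns)
    lex = lexical_match(columns, corpus, cfg.lexical_threshold)
    matched_cols = {m.source_column for m in lex}
    matched_terms = {m.reference_term for m in lex}
    residue = [c for c in columns if c not in matched_cols]
    sem = semantic_match(residue, corpus, cfg.semantic_threshold,
                         exclude_terms=matched_terms, config=cfg)
    accepted = lex + sem
    if not accepted:
        raise HarmonizationError("no alignment possible")
    transforms, warns = build_transforms(accepted, table, corpus, cfg)

    by_term = {m.reference_term: m for m in accepted}
    ordered_terms = [t for t in corpus.term_names if t in by_term]
    data = {}
    for term in ordered_terms:
        src = by_term[term].source_column
        tr = transforms[term]
        data[term] = [tr.apply(v) for v in table.df[src].to_numpy()]
    out = CohortTable(table.cohort_id, pd.DataFrame(data))

    accepted_cols = {m.source_column for m in accepted}
    mapping = HarmonizationMapping(
        cohort_id=table.cohort_id,
        matches=accepted,
        transforms=transforms,
        unmatched_source=[c for c in columns if c not in accepted_cols],
        unmatched_reference=[t for t in corpus.term_names if t not in by_term],
        warnings=warns,
    )
    n_std = sum(1 for tr in transforms.values() if tr.kind != "identity")
    coverage = CoverageReport(
        cohort_id=table.cohort_id,
        n_reference_terms=len(corpus),
        n_matched=len(accepted),
        n_standardized=n_std,
        lexical_threshold=cfg.lexical_threshold,
        semantic_threshold=cfg.semantic_threshold,
    )
    return out, mapping, coverage


def common_schema(tables: Iterable[CohortTable]) -> list[str]:
    """Columns shared by all harmonized tables, in first-table order
    (the pipeline glue for multi-cohort analyses)."""
    tables = list(tables)
    common = set(tables[0].df.columns)
    for t in tables[1:]:
        common &= set(t.df.columns)
    return [c for c in tables[0].df.columns if c in common]
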