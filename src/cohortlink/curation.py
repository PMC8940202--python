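"""Per-cohort data quality enhancement.

Detects bad, inconsistent and duplicated features, flags outlier cells, and
imputes missing values, producing a replayable :class:`CurationReport`.
Rows (patients) are never dropped: only columns are removed and only cells
are blanked or imputed, so downstream case/control bookkeeping stays intact.

All thresholds live in :class:`CurationConfig`; the defaults are
conservative choices that leave clean clinical tables untouched (no outlier
flags on well-behaved data, fixpoint behaviour on already-curated tables).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._text import is_missing, normalized_form, parse_numeric

Kind = Literal["numeric", "categorical", "binary", "date", "text", "unknown"]

_DATE_RE = re.compile(
    r"^\s*(\d{4}[-/]\d{1,2}[-/]\d{1,2}|\d{1,2}[-/]\d{1,2}[-/]\d{4})\s*$")


class CurationError(ValueError):
    pass


@dataclass
class CurationConfig:
    """Tunable curation thresholds (all findings are reproducible from the
    table plus this config alone)."""

    bad_missing_threshold: float = 0.5      # missing_fraction above => bad
    inconsistency_tolerance: float = 0.05   # fraction of offending cells
    duplicate_agreement: float = 0.99       # co-present value agreement
    outlier_iqr_factor: float = 3.0         # fence = Q1/Q3 -/+ k*IQR
    outlier_min_values: int = 8             # skip sparser features
    extra_missing_tokens: tuple[str, ...] = ()

    @property
    def missing_tokens(self) -> frozenset[str]:
        return frozenset(t.lower() for t in self.extra_missing_tokens)


@dataclass
class FeatureDescriptor:
    column_name: str
    declared_kind: Kind = "unknown"
    observed_kind: Kind = "unknown"
    missing_fraction: float = 0.0
    n_distinct: int = 0
    flags: set[str] = field(default_factory=set)


@dataclass
class Finding:
    feature: str
    rule: str                       # kind_mismatch | unparseable | out_of_domain | duplicate_name | duplicate_values | outlier | indeterminate | too_few_values
    cells: list[int] = field(default_factory=list)   # offending row indices
    detail: str = ""
    partner: str | None = None      # duplicate findings: the earlier column


@dataclass
class CohortTable:
    """A patient-by-feature table; cells are strings (possibly missing)."""

    cohort_id: str
    df: pd.DataFrame

    @classmethod
    def from_csv(cls, path: str | Path, cohort_id: str | None = None,
                 delimiter: str = ",") -> "CohortTable":
        df = pd.read_csv(path, dtype=str, sep=delimiter, keep_default_na=False)
        return cls(cohort_id or Path(path).stem, df)

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.df.to_csv(path, index=False, sep=delimiter)

    @property
    def n_rows(self) -> int:
        return len(self.df)


def _nonmissing(series: pd.Series, cfg: CurationConfig):
    """(positional indices, stripped string values) of non-missing cells."""
    idx, vals = [], []
    extra = cfg.missing_tokens
    for i, cell in enumerate(series.to_numpy()):
        if not is_missing(cell, extra):
            idx.append(i)
            vals.append(str(cell).strip())
    return idx, vals


def _infer_kind(vals: list[str]) -> Kind:
    if not vals:
        return "unknown"
    parsed = [parse_numeric(v) for v in vals]
    ok = [p for p in parsed if p is not None]
    if len(ok) == len(vals) and set(vals) <= {"0", "1"}:
        return "binary"
    if len(ok) > len(vals) / 2:
        return "numeric"
    n_dates = sum(bool(_DATE_RE.match(v)) for v in vals)
    if n_dates > len(vals) / 2:
        return "date"
    return "categorical" if len(set(vals)) <= max(2, 0.1 * len(vals)) else "text"


def _declared_kind(column: str, model) -> tuple[Kind, object]:
    """Declared kind (and domain) via exact normalized-name model lookup."""
    if model is None:
        return "unknown", None
    form = normalized_form(column)
    for term in model.terms:
        if normalized_form(term.name) == form:
            return term.domain.kind, term.domain
    return "unknown", None


def profile(table: CohortTable, model=None,
            config: CurationConfig | None = None) -> list[FeatureDescriptor]:
    """One descriptor per column; observed kind by majority vote over
    non-empty cells, exact missing fractions, bad-feature flags."""
    cfg = config or CurationConfig()
    if table.n_rows == 0:
        raise CurationError("empty cohort")
    out = []
    n = table.n_rows
    for col in table.df.columns:
        idx, vals = _nonmissing(table.df[col], cfg)
        declared, _ = _declared_kind(col, model)
        d = FeatureDescriptor(
            column_name=col,
            declared_kind=declared,
            observed_kind=_infer_kind(vals),
            missing_fraction=(n - len(idx)) / n,
            n_distinct=len(set(vals)),
        )
        if d.missing_fraction > cfg.bad_missing_threshold or d.n_distinct <= 1:
            d.flags.add("bad")
        out.append(d)
    return out


_COMPATIBLE = {
    ("binary", "binary"), ("numeric", "numeric"), ("numeric", "binary"),
    ("categorical", "categorical"), ("categorical", "binary"),
    ("date", "date"),
    # yes/no-style encodings of a binary term read as categorical; that is
    # an encoding difference for harmonization to standardize, not a defect
    ("binary", "categorical"),
}


def _recodable(value: str, domain) -> bool:
    """A value outside the domain that standardization can still map
    (alternative binary encodings, case/spelling variants of categories)."""
    from ._text import BINARY_NEGATIVE, BINARY_POSITIVE, lexical_similarity
    if domain.kind == "binary":
        return value.lower() in BINARY_POSITIVE | BINARY_NEGATIVE
    if domain.kind == "categorical":
        return any(lexical_similarity(value, c) >= 0.5
                   for c in domain.categories)
    return False


def detect_inconsistent(table: CohortTable, descriptors, model=None,
                        config: CurationConfig | None = None) -> list[Finding]:
    """Features whose declared and observed kinds clash, whose values fail
    to parse under the observed kind, or whose values fall outside the
    mapped reference value domain (beyond the configured tolerance)."""
    cfg = config or CurationConfig()
    findings = []
    for d in descriptors:
        col = d.column_name
        idx, vals = _nonmissing(table.df[col], cfg)
        if not vals:
            continue
        if (d.declared_kind != "unknown" and d.observed_kind != "unknown"
                and (d.declared_kind, d.observed_kind) not in _COMPATIBLE):
            findings.append(Finding(col, "kind_mismatch",
                                    detail=f"declared {d.declared_kind}, "
                                           f"observed {d.observed_kind}"))
            d.flags.add("inconsistent")
        bad_cells = [i for i, v in zip(idx, vals)
                     if not _parses_as(v, d.observed_kind)]
        if len(bad_cells) / len(vals) > cfg.inconsistency_tolerance:
            findings.append(Finding(col, "unparseable", cells=bad_cells))
            d.flags.add("inconsistent")
        _, domain = _declared_kind(col, model)
        if domain is not None:
            out_cells = [i for i, v in zip(idx, vals)
                         if not domain.contains(v) and not _recodable(v, domain)]
            if out_cells:
                f = Finding(col, "out_of_domain", cells=out_cells)
                findings.append(f)
                if len(out_cells) / len(vals) > cfg.inconsistency_tolerance:
                    d.flags.add("inconsistent")
    return findings


def _parses_as(value: str, kind: Kind) -> bool:
    if kind == "numeric":
        return parse_numeric(value) is not None
    if kind == "binary":
        return value in ("0", "1")
    if kind == "date":
        return bool(_DATE_RE.match(value))
    return True


def detect_duplicates(table: CohortTable,
                      config: CurationConfig | None = None) -> list[Finding]:
    """Column pairs equal by normalized name or by value agreement on
    co-present rows; the later column of a pair is the duplicate."""
    cfg = config or CurationConfig()
    findings = []
    cols = list(table.df.columns)
    arrays = {}
    for col in cols:
        idx, vals = _nonmissing(table.df[col], cfg)
        arrays[col] = dict(zip(idx, vals))
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            if normalized_form(a) == normalized_form(b) and normalized_form(a):
                findings.append(Finding(b, "duplicate_name", partner=a))
                continue
            va, vb = arrays[a], arrays[b]
            common = va.keys() & vb.keys()
            if not common:
                if va and vb:
                    findings.append(Finding(b, "indeterminate", partner=a))
                continue
            agree = sum(va[r] == vb[r] for r in common) / len(common)
            if agree >= cfg.duplicate_agreement:
                findings.append(Finding(b, "duplicate_values", partner=a,
                                        detail=f"agreement {agree:.3f}"))
    return findings


def detect_outliers(table: CohortTable, descriptors,
                    config: CurationConfig | None = None) -> list[Finding]:
    """Cells outside the Tukey-style fence Q1 - k*IQR .. Q3 + k*IQR
    (linear-interpolation quartiles, default k = 3, numeric features only).
    Sparse features are skipped and recorded as ``too_few_values``.

    Quartiles are computed over the *distinct* observed values: a mass of
    identical cells (the footprint of an earlier imputation) would otherwise
    shrink the IQR and turn ordinary values into outliers on a re-run,
    breaking the pipeline's idempotence.
    """
    cfg = config or CurationConfig()
    findings = []
    for d in descriptors:
        if d.observed_kind != "numeric":
            continue
        idx, vals = _nonmissing(table.df[d.column_name], cfg)
        parsed = [(i, parse_numeric(v)) for i, v in zip(idx, vals)]
        parsed = [(i, p) for i, p in parsed if p is not None]
        if len(parsed) < cfg.outlier_min_values:
            findings.append(Finding(d.column_name, "too_few_values"))
            continue
        arr = np.unique([p for _, p in parsed])
        q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - cfg.outlier_iqr_factor * iqr, q3 + cfg.outlier_iqr_factor * iqr
        cells = [i for i, p in parsed if p < lo or p > hi]
        if cells:
            findings.append(Finding(d.column_name, "outlier", cells=cells))
            d.flags.add("outlier-bearing")
    return findings


def _format_numeric(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def impute_missing(table: CohortTable, descriptors,
                   config: CurationConfig | None = None):
    """Median-impute numeric features, mode-impute the rest (ties go to the
    lexicographically smallest value); returns the new table and the cell
    actions taken."""
    cfg = config or CurationConfig()
    df = table.df.copy()
    actions = []
    for d in descriptors:
        if "bad" in d.flags or d.missing_fraction > cfg.bad_missing_threshold:
            continue
        col = d.column_name
        if col not in df.columns:
            continue
        idx, vals = _nonmissing(df[col], cfg)
        if not vals:
            continue
        missing_rows = [i for i in range(len(df)) if i not in set(idx)]
        if not missing_rows:
            continue
        if d.observed_kind in ("numeric", "binary"):
            parsed = [p for p in (parse_numeric(v) for v in vals)
                      if p is not None]
            if d.observed_kind == "binary":
                ones = sum(v == "1" for v in vals)
                fill = "1" if ones > len(vals) - ones else "0"
            else:
                fill = _format_numeric(float(np.median(parsed)))
        else:
            counts: dict[str, int] = {}
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
            top = max(counts.values())
            fill = min(v for v, c in counts.items() if c == top)
        colpos = df.columns.get_loc(col)
        for r in missing_rows:
            df.iloc[r, colpos] = fill
            actions.append({"action": "impute", "row": r, "column": col,
                            "value": fill})
    return CohortTable(table.cohort_id, df), actions


@dataclass
class CurationReport:
    """Replayable record of everything curation did to one cohort."""

    cohort_id: str
    descriptors: list[FeatureDescriptor]
    n_bad: int = 0
    n_inconsistent: int = 0
    n_duplicate: int = 0
    n_outlier_cells: int = 0
    total_missing_pct: float = 0.0
    actions: list[dict] = field(default_factory=list)
    findings: list[Finding] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        for fd in d["descriptors"]:
            fd["flags"] = sorted(fd["flags"])
        return d

    def apply_actions(self, raw: CohortTable) -> CohortTable:
        """Replay the action log against the raw table."""
        df = raw.df.copy()
        for a in self.actions:
            if a["action"] == "drop_feature":
                df = df.drop(columns=[a["column"]])
            elif a["action"] == "blank":
                df.iloc[a["row"], df.columns.get_loc(a["column"])] = ""
            elif a["action"] == "impute":
                df.iloc[a["row"], df.columns.get_loc(a["column"])] = a["value"]
        return CohortTable(raw.cohort_id, df)


def curate(table: CohortTable, model=None,
           config: CurationConfig | None = None):
    """Full curation pipeline.

    Order: profile -> drop bad features (missing fraction above threshold,
    or constant) -> drop inconsistent features -> drop duplicate columns ->
    blank outlier cells (then treated as missing) -> impute.  Returns the
    curated table and a :class:`CurationReport` whose action log replays
    the transformation exactly.
    """
    cfg = config or CurationConfig()
    descriptors = profile(table, model, cfg)
    by_name = {d.column_name: d for d in descriptors}
    actions: list[dict] = []
    all_findings: list[Finding] = []

    df = table.df.copy()

    def drop(col: str, reason: str):
        nonlocal df
        df = df.drop(columns=[col])
        actions.append({"action": "drop_feature", "column": col,
                        "reason": reason})

    n_bad = 0
    for d in descriptors:
        if "bad" in d.flags:
            drop(d.column_name, "bad")
            n_bad += 1

    live = [by_name[c] for c in df.columns]
    inconsistent = detect_inconsistent(CohortTable(table.cohort_id, df),
                                       live, model, cfg)
    all_findings += inconsistent
    dropped_inc = set()
    for d in live:
        if "inconsistent" in d.flags:
            drop(d.column_name, "inconsistent")
            dropped_inc.add(d.column_name)

    dup = detect_duplicates(CohortTable(table.cohort_id, df), cfg)
    all_findings += dup
    n_dup = 0
    for f in dup:
        if f.rule in ("duplicate_name", "duplicate_values") \
                and f.feature in df.columns:
            by_name[f.feature].flags.add("duplicate")
            drop(f.feature, "duplicate")
            n_dup += 1

    if df.shape[1] == 0:
        raise CurationError("no usable features")

    live = [by_name[c] for c in df.columns]
    out_findings = detect_outliers(CohortTable(table.cohort_id, df), live, cfg)
    all_findings += out_findings
    n_outlier_cells = 0
    for f in out_findings:
        if f.rule != "outlier":
            continue
        colpos = df.columns.get_loc(f.feature)
        for r in f.cells:
            df.iloc[r, colpos] = ""
            actions.append({"action": "blank", "row": r, "column": f.feature})
            n_outlier_cells += 1

    # raw missingness of retained features (before blanking/imputation)
    retained = list(df.columns)
    raw_missing = sum(
        by_name[c].missing_fraction * table.n_rows for c in retained)
    total_missing_pct = 100.0 * raw_missing / (len(retained) * table.n_rows)

    work = CohortTable(table.cohort_id, df)
    live = profile(work, model, cfg)
    # carry observed kinds from the original profile; blanked cells must not
    # flip a numeric feature to categorical
    for d in live:
        d.observed_kind = by_name[d.column_name].observed_kind
    work, impute_actions = impute_missing(work, live, cfg)
    actions += impute_actions

    report = CurationReport(
        cohort_id=table.cohort_id,
        descriptors=descriptors,
        n_bad=n_bad,
        n_inconsistent=len(dropped_inc),
        n_duplicate=n_dup,
        n_outlier_cells=n_outlier_cells,
        total_missing_pct=total_missing_pct,
        actions=actions,
        findings=all_findings,
    )
    return work, report
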