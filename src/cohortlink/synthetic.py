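"""Synthetic multi-cohort studies with known ground truth.

Emulates the structure of a multi-centre rare-outcome study: several
cohorts that encode overlapping clinical concepts under lexically perturbed
column names and divergent value encodings, carry injected quality defects
(missingness, outliers, duplicated/bad/inconsistent columns), and share one
latent outcome model — a rare binary endpoint (~5% prevalence, the
lymphoma-in-Sjögren's setting) driven by a handful of signal features.

Because every rename, every defect and every label is recorded in the
:class:`StudyGroundTruth`, each pipeline stage's output can be scored
exactly: curation against the injected defects, harmonization against the
planted column->term map, and learning against the planted signal.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._text import normalized_form
from .curation import CohortTable
from .reference_model import (CLINICAL_SYNONYMS, MedicalCorpus,
                              ReferenceOntology, ReferenceTerm,
                              StaticSynonymSource, ValueDomain, build_corpus)

#: Catalogue of reference terms: (name, parent, kind, unit, range, categories).
#: The named lymphoma-signal features of the reference disease model
#: ("C4", "lymphadenopathy", "salivary gland swelling", "Anti-La", "gender",
#: "age") are always present so signal- and rule-recovery are measurable.
_CORE_CATALOGUE = [
    ("Demographics", None, "categorical", "", None, ["recorded"]),
    ("gender", "Demographics", "categorical", "", None, ["female", "male"]),
    ("age", "Demographics", "numeric", "years", (18.0, 90.0), None),
    ("Laboratory", None, "categorical", "", None, ["recorded"]),
    ("C4", "Laboratory", "numeric", "mg/dL", (4.0, 60.0), None),
    ("Anti-La", "Laboratory", "binary", "", None, None),
    ("Clinical", None, "categorical", "", None, ["recorded"]),
    ("lymphadenopathy", "Clinical", "binary", "", None, None),
    ("salivary gland swelling", "Clinical", "binary", "", None, None),
    ("Outcome", None, "categorical", "", None, ["recorded"]),
    ("lymphoma", "Outcome", "binary", "", None, None),
]

_FILLER_CATALOGUE = [
    ("C3", "Laboratory", "numeric", "mg/dL", (50.0, 200.0), None),
    ("rheumatoid factor", "Laboratory", "binary", "", None, None),
    ("ESR", "Laboratory", "numeric", "mm/h", (1.0, 100.0), None),
    ("IgG level", "Laboratory", "numeric", "mg/dL", (500.0, 2500.0), None),
    ("WBC count", "Laboratory", "numeric", "10^9/L", (2.0, 15.0), None),
    ("cryoglobulins", "Laboratory", "binary", "", None, None),
    ("ANA titer", "Laboratory", "numeric", "", (0.0, 1280.0), None),
    ("Anti-Ro", "Laboratory", "binary", "", None, None),
    ("dry mouth", "Clinical", "binary", "", None, None),
    ("dry eyes", "Clinical", "binary", "", None, None),
    ("raynaud phenomenon", "Clinical", "binary", "", None, None),
    ("purpura", "Clinical", "binary", "", None, None),
    ("parotid enlargement", "Clinical", "binary", "", None, None),
    ("arthritis", "Clinical", "binary", "", None, None),
    ("fatigue", "Clinical", "binary", "", None, None),
    ("skin involvement", "Clinical", "binary", "", None, None),
    ("renal involvement", "Clinical", "binary", "", None, None),
    ("peripheral neuropathy", "Clinical", "binary", "", None, None),
    ("schirmer test", "Clinical", "numeric", "mm", (0.0, 35.0), None),
    ("smoking status", "Demographics", "categorical", "", None,
     ["never", "former", "current"]),
]

#: Default planted signal: per-feature log-odds on the latent scale
#: (binary features enter as 0/1, numeric features standardized).  Low C4
#: is the risk direction, matching its clinical role.
DEFAULT_EFFECTS = {
    "lymphadenopathy": 2.6,
    "salivary gland swelling": 2.3,
    "Anti-La": 2.0,
    "C4": -1.8,
    "gender": 0.9,       # male = 1 after reference coding
    "age": 0.4,          # per standardized year
}

#: Columns whose names are only lightly perturbed and never made defective:
#: endpoints and demographics are the best-standardized fields in practice.
PROTECTED = ("lymphoma", "age", "gender")


class SyntheticError(ValueError):
    pass


def generate_reference(n_terms: int = 26, depth: int = 3,
                       seed: int = 0) -> ReferenceOntology:
    """Random disease reference model around the fixed clinical core.

    ``depth`` >= 3 inserts intermediate classes (serology under Laboratory,
    symptoms under Clinical) so class paths have three levels.  Two calls
    with the same arguments produce identical models.
    """
    if n_terms < 2:
        raise SyntheticError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    rows = list(_CORE_CATALOGUE)
    if n_terms > len(rows):
        extra = min(n_terms - len(rows), len(_FILLER_CATALOGUE))
        picks = rng.choice(len(_FILLER_CATALOGUE), size=extra, replace=False)
        rows += [_FILLER_CATALOGUE[i] for i in sorted(picks)]
    else:
        rows = rows[:n_terms]
    terms = []
    names = {r[0] for r in rows}
    inserted: dict[str, str] = {}
    if depth >= 3 and n_terms > len(_CORE_CATALOGUE):
        inserted = {"Laboratory": "serology", "Clinical": "symptoms"}
    for name, parent, kind, unit, rng_, cats in rows:
        if parent is not None and parent not in names:
            parent = None
        if name in ("Anti-La", "Anti-Ro", "ANA titer", "rheumatoid factor") \
                and "Laboratory" in inserted:
            parent = "serology"
        if name in ("dry mouth", "dry eyes", "fatigue") \
                and "Clinical" in inserted:
            parent = "symptoms"
        terms.append(ReferenceTerm(
            name=name,
            domain=ValueDomain(kind=kind, unit=unit,
                               numeric_range=rng_,
                               categories=tuple(cats) if cats else None),
            parent=parent))
    if inserted:
        out = []
        for t in terms:
            out.append(t)
            if t.name == "Laboratory":
                out.append(ReferenceTerm(
                    "serology", ValueDomain("categorical",
                                            categories=("recorded",)),
                    parent="Laboratory"))
            if t.name == "Clinical":
                out.append(ReferenceTerm(
                    "symptoms", ValueDomain("categorical",
                                            categories=("recorded",)),
                    parent="Clinical"))
        terms = out
    return ReferenceOntology(terms, name="synthetic-disease-model",
                             version="1.0")


@dataclass
class PerturbationConfig:
    edit_fraction: float = 0.10       # character edits per name length
    synonym_swap_prob: float = 0.20
    case_noise_prob: float = 0.5
    separator_noise_prob: float = 0.5


@dataclass
class DefectConfig:
    missing_rate: float = 0.0         # MCAR, per cell, non-protected columns
    outlier_rate: float = 0.0         # per cell, signal-free numeric columns
    n_duplicate_cols: int = 0
    n_bad_cols: int = 0
    n_inconsistent_cols: int = 0


@dataclass
class OutcomeConfig:
    prevalence: float = 0.05
    effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    min_cases: int = 4                # rejection-sample the outcome vector

    def __post_init__(self):
        if not 0 < self.prevalence < 0.5:
            raise SyntheticError("prevalence must lie in (0, 0.5)")


@dataclass
class GeneratorConfig:
    n_cohorts: int = 4
    rows: tuple[int, ...] = (200, 200, 100, 100)
    n_terms: int = 26
    depth: int = 3
    term_presence_prob: float = 0.9
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    # per-cohort missingness spans the band reported for real registries
    defects: tuple[DefectConfig, ...] = field(default_factory=lambda: (
        DefectConfig(missing_rate=0.35, n_duplicate_cols=1, n_bad_cols=2,
                     n_inconsistent_cols=1, outlier_rate=0.002),
        DefectConfig(missing_rate=0.30, n_duplicate_cols=1, n_bad_cols=1,
                     n_inconsistent_cols=1, outlier_rate=0.002),
        DefectConfig(missing_rate=0.22, n_bad_cols=1),
        DefectConfig(missing_rate=0.17),
    ))
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_cohorts < 2:
            raise SyntheticError("need at least 2 cohorts")
        if len(self.rows) < self.n_cohorts:
            self.rows = tuple(self.rows) + (self.rows[-1],) * (
                self.n_cohorts - len(self.rows))
        if len(self.defects) < self.n_cohorts:
            self.defects = tuple(self.defects) + (DefectConfig(),) * (
                self.n_cohorts - len(self.defects))


@dataclass
class CohortGroundTruth:
    cohort_id: str
    column_map: dict[str, str]                # observed column -> term
    labels: np.ndarray
    clean: CohortTable                        # canonical names/encodings
    duplicate_cols: list[tuple[str, str]] = field(default_factory=list)
    bad_cols: list[str] = field(default_factory=list)
    inconsistent_cols: list[str] = field(default_factory=list)
    outlier_cells: list[tuple[int, str]] = field(default_factory=list)
    n_missing: int = 0


@dataclass
class StudyGroundTruth:
    model: ReferenceOntology
    corpus: MedicalCorpus
    effects: dict[str, float]
    intercept: float
    prevalence: float
    cohorts: dict[str, CohortGroundTruth] = field(default_factory=dict)


class _LatentModel:
    """Shared per-study sampling distributions and outcome model."""

    def __init__(self, model: ReferenceOntology, outcome: OutcomeConfig,
                 rng: np.random.Generator):
        self.model = model
        self.outcome = outcome
        leaves = [t for t in model.terms if not model.children(t.name)]
        self.columns = [t for t in leaves if t.name != "lymphoma"]
        self.binary_p = {}
        self.cat_p = {}
        for t in self.columns:
            if t.domain.kind == "binary":
                self.binary_p[t.name] = float(rng.uniform(0.15, 0.40))
            elif t.domain.kind == "categorical":
                k = len(t.domain.categories)
                self.cat_p[t.name] = rng.dirichlet(np.full(k, 2.0))
        self.intercept = self._calibrate(rng)

    def sample_covariates(self, n: int, rng: np.random.Generator
                          ) -> dict[str, np.ndarray]:
        out = {}
        for t in self.columns:
            d = t.domain
            if d.kind == "numeric":
                low, high = d.numeric_range
                mid, sd = (low + high) / 2.0, (high - low) / 6.0
                out[t.name] = np.clip(rng.normal(mid, sd, n), low, high)
            elif d.kind == "binary":
                out[t.name] = rng.binomial(1, self.binary_p[t.name], n)
            else:
                cats = np.arange(len(d.categories))
                out[t.name] = rng.choice(cats, size=n, p=self.cat_p[t.name])
        return out

    def linear_predictor(self, cov: dict[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(cov.values())))
        lp = np.zeros(n)
        for name, beta in self.outcome.effects.items():
            if name not in cov:
                continue
            t = self.model[name]
            x = np.asarray(cov[name], dtype=float)
            if t.domain.kind == "numeric":
                low, high = t.domain.numeric_range
                x = (x - (low + high) / 2.0) / ((high - low) / 6.0)
            lp += beta * x
        return lp

    def _calibrate(self, rng: np.random.Generator) -> float:
        cov = self.sample_covariates(20000, rng)
        lp = self.linear_predictor(cov)
        lo, hi = -30.0, 10.0
        for _ in range(80):
            mid = (lo + hi) / 2.0
            p = 1.0 / (1.0 + np.exp(-(lp + mid)))
            if p.mean() > self.outcome.prevalence:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2.0

    def sample_outcome(self, cov, rng: np.random.Generator) -> np.ndarray:
        lp = self.linear_predictor(cov) + self.intercept
        p = 1.0 / (1.0 + np.exp(-lp))
        for _ in range(200):
            y = rng.binomial(1, p)
            if y.sum() >= self.outcome.min_cases:
                return y
        raise SyntheticError("could not reach the minimum case count")


def _fmt(domain: ValueDomain, value) -> str:
    if domain.kind == "numeric":
        return f"{float(value):.2f}"
    if domain.kind == "binary":
        return str(int(value))
    return domain.categories[int(value)]


_BINARY_VARIANTS = [("0", "1"), ("no", "yes"), ("false", "true"),
                    ("absent", "present")]


def _perturb_name(name: str, corpus: MedicalCorpus, pcfg: PerturbationConfig,
                  rng: np.random.Generator, protected: bool) -> str:
    out = name
    if not protected and rng.random() < pcfg.synonym_swap_prob:
        entry = corpus.entries.get(name)
        if entry:
            others = [s for s in entry.synonyms if s != name]
            if others:
                out = others[int(rng.integers(len(others)))]
    if not protected:
        n_edits = int(pcfg.edit_fraction * len(out))
        letters = string.ascii_lowercase
        for _ in range(n_edits):
            pos = int(rng.integers(len(out)))
            op = rng.random()
            if op < 0.4 and len(out) > 3:          # deletion
                out = out[:pos] + out[pos + 1:]
            elif op < 0.7:                          # substitution
                out = out[:pos] + letters[int(rng.integers(26))] + out[pos + 1:]
            else:                                   # insertion
                out = out[:pos] + letters[int(rng.integers(26))] + out[pos:]
    if rng.random() < pcfg.case_noise_prob:
        style = int(rng.integers(3))
        out = [out, out.title(), out.upper()][style]
    if rng.random() < pcfg.separator_noise_prob:
        sep = "_" if rng.random() < 0.5 else "-"
        out = out.replace(" ", sep)
    return out


def generate_cohort(latent: _LatentModel, corpus: MedicalCorpus,
                    cfg: GeneratorConfig, cohort_index: int,
                    rng: np.random.Generator
                    ) -> tuple[CohortTable, CohortGroundTruth]:
    """One cohort table plus the ground truth that scores it."""
    n = cfg.rows[cohort_index]
    dcfg = cfg.defects[cohort_index]
    cohort_id = f"cohort_{cohort_index}"
    cov = latent.sample_covariates(n, rng)
    y = latent.sample_outcome(cov, rng)

    # clean canonical table
    clean_cols = {}
    present_terms = []
    # endpoints, demographics and the core signal features are recorded in
    # every cohort (as in the real multi-centre study); filler terms are
    # present with the configured probability
    always = set(PROTECTED) | set(latent.outcome.effects)
    for t in latent.columns:
        if t.name not in always and rng.random() > cfg.term_presence_prob:
            continue
        present_terms.append(t.name)
        clean_cols[t.name] = [_fmt(t.domain, v) for v in cov[t.name]]
    clean_cols["lymphoma"] = [str(int(v)) for v in y]
    present_terms.append("lymphoma")
    clean = CohortTable(cohort_id, pd.DataFrame(clean_cols))

    # perturbed names, unique post-normalization
    column_map: dict[str, str] = {}
    data: dict[str, list[str]] = {}
    taken: set[str] = set()
    for term in present_terms:
        protected = term in PROTECTED
        for _ in range(20):
            new = _perturb_name(term, corpus, cfg.perturbation, rng, protected)
            if normalized_form(new) and normalized_form(new) not in taken:
                break
        else:
            new = term
        taken.add(normalized_form(new))
        column_map[new] = term
        data[new] = list(clean_cols[term])

    # divergent value encodings (binary variants, category case styles)
    for new, term in column_map.items():
        d = latent.model[term].domain
        if d.kind == "binary" and term != "lymphoma":
            neg, pos = _BINARY_VARIANTS[int(rng.integers(len(_BINARY_VARIANTS)))]
            data[new] = [pos if v == "1" else neg for v in data[new]]
        elif d.kind == "categorical" and rng.random() < 0.5:
            data[new] = [v.title() for v in data[new]]

    truth = CohortGroundTruth(cohort_id=cohort_id, column_map=column_map,
                              labels=y, clean=clean)

    # injected defects (locations recorded)
    signal = set(latent.outcome.effects)
    numeric_free = [c for c, t in column_map.items()
                    if latent.model[t].domain.kind == "numeric"
                    and t not in signal and t not in PROTECTED]
    if dcfg.outlier_rate > 0:
        for col in numeric_free:
            term = column_map[col]
            low, high = latent.model[term].domain.numeric_range
            k = int(round(dcfg.outlier_rate * n))
            for r in rng.choice(n, size=k, replace=False):
                data[col][int(r)] = f"{high + 10 * (high - low):.2f}"
                truth.outlier_cells.append((int(r), col))
    dup_candidates = [c for c in column_map
                      if column_map[c] not in PROTECTED]
    for k in range(dcfg.n_duplicate_cols):
        if not dup_candidates:
            break
        src = dup_candidates[int(rng.integers(len(dup_candidates)))]
        name = f"{src} ({k + 2})"
        data[name] = list(data[src])
        truth.duplicate_cols.append((name, src))
    for k in range(dcfg.n_bad_cols):
        name = f"extra field {k + 1}"
        vals = [f"{rng.normal():.3f}" for _ in range(n)]
        blank = rng.choice(n, size=int(0.8 * n), replace=False)
        for r in blank:
            vals[int(r)] = ""
        data[name] = vals
        truth.bad_cols.append(name)
    for k in range(dcfg.n_inconsistent_cols):
        name = f"free note {k + 1}"
        vals = [f"{rng.normal(10, 2):.2f}" for _ in range(n)]
        junk = rng.choice(n, size=max(1, int(0.1 * n)), replace=False)
        for r in junk:
            vals[int(r)] = "err"
        data[name] = vals
        truth.inconsistent_cols.append(name)
    if dcfg.missing_rate > 0:
        spiked = {}
        for r, col in truth.outlier_cells:
            spiked.setdefault(col, set()).add(r)
        for col, term in column_map.items():
            # defects go to signal-free columns only, so defect handling and
            # signal recovery stay separately measurable
            if term in PROTECTED or term in signal:
                continue
            mask = rng.random(n) < dcfg.missing_rate
            for r in np.flatnonzero(mask):
                if r in spiked.get(col, ()):  # keep injected outliers visible
                    continue
                data[col][r] = ""
                truth.n_missing += 1

    table = CohortTable(cohort_id, pd.DataFrame(data))
    return table, truth


def generate_study(config: GeneratorConfig | None = None
                   ) -> tuple[list[CohortTable], StudyGroundTruth]:
    """Generate a full multi-cohort study.

    Cohorts share the latent outcome model but differ in schemas,
    encodings, defect rates and sizes; default sizes (200, 200, 100, 100)
    echo a 3-train/1-test split at desk scale.  Byte-identical outputs for
    identical ``(config, seed)``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    model = generate_reference(cfg.n_terms, cfg.depth,
                               seed=int(rng.integers(2**31)))
    corpus = build_corpus(model, StaticSynonymSource(CLINICAL_SYNONYMS))
    latent = _LatentModel(model, cfg.outcome, rng)
    cohorts, truth = [], StudyGroundTruth(
        model=model, corpus=corpus, effects=dict(cfg.outcome.effects),
        intercept=latent.intercept, prevalence=cfg.outcome.prevalence)
    for i in range(cfg.n_cohorts):
        table, ct = generate_cohort(latent, corpus, cfg, i, rng)
        cohorts.append(table)
        truth.cohorts[table.cohort_id] = ct
    return cohorts, truth


def study_to_spaces(cohorts: list[CohortTable], truth: StudyGroundTruth,
                    curation_config=None, harmonization_config=None):
    """Full pipeline glue: curate and harmonize every cohort, restrict to
    the shared schema, and wrap each as a private space.

    Returns ``(spaces dict, harmonized tables, mappings, schema)``.
    """
    from .curation import curate
    from .federated import FederatedError, PrivateSpace
    from .harmonization import common_schema, harmonize

    harmonized, mappings = [], []
    for table in cohorts:
        curated, _ = curate(table, truth.model, curation_config)
        h, mapping, _ = harmonize(curated, truth.corpus, harmonization_config)
        harmonized.append(h)
        mappings.append(mapping)
    schema = common_schema(harmonized)
    for required in PROTECTED:
        if required not in schema:
            raise FederatedError(
                f"required column {required!r} lost during harmonization")
    aligned = [CohortTable(h.cohort_id, h.df[schema].copy())
               for h in harmonized]
    spaces = {h.cohort_id: PrivateSpace.from_harmonized(h, truth.corpus)
              for h in aligned}
    return spaces, aligned, mappings, schema
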