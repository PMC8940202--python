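# cohortlink

Multi-centre clinical registries describe the same patients in
incompatible ways: each cohort names its variables differently
(`Anti-La`, `anti_la`, `ANTI LA`), encodes them differently (`yes/no`,
`0/1`, `present/absent`) and carries its own quality defects — duplicated
and half-empty columns, unparseable cells, outliers, heavy missingness.
That heterogeneity blocks the pooled analyses that rare outcomes need
most. `cohortlink` is a toolkit for that problem, built around the
lymphoma-in-Sjögren's setting (a binary endpoint affecting ~5% of
patients, spread across several small cohorts that cannot be centralized):

1. **Curation** — per-cohort quality enhancement: bad / inconsistent /
   duplicated feature detection, IQR-fence outlier flagging, median/mode
   imputation, all recorded in a replayable action log.
2. **Harmonization** — ontology-driven terminology alignment. A disease
   *reference model* (term hierarchy + value domains, JSON) is flattened
   into a synonym-enriched *medical corpus*; cohort columns are linked to
   reference terms by lexical matching (normalized Levenshtein similarity,
   greedy injective assignment at threshold 0.80) and, for the residue, by
   semantic matching (token/synonym/class-path composite at 0.60); matched
   values are standardized into the reference domains.
3. **Consistency** — PCA is fitted on the integrated dataset and each
   cohort's first-two-PC score distributions are compared against the
   remaining cohorts with the two-sided Wilcoxon rank-sum test.
4. **Federated incremental learning** — five classifier families (XGBoost,
   linear SVM, logistic regression, multinomial naive Bayes, MLP) trained
   across per-cohort private spaces: fit on the first space, update
   incrementally through the rest, evaluate on a full held-out cohort.
   Class imbalance is handled by 1:2 age/sex-matched control
   downsampling per training space, repeated over 5 seeded runs; clinical
   decision rules are distilled from the boosted model.
5. **Synthetic studies** — a generator that emulates the whole setting
   (perturbed schemas, divergent encodings, injected defects, a planted
   rare-outcome signal) with complete ground truth, so every stage is
   testable end to end.

## Worked example

```bash
python examples/05_incremental_learning.py
```

```
4 cohorts harmonized to a shared schema of 16 terms
xgboost, 5 runs, held-out cohort_3:
  auc          0.907 +/- 0.027
  accuracy     0.856 +/- 0.011
  sensitivity  0.550 +/- 0.112
  specificity  0.869 +/- 0.016
label-shuffled control AUC: 0.524 (chance level - the signal is real)
top gain-ranked features: ['C4', 'salivary gland swelling', 'ANA titer', 'lymphadenopathy', 'renal involvement']
  C4 <= 0.43 ?
    yes: C4 <= 0.28 ?
    ...
```

Four heterogeneous synthetic cohorts (200/200/100/100 patients, ~5%
lymphoma prevalence) are curated, harmonized to one schema, and used to
train an incremental XGBoost model on three cohorts and evaluate it on the
held-out fourth. The mean AUC of 0.907 over five matched-downsampling
runs says the model ranks a random future case above a random control 91%
of the time; the shuffled-label control at 0.524 confirms the performance
comes from the planted clinical signal, not leakage. The distilled rule
tree splits on low complement C4 and lymphadenopathy — exactly the
features the generator planted as risk factors (thresholds are on the
model's [0,1]-scaled inputs).

The other examples (`examples/01`–`04`) walk the corpus construction,
curation, harmonization and consistency stages individually, each printing
what it computes and recovering the generator's ground truth.

A thin CLI mirrors the stages:

```bash
cohortlink simulate --outdir fixtures --seed 0
cohortlink corpus --model fixtures/reference_model.json --out corpus.json --enrich
cohortlink curate --in fixtures/cohort_0.csv --model fixtures/reference_model.json \
    --out curated.csv --report report.json
cohortlink harmonize --in curated.csv --corpus corpus.json --out harmonized.csv
cohortlink check --cohorts a.csv --cohorts b.csv --report consistency.json
cohortlink train --plan plan.yaml --out results.json
```

## Layout

```
src/cohortlink/
  reference_model.py   reference model, ontology view, medical corpus
  curation.py          quality profiling, findings, imputation, reports
  harmonization.py     lexical/semantic matching, value standardization
  consistency.py       integrated-basis PCA + rank-sum homogeneity checks
  federated.py         matched downsampling, incremental models, evaluation
  synthetic.py         ground-truthed multi-cohort study generator
  cli.py               thin command-line wrapper
docs/methods.md        models, assumptions, parameter choices, limitations
examples/              one narrative script per capability
tests/                 pytest suite (unit, property, acceptance)
```
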