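"""Curate a cohort table carrying injected quality defects.

The generator plants duplicated columns, mostly-empty columns, columns with
unparseable cells, extreme outlier cells and missing values — and records
where.  Curation finds them, drops/blanks/imputes, and its report replays
the whole transformation.
"""

import cohortlink as cl
from cohortlink.synthetic import DefectConfig, GeneratorConfig, PerturbationConfig

cfg = GeneratorConfig(
    seed=11, n_cohorts=2, rows=(200, 50),
    perturbation=PerturbationConfig(edit_fraction=0.0, synonym_swap_prob=0.0),
    defects=(DefectConfig(missing_rate=0.2, n_duplicate_cols=1,
                          n_bad_cols=2, n_inconsistent_cols=1,
                          outlier_rate=0.01),
             DefectConfig()))
cohorts, truth = cl.generate_study(cfg)
raw = cohorts[0]
gt = truth.cohorts["cohort_0"]

curated, report = cl.curate(raw, truth.model)
print(f"{raw.cohort_id}: {raw.df.shape[1]} raw columns -> "
      f"{curated.df.shape[1]} curated")
print(f"bad features dropped:      {report.n_bad} "
      f"(injected {len(gt.bad_cols)})")
print(f"inconsistent dropped:      {report.n_inconsistent} "
      f"(injected {len(gt.inconsistent_cols)})")
print(f"duplicates dropped:        {report.n_duplicate} "
      f"(injected {len(gt.duplicate_cols)})")
print(f"outlier cells blanked:     {report.n_outlier_cells} "
      f"(injected {len(gt.outlier_cells)})")
print(f"missingness before:        {report.total_missing_pct:.1f}% "
      f"-> 0% after imputation")

# the action log replays the raw table into the curated one exactly
replayed = report.apply_actions(raw)
assert replayed.df.equals(curated.df)
print(f"replayed {len(report.actions)} actions: curated table reproduced")
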