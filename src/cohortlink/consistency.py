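"""Post-harmonization homogeneity checks.

After harmonization all cohorts share one schema; if harmonization worked,
each cohort's patients should occupy the same region of feature space as
the pooled, integrated dataset.  The check here fits a PCA on the
integrated (row-concatenated) data, projects every cohort into that common
basis, and compares the distribution of each cohort's first two principal
component scores against the scores of the remaining cohorts with the
two-sided Wilcoxon rank-sum test.  Large p-values (above ``alpha``) mean
the score distributions are statistically indistinguishable — the
harmonized cohorts are mutually consistent.

Comparing a cohort against the pool *excluding itself* keeps the two
samples disjoint, so the rank-sum test retains its nominal type-I error
rate; with a single cohort the comparison degenerates to cohort-vs-itself
and passes trivially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .curation import CohortTable


class ConsistencyError(ValueError):
    pass


def _numeric_matrix(df: pd.DataFrame) -> np.ndarray:
    return df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)


def first_two_pcs(data, return_loadings: bool = False):
    """First two principal components of a z-scored numeric matrix.

    Columns are standardized to mean 0 / sd 1 (zero-variance columns are
    dropped with a warning); components come from the eigendecomposition of
    the covariance matrix, ordered by decreasing eigenvalue, with the sign
    convention that each component's largest-magnitude loading is positive.

    Returns ``(scores (n, 2), explained_variance_shares (2,))``.
    """
    X = _numeric_matrix(data.df if isinstance(data, CohortTable) else
                        pd.DataFrame(data))
    if X.shape[0] < 3:
        raise ConsistencyError("need at least 3 rows for PCA")
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(X, axis=0)
            sd = np.nanstd(X, axis=0, ddof=1)
    mu, sd = np.nan_to_num(mu), np.nan_to_num(sd)
    keep = sd > 0
    if keep.sum() < 2:
        raise ConsistencyError("need at least 2 numeric non-constant columns")
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    Z = np.nan_to_num(Z)  # residual missing cells contribute the mean
    cov = np.cov(Z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    comps = eigvecs[:, :2].copy()
    for k in range(2):
        j = np.argmax(np.abs(comps[:, k]))
        if comps[j, k] < 0:
            comps[:, k] = -comps[:, k]
    scores = Z @ comps
    shares = eigvals[:2] / eigvals.sum()
    if return_loadings:
        return scores, shares, comps, (mu, sd, keep)
    return scores, shares


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the sum of the ranks of ``x`` in the pooled ranking
    (midranks for ties).  The p-value is exact (enumeration over rank
    assignments) when the pooled size is at most 12 and there are no ties,
    otherwise a normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConsistencyError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    m, n = x.size, y.size
    N = m + n
    W = float(ranks[:m].sum())
    mu = m * (N + 1) / 2.0
    has_ties = np.unique(pooled).size < N
    if N <= 12 and not has_ties:
        dev = abs(W - mu)
        count = 0
        total = 0
        for combo in combinations(range(1, N + 1), m):
            total += 1
            if abs(sum(combo) - mu) >= dev - 1e-12:
                count += 1
        return W, count / total
    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (N * (N - 1))
                if N > 1 else 0.0)
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return W, 1.0
    z = max(0.0, abs(W - mu) - 0.5) / math.sqrt(var)
    return W, min(1.0, 2.0 * norm.sf(z))


@dataclass
class ComponentTest:
    cohort_id: str
    component: int            # 1 or 2
    statistic: float
    p_value: float
    passed: bool


@dataclass
class ConsistencyReport:
    alpha: float
    tests: list[ComponentTest]
    explained_variance: dict[str, list[float]]   # dataset id -> [PC1, PC2]
    overall_pass: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def consistency_check(cohorts: list[CohortTable],
                      alpha: float = 0.05) -> ConsistencyReport:
    """Rank-sum comparison of each cohort's PC scores against the rest.

    All cohorts must share the harmonized schema.  PCA is fitted once on
    the integrated dataset; each cohort's scores are its own rows'
    projections in that basis.  A cohort passes on a component when the
    two-sided rank-sum p-value exceeds ``alpha``; the report passes overall
    when every per-cohort/per-component test passes.
    """
    if not cohorts:
        raise ConsistencyError("no cohorts")
    ref_cols = list(cohorts[0].df.columns)
    for c in cohorts[1:]:
        if list(c.df.columns) != ref_cols:
            diff = set(c.df.columns) ^ set(ref_cols)
            raise ConsistencyError(
                f"schema mismatch between {cohorts[0].cohort_id!r} and "
                f"{c.cohort_id!r}: {sorted(diff)}")
    integrated = CohortTable(
        "integrated", pd.concat([c.df for c in cohorts], ignore_index=True))
    scores, shares = first_two_pcs(integrated)
    ev = {"integrated": [float(shares[0]), float(shares[1])]}
    # per-cohort explained variance of its own first two PCs
    for c in cohorts:
        try:
            _, s = first_two_pcs(c)
            ev[c.cohort_id] = [float(s[0]), float(s[1])]
        except ConsistencyError:
            ev[c.cohort_id] = [float("nan"), float("nan")]

    offsets = np.cumsum([0] + [len(c.df) for c in cohorts])
    tests = []
    for i, c in enumerate(cohorts):
        own = scores[offsets[i]:offsets[i + 1]]
        rest = np.concatenate([scores[:offsets[i]], scores[offsets[i + 1]:]])
        if rest.shape[0] == 0:       # single cohort: compare with itself
            rest = own
        for k in (0, 1):
            stat, p = rank_sum_test(own[:, k], rest[:, k])
            tests.append(ComponentTest(c.cohort_id, k + 1, stat, p, p > alpha))
    return ConsistencyReport(
        alpha=alpha,
        tests=tests,
        explained_variance=ev,
        overall_pass=all(t.passed for t in tests),
    )
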