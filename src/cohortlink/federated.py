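"""Incremental learning across private data partitions.

Each harmonized cohort lives in its own *private space*; only model state
moves between spaces.  A model is fitted on the first training space,
incrementally updated through the remaining ones in order, and evaluated on
the full held-out test space.  Five classifier families are supported, each
behind the same :class:`IncrementalModel` contract:

``multinomial_nb``
    Class/feature count accumulation (``partial_fit``); sequential updates
    are *exactly* equivalent to a pooled single-batch fit.
``logistic`` / ``svm_linear``
    Stochastic-gradient surrogates (log / hinge loss) updated by additional
    gradient passes on each batch.
``mlp``
    Multi-layer perceptron whose weights continue from their current values
    on every new batch.
``xgboost``
    New boosting rounds are appended per batch, using the existing ensemble
    as the starting margin.

Class imbalance is handled as in rare-outcome case/control studies: per
training space the controls are downsampled to ``ratio`` (default 2)
age/sex-matched controls per case; the test space is never downsampled.
Features are min-max scaled to [0, 1] with parameters frozen on the first
training batch (multinomial NB requires nonnegative inputs; the same
scaling is applied to every algorithm for comparability).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeRegressor

from .curation import CohortTable
from .reference_model import MedicalCorpus

ALGORITHMS = ("xgboost", "svm_linear", "logistic", "multinomial_nb", "mlp")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "xgboost": [{"rounds": r, "depth": d, "eta": e}
                for r in (25, 50) for d in (2, 3) for e in (0.1, 0.3)],
    "svm_linear": [{"alpha": a} for a in (1e-4, 1e-3, 1e-2)],
    "logistic": [{"alpha": a} for a in (1e-4, 1e-3, 1e-2)],
    "multinomial_nb": [{"alpha": 0.5}, {"alpha": 1.0}],
    "mlp": [{"hidden": (16,), "epochs": 20}, {"hidden": (32,), "epochs": 20}],
}

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "xgboost": {"rounds": 50, "depth": 3, "eta": 0.3},
    "svm_linear": {"alpha": 1e-3},
    "logistic": {"alpha": 1e-3},
    "multinomial_nb": {"alpha": 1.0},
    "mlp": {"hidden": (16,), "epochs": 20},
}


class FederatedError(ValueError):
    pass


@dataclass
class PrivateSpace:
    """One cohort's local partition: numeric design matrix, binary outcome
    (0 = no, 1 = yes), and the demographics used for control matching."""

    space_id: str
    X: pd.DataFrame
    y: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self):
        vals = set(np.unique(self.y).tolist())
        if not vals <= {0, 1}:
            raise FederatedError(
                f"outcome of {self.space_id!r} is not binary 0/1: {vals}")

    @classmethod
    def from_harmonized(cls, table: CohortTable, corpus: MedicalCorpus,
                        outcome: str = "lymphoma", age: str = "age",
                        sex: str = "gender") -> "PrivateSpace":
        """Encode a harmonized table: numeric/binary columns as floats,
        categorical columns as reference-ordered integer codes, date
        columns dropped."""
        df = table.df
        if outcome not in df.columns:
            raise FederatedError(f"outcome column {outcome!r} missing")
        cols = {}
        for col in df.columns:
            if col == outcome:
                continue
            kind = (corpus.entries[col].domain.kind
                    if col in corpus.entries else "numeric")
            if kind == "date":
                continue
            if kind == "categorical":
                cats = list(corpus.entries[col].domain.categories)
                cols[col] = [float(cats.index(str(v).strip()))
                             if str(v).strip() in cats else np.nan
                             for v in df[col].to_numpy()]
            else:
                cols[col] = pd.to_numeric(df[col], errors="coerce")
        X = pd.DataFrame(cols)
        X = X.fillna(X.median(numeric_only=True)).fillna(0.0)
        y = pd.to_numeric(df[outcome], errors="coerce").fillna(0).astype(int)
        age_arr = (X[age].to_numpy(dtype=float) if age in X.columns
                   else np.zeros(len(df)))
        sex_arr = (X[sex].to_numpy() if sex in X.columns
                   else np.zeros(len(df)))
        return cls(table.cohort_id, X, y.to_numpy(), age_arr, sex_arr)

    def subset(self, rows) -> tuple[pd.DataFrame, np.ndarray]:
        rows = np.asarray(rows)
        return self.X.iloc[rows], self.y[rows]


@dataclass
class TrainingPlan:
    """One incremental training/testing configuration."""

    train_spaces: list[str]
    test_space: str
    algorithm: str = "xgboost"
    n_runs: int = 5
    control_ratio: int = 2
    seeds: list[int] | None = None
    grid: list[dict] | None = None
    tune: bool = True

    def __post_init__(self):
        if self.test_space in self.train_spaces:
            raise FederatedError("test space must not be a training space")
        if self.algorithm not in ALGORITHMS:
            raise FederatedError(f"unknown algorithm {self.algorithm!r}")
        if self.n_runs < 1 or self.control_ratio < 1:
            raise FederatedError("n_runs and control_ratio must be >= 1")
        if self.seeds is None:
            self.seeds = list(range(self.n_runs))
        if len(self.seeds) != self.n_runs:
            raise FederatedError("need one seed per run")


def match_controls(space: PrivateSpace, ratio: int = 2, seed: int = 0):
    """Age/sex-matched control downsampling at 1:``ratio``.

    Case order is randomized by ``seed``; each case greedily takes the
    ``ratio`` same-sex controls with minimal absolute age difference (ties
    to the smaller row index), without replacement.  When same-sex controls
    run out the nearest-age control of any sex is taken and a warning
    recorded; when controls run out entirely, all controls are returned
    with an insufficiency warning.

    Returns ``(control_indices, warnings, mean_age_gap)``.
    """
    cases = np.flatnonzero(space.y == 1)
    if cases.size == 0:
        raise FederatedError(f"no positive class in {space.space_id!r}")
    controls = set(np.flatnonzero(space.y == 0).tolist())
    rng = np.random.default_rng(seed)
    order = rng.permutation(cases)
    selected: list[int] = []
    warnings: list[str] = []
    gaps: list[float] = []
    for case in order:
        for _ in range(ratio):
            if not controls:
                warnings.append("controls exhausted: returning all controls")
                return sorted(selected), warnings, float(np.mean(gaps) if gaps else 0.0)
            same_sex = [c for c in controls if space.sex[c] == space.sex[case]]
            pool = same_sex
            if not pool:
                pool = list(controls)
                warnings.append(
                    f"no same-sex control left for case row {int(case)}; "
                    "falling back to any-sex nearest age")
            best = min(pool, key=lambda c: (abs(space.age[c] - space.age[case]), c))
            controls.discard(best)
            selected.append(int(best))
            gaps.append(float(abs(space.age[best] - space.age[case])))
    return sorted(selected), warnings, float(np.mean(gaps) if gaps else 0.0)


def matched_batch(space: PrivateSpace, ratio: int = 2, seed: int = 0):
    """Cases plus their matched controls as one training batch."""
    controls, warnings, gap = match_controls(space, ratio, seed)
    rows = np.sort(np.concatenate(
        [np.flatnonzero(space.y == 1), np.asarray(controls, dtype=int)]))
    X, y = space.subset(rows)
    return X, y, warnings, gap


@dataclass
class IncrementalModel:
    """Algorithm-agnostic handle over a partially fitted classifier."""

    algorithm: str
    estimator: object
    feature_names: list[str]
    scaler: tuple[np.ndarray, np.ndarray]     # frozen (min, span) of batch 1
    hyperparams: dict
    seed: int
    n_batches_seen: int = 0
    trained_on: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def scale(self, X: pd.DataFrame) -> np.ndarray:
        lo, span = self.scaler
        Z = (X[self.feature_names].to_numpy(dtype=float) - lo) / span
        return np.clip(Z, 0.0, 1.0)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Class-1 probability scores."""
        if self.n_batches_seen < 1:
            raise FederatedError("model has seen no batch")
        Z = self.scale(X)
        if self.algorithm == "xgboost":
            return self.estimator.predict(
                xgb.DMatrix(Z, feature_names=self.feature_names))
        if self.algorithm == "svm_linear":
            d = self.estimator.decision_function(Z)
            return 1.0 / (1.0 + np.exp(-d))
        return self.estimator.predict_proba(Z)[:, 1]


def _check_two_classes(y) -> None:
    if np.unique(y).size < 2:
        raise FederatedError("batch contains a single class")


def _xgb_params(hp: dict, seed: int) -> dict:
    return {"objective": "binary:logistic", "max_depth": int(hp["depth"]),
            "eta": float(hp["eta"]), "seed": int(seed), "nthread": 1,
            "verbosity": 0}


def _sgd_like(algorithm: str, hp: dict, seed: int):
    loss = "hinge" if algorithm == "svm_linear" else "log_loss"
    return SGDClassifier(loss=loss, alpha=float(hp.get("alpha", 1e-3)),
                         random_state=seed, learning_rate="optimal",
                         shuffle=False)


def _gradient_passes(est, Z, y, epochs: int, rng: np.random.Generator,
                     first: bool):
    classes = np.array([0, 1])
    for e in range(epochs):
        perm = rng.permutation(len(y))
        if first and e == 0:
            est.partial_fit(Z[perm], y[perm], classes=classes)
        else:
            est.partial_fit(Z[perm], y[perm])


def init_fit(algorithm: str, X: pd.DataFrame, y, hyperparams: dict | None = None,
             seed: int = 0, space_id: str = "") -> IncrementalModel:
    """Fit a fresh model on the first (matched, downsampled) batch."""
    if algorithm not in ALGORITHMS:
        raise FederatedError(f"unknown algorithm {algorithm!r}")
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    hp = {**DEFAULT_HYPERPARAMS[algorithm], **(hyperparams or {})}
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    lo = arr.min(axis=0)
    span = arr.max(axis=0) - lo
    span[span == 0] = 1.0
    model = IncrementalModel(algorithm=algorithm, estimator=None,
                             feature_names=names, scaler=(lo, span),
                             hyperparams=hp, seed=seed)
    Z = model.scale(X)
    rng = np.random.default_rng(seed)
    if algorithm == "multinomial_nb":
        est = MultinomialNB(alpha=float(hp["alpha"]))
        est.partial_fit(Z, y, classes=np.array([0, 1]))
    elif algorithm in ("svm_linear", "logistic"):
        est = _sgd_like(algorithm, hp, seed)
        _gradient_passes(est, Z, y, int(hp.get("epochs", 20)), rng, True)
    elif algorithm == "mlp":
        est = MLPClassifier(hidden_layer_sizes=tuple(hp["hidden"]),
                            random_state=seed)
        _gradient_passes(est, Z, y, int(hp.get("epochs", 20)), rng, True)
    else:  # xgboost
        d = xgb.DMatrix(Z, label=y, feature_names=names)
        est = xgb.train(_xgb_params(hp, seed), d,
                        num_boost_round=int(hp["rounds"]))
    model.estimator = est
    model.n_batches_seen = 1
    model.trained_on.append(space_id)
    return model


def update(model: IncrementalModel, X: pd.DataFrame, y,
           space_id: str = "") -> IncrementalModel:
    """Advance the model state on one additional batch (in place)."""
    if list(X.columns) != model.feature_names:
        raise FederatedError(
            "schema mismatch: batch columns differ from the model's schema")
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        model.warnings.append(
            f"batch from {space_id!r} skipped: single class")
        return model
    Z = model.scale(X)
    hp = model.hyperparams
    rng = np.random.default_rng(model.seed + 1000 * model.n_batches_seen)
    if model.algorithm == "multinomial_nb":
        model.estimator.partial_fit(Z, y)
    elif model.algorithm in ("svm_linear", "logistic", "mlp"):
        _gradient_passes(model.estimator, Z, y,
                         int(hp.get("epochs", 20)), rng, False)
    else:
        d = xgb.DMatrix(Z, label=y, feature_names=model.feature_names)
        model.estimator = xgb.train(
            _xgb_params(hp, model.seed), d,
            num_boost_round=int(hp["rounds"]), xgb_model=model.estimator)
    model.n_batches_seen += 1
    model.trained_on.append(space_id)
    return model


def tune_hyperparameters(algorithm: str, X: pd.DataFrame, y,
                         grid: list[dict] | None = None, seed: int = 0):
    """Exhaustive grid search, stratified 3-fold CV, max mean AUC.

    Ties resolve to the earlier grid entry.  Returns ``(best, log)`` where
    the log holds one ``(params, mean_auc)`` record per configuration.
    """
    y = np.asarray(y, dtype=int)
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    if not grid:
        raise FederatedError("empty hyperparameter grid")
    n_minority = int(min(np.bincount(y, minlength=2)))
    n_folds = 3 if n_minority >= 3 else 2
    if n_minority < 2:
        raise FederatedError("too few minority samples for cross-validation")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    log = []
    best, best_auc = None, -np.inf
    for params in grid:
        aucs = []
        for tr, va in cv.split(X, y):
            m = init_fit(algorithm, X.iloc[tr], y[tr], params, seed)
            aucs.append(roc_auc_score(y[va], m.predict_proba(X.iloc[va])))
        mean_auc = float(np.mean(aucs))
        log.append({"params": params, "mean_auc": mean_auc})
        if mean_auc > best_auc:
            best, best_auc = params, mean_auc
    return best, log


@dataclass
class RunResult:
    run_index: int
    seed: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: list[tuple[float, float]]
    mean_age_gap: float = 0.0
    warnings: list[str] = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(model: IncrementalModel, space: PrivateSpace,
             run_index: int = 0, seed: int = 0) -> RunResult:
    """Score the full test space (no downsampling at test time).

    Class decision at probability 0.5; ROC by threshold sweep; AUC is the
    trapezoidal area (identical to the concordant-pair statistic with ties
    counted one half).
    """
    y = space.y
    if np.unique(y).size < 2:
        raise FederatedError("single-class test set: metrics undefined")
    scores = model.predict_proba(space.X)
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fpr, tpr, _ = roc_curve(y, scores)
    return RunResult(
        run_index=run_index, seed=seed, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc=list(zip(fpr.tolist(), tpr.tolist())),
        hyperparams=dict(model.hyperparams),
    )


METRICS = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass
class EvaluationSummary:
    algorithm: str
    test_space: str
    train_spaces: list[str]
    runs: list[RunResult]
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {"algorithm": self.algorithm, "test_space": self.test_space,
                "train_spaces": self.train_spaces,
                "runs": [r.to_dict() for r in self.runs],
                "mean": self.mean, "sd": self.sd}


def _shuffled(space: PrivateSpace, rng: np.random.Generator) -> PrivateSpace:
    s = copy.copy(space)
    s.y = rng.permutation(space.y)
    return s


def run_experiment(plan: TrainingPlan, spaces: dict[str, PrivateSpace],
                   shuffle_labels: bool = False) -> EvaluationSummary:
    """Run the full incremental protocol.

    Per run ``r`` with seed ``s_r``: matched 1:``ratio`` downsampling in
    every training space with ``s_r``, hyperparameter tuning and initial
    fit on the first space, incremental updates through the remaining
    spaces in order, evaluation on the full test space.  The summary holds
    per-metric mean and sd over runs.

    ``shuffle_labels=True`` runs the permutation control: every space's
    outcome vector is re-shuffled per run with the run seed, destroying the
    signal while preserving class balance.
    """
    missing = [s for s in plan.train_spaces + [plan.test_space]
               if s not in spaces]
    if missing:
        raise FederatedError(f"unknown spaces {missing}")
    runs = []
    for r, seed in enumerate(plan.seeds):
        use = dict(spaces)
        if shuffle_labels:
            rng = np.random.default_rng(seed + 77_000)
            use = {k: _shuffled(v, rng) for k, v in use.items()}
        first = use[plan.train_spaces[0]]
        X1, y1, warns, gap = matched_batch(first, plan.control_ratio, seed)
        if plan.tune:
            hp, _ = tune_hyperparameters(plan.algorithm, X1, y1,
                                         plan.grid, seed)
        else:
            hp = (plan.grid or [DEFAULT_HYPERPARAMS[plan.algorithm]])[0]
        model = init_fit(plan.algorithm, X1, y1, hp, seed, first.space_id)
        gaps = [gap]
        for sid in plan.train_spaces[1:]:
            Xb, yb, w2, gap2 = matched_batch(use[sid], plan.control_ratio,
                                             seed)
            warns += w2
            gaps.append(gap2)
            update(model, Xb, yb, sid)
        res = evaluate(model, use[plan.test_space], r, seed)
        res.warnings = warns + model.warnings
        res.mean_age_gap = float(np.mean(gaps))
        runs.append(res)
    mean = {m: float(np.mean([getattr(r, m) for r in runs])) for m in METRICS}
    sd = {m: (float(np.std([getattr(r, m) for r in runs], ddof=1))
              if len(runs) > 1 else 0.0) for m in METRICS}
    return EvaluationSummary(plan.algorithm, plan.test_space,
                             list(plan.train_spaces), runs, mean, sd)


def leave_one_cohort_out(plan: TrainingPlan, spaces: dict[str, PrivateSpace],
                         shuffle_labels: bool = False
                         ) -> dict[str, EvaluationSummary]:
    """Iterate the plan over every choice of held-out test cohort."""
    all_ids = list(plan.train_spaces) + [plan.test_space]
    out = {}
    for test in all_ids:
        p = TrainingPlan(
            train_spaces=[s for s in all_ids if s != test],
            test_space=test, algorithm=plan.algorithm, n_runs=plan.n_runs,
            control_ratio=plan.control_ratio, seeds=list(plan.seeds),
            grid=plan.grid, tune=plan.tune)
        out[test] = run_experiment(p, spaces, shuffle_labels)
    return out


@dataclass
class DecisionRuleTree:
    """Surrogate decision tree distilled from a boosted-tree model.

    Internal nodes are ``{"feature", "threshold", "yes", "no"}`` (the
    *yes* branch takes feature <= threshold, thresholds on the model's
    [0, 1]-scaled inputs); leaves are ``{"probability", "n"}`` where the
    probability is the mean predicted class-1 probability in the leaf.
    """

    root: dict
    top_features: list[str]
    max_depth: int

    def node_features(self) -> set[str]:
        feats: set[str] = set()

        def walk(node: dict):
            if "feature" in node:
                feats.add(node["feature"])
                walk(node["yes"])
                walk(node["no"])

        walk(self.root)
        return feats


def extract_rules(model: IncrementalModel, X_pool: pd.DataFrame,
                  max_depth: int = 3, top_k: int = 5) -> DecisionRuleTree:
    """Induce clinical decision rules from the boosted-tree model.

    The booster's gain-ranked top-``top_k`` features are kept; a single
    surrogate tree of depth <= ``max_depth`` is fitted to the model's
    predicted probabilities on the pooled training data over those
    features.
    """
    if model.algorithm != "xgboost":
        raise FederatedError("rules available for xgboost only")
    gains = model.estimator.get_score(importance_type="gain")
    ranked = sorted(gains, key=lambda f: -gains[f])
    top = ranked[:top_k]
    if not top:
        raise FederatedError("model has no informative splits")
    probs = model.predict_proba(X_pool)
    Z = model.scale(X_pool)
    idx = [model.feature_names.index(f) for f in top]
    surrogate = DecisionTreeRegressor(max_depth=max_depth, random_state=0)
    surrogate.fit(Z[:, idx], probs)
    t = surrogate.tree_

    def build(node: int) -> dict:
        if t.children_left[node] == -1:
            return {"probability": float(t.value[node][0][0]),
                    "n": int(t.n_node_samples[node])}
        return {
            "feature": top[t.feature[node]],
            "threshold": float(t.threshold[node]),
            "yes": build(t.children_left[node]),
            "no": build(t.children_right[node]),
        }

    return DecisionRuleTree(root=build(0), top_features=top,
                            max_depth=max_depth)
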