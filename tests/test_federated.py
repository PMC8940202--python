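"""Matched downsampling, incremental contracts, evaluation, rule extraction."""

import numpy as np
import pandas as pd
import pytest

import cohortlink as cl
from cohortlink.federated import (DEFAULT_HYPERPARAMS, FederatedError,
                                  PrivateSpace)


def space_from(y, age, sex, extra=None, space_id="s"):
    n = len(y)
    X = pd.DataFrame({"age": np.asarray(age, dtype=float),
                      "gender": np.asarray(sex, dtype=float)})
    if extra is not None:
        for k, v in extra.items():
            X[k] = np.asarray(v, dtype=float)
    return PrivateSpace(space_id, X, np.asarray(y, dtype=int),
                        np.asarray(age, dtype=float), np.asarray(sex))


def toy_space(seed, n=120, p_case=0.2, signal=2.5, space_id="s"):
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    noise = r.normal(size=n)
    logits = signal * x - 1.5
    y = r.binomial(1, 1 / (1 + np.exp(-logits)))
    if y.sum() < 2 or y.sum() > n - 2:
        return toy_space(seed + 1, n, p_case, signal, space_id)
    age = r.uniform(30, 70, n)
    sex = r.integers(0, 2, n)
    X = pd.DataFrame({"x": x, "noise": noise, "age": age,
                      "gender": sex.astype(float)})
    return PrivateSpace(space_id, X, y, age, sex)


class TestMatchControls:
    def test_ratio_and_sex_concordance(self, rng):
        y = np.array([1] * 5 + [0] * 100)
        age = np.concatenate([rng.uniform(40, 60, 5), rng.uniform(20, 80, 100)])
        sex = np.concatenate([np.array([0, 0, 1, 1, 0]),
                              rng.integers(0, 2, 100)])
        sp = space_from(y, age, sex)
        controls, warnings, gap = cl.match_controls(sp, ratio=2, seed=0)
        assert len(controls) == 10
        assert warnings == []
        sexes = {c: sp.sex[c] for c in controls}
        # every selected control is a control row and appears once
        assert all(y[c] == 0 for c in controls)
        assert len(set(controls)) == 10

    def test_exhaustion_returns_all_controls(self, rng):
        y = np.array([1] * 5 + [0] * 7)
        sp = space_from(y, rng.uniform(30, 70, 12), rng.integers(0, 2, 12))
        controls, warnings, _ = cl.match_controls(sp, ratio=2, seed=1)
        assert sorted(controls) == list(range(5, 12))
        assert any("exhaust" in w for w in warnings)

    def test_nearest_age_equals_bruteforce_oracle(self):
        # one case per sex; unique nearest ages make matching unambiguous
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        age = np.array([50.0, 30.0, 49.0, 60.0, 31.5, 70.0, 44.0, 30.4])
        sex = np.array([0, 1, 0, 0, 1, 1, 0, 1])
        sp = space_from(y, age, sex)
        controls, _, _ = cl.match_controls(sp, ratio=2, seed=0)

        # oracle: for each case, two same-sex controls minimizing |age gap|
        expected = set()
        for case in (0, 1):
            pool = [i for i in range(2, 8) if sex[i] == sex[case]
                    and i not in expected]
            pool.sort(key=lambda i: (abs(age[i] - age[case]), i))
            expected.update(pool[:2])
        assert set(controls) == expected

    def test_no_cases_errors(self, rng):
        sp = space_from(np.zeros(10, dtype=int), rng.uniform(20, 80, 10),
                        rng.integers(0, 2, 10))
        with pytest.raises(FederatedError, match="no positive class"):
            cl.match_controls(sp)


class TestIncrementalContracts:
    def test_nb_counts_match_hand_arithmetic(self):
        # 4 rows, 2 features already in [0,1]; alpha=1 smoothing
        X = pd.DataFrame({"a": [1.0, 0.0, 1.0, 1.0],
                          "b": [0.0, 1.0, 0.0, 1.0]})
        y = np.array([0, 0, 1, 1])
        m = cl.init_fit("multinomial_nb", X, y, {"alpha": 1.0}, 0)
        est = m.estimator
        assert est.class_count_.tolist() == [2.0, 2.0]
        # class 1 rows: a = 1+1 = 2, b = 0+1 = 1; theta = (count+1)/(total+2)
        np.testing.assert_allclose(
            np.exp(est.feature_log_prob_[1]), [(2 + 1) / (3 + 2),
                                               (1 + 1) / (3 + 2)])

    @pytest.mark.parametrize("algorithm", cl.ALGORITHMS)
    def test_same_seed_is_deterministic(self, algorithm):
        sp = toy_space(0)
        probe = toy_space(99).X
        preds = []
        for _ in range(2):
            m = cl.init_fit(algorithm, sp.X, sp.y,
                            DEFAULT_HYPERPARAMS[algorithm], seed=7)
            preds.append(m.predict_proba(probe))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_svm_separates_separable_data(self):
        r = np.random.default_rng(0)
        X = pd.DataFrame({"x": np.r_[r.uniform(0, 0.3, 40),
                                     r.uniform(0.7, 1.0, 40)],
                          "z": r.normal(size=80)})
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        m = cl.init_fit("svm_linear", X, y, {"alpha": 1e-4, "epochs": 50}, 0)
        acc = ((m.predict_proba(X) >= 0.5).astype(int) == y).mean()
        assert acc == 1.0

    def test_nb_update_equals_pooled_fit(self):
        """Sequential NB updates over any partition equal the single-batch
        fit on the union (sufficient statistics)."""
        sp = toy_space(3, n=90)
        pooled = cl.init_fit("multinomial_nb", sp.X, sp.y, {"alpha": 1.0}, 0)
        for cut in (20, 45, 70):
            part = cl.init_fit("multinomial_nb", sp.X.iloc[:cut], sp.y[:cut],
                               {"alpha": 1.0}, 0)
            part.scaler = pooled.scaler    # shared frozen scaling
            part.estimator = type(part.estimator)(alpha=1.0)
            part.estimator.partial_fit(pooled.scale(sp.X.iloc[:cut]),
                                       sp.y[:cut], classes=np.array([0, 1]))
            cl.update(part, sp.X.iloc[cut:], sp.y[cut:])
            np.testing.assert_allclose(part.estimator.feature_log_prob_,
                                       pooled.estimator.feature_log_prob_,
                                       atol=1e-12)
            np.testing.assert_allclose(part.estimator.class_log_prior_,
                                       pooled.estimator.class_log_prior_,
                                       atol=1e-12)

    def test_nb_repeated_batch_keeps_priors(self):
        sp = toy_space(5, n=60)
        m = cl.init_fit("multinomial_nb", sp.X, sp.y, {"alpha": 1.0}, 0)
        before = m.estimator.class_log_prior_.copy()
        cl.update(m, sp.X, sp.y)
        np.testing.assert_allclose(m.estimator.class_log_prior_, before,
                                   atol=1e-12)

    def test_xgb_update_appends_rounds(self):
        sp1, sp2 = toy_space(1), toy_space(2)
        hp = {"rounds": 10, "depth": 2, "eta": 0.3}
        m = cl.init_fit("xgboost", sp1.X, sp1.y, hp, 0)
        assert len(m.estimator.get_dump()) == 10
        probe = toy_space(42).X
        before = m.predict_proba(probe)
        cl.update(m, sp2.X, sp2.y)
        assert len(m.estimator.get_dump()) == 20
        assert m.n_batches_seen == 2
        assert not np.array_equal(before, m.predict_proba(probe))

    def test_update_schema_mismatch_errors(self):
        sp = toy_space(1)
        m = cl.init_fit("logistic", sp.X, sp.y, None, 0)
        with pytest.raises(FederatedError, match="schema"):
            cl.update(m, sp.X.rename(columns={"x": "other"}), sp.y)

    def test_single_class_batch_errors_on_init(self):
        sp = toy_space(1)
        with pytest.raises(FederatedError, match="single class"):
            cl.init_fit("logistic", sp.X, np.zeros(len(sp.y), int), None, 0)


class TestTuning:
    def test_singleton_grid_returned_with_log(self):
        sp = toy_space(0)
        best, log = cl.tune_hyperparameters(
            "logistic", sp.X, sp.y, [{"alpha": 1e-3}], seed=0)
        assert best == {"alpha": 1e-3}
        assert len(log) == 1 and "mean_auc" in log[0]

    def test_weak_regularization_wins_when_signal_must_be_learned(self):
        # multi-feature noisy data: crushing regularization freezes the
        # gradient updates and loses ranking power, so CV AUC prefers the
        # weakly regularized configuration
        r = np.random.default_rng(1)
        n = 120
        X = pd.DataFrame(r.normal(size=(n, 6)), columns=list("abcdef"))
        y = ((X["a"] + 0.8 * X["b"]
              + r.normal(scale=1.0, size=n)) > 0).astype(int).to_numpy()
        best, log = cl.tune_hyperparameters(
            "logistic", X, y, [{"alpha": 1e4}, {"alpha": 1e-4}], seed=0)
        assert best == {"alpha": 1e-4}
        assert log[1]["mean_auc"] > log[0]["mean_auc"]

    def test_same_seed_same_selection(self):
        sp = toy_space(4)
        picks = [cl.tune_hyperparameters("xgboost", sp.X, sp.y,
                                         None, seed=3)[0]
                 for _ in range(2)]
        assert picks[0] == picks[1]


class TestEvaluate:
    def _space(self, scores, labels):
        n = len(labels)
        X = pd.DataFrame({"s": scores, "age": np.zeros(n),
                          "gender": np.zeros(n)})
        return PrivateSpace("t", X, np.asarray(labels, int),
                            np.zeros(n), np.zeros(n))

    class _FixedModel(cl.IncrementalModel):
        def predict_proba(self, X):
            return X["s"].to_numpy(dtype=float)

    def _model(self):
        return self._FixedModel("xgboost", None, ["s", "age", "gender"],
                                (np.zeros(3), np.ones(3)), {}, 0,
                                n_batches_seen=1)

    def test_perfect_separation(self):
        res = cl.evaluate(self._model(),
                          self._space([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]))
        assert (res.auc, res.sensitivity, res.specificity) == (1.0, 1.0, 1.0)

    def test_auc_equals_concordant_pair_count(self):
        res = cl.evaluate(self._model(),
                          self._space([0.9, 0.3, 0.8, 0.2], [1, 1, 0, 0]))
        assert res.auc == pytest.approx(0.75)   # 3 of 4 concordant pairs

    def test_random_scores_near_half(self):
        r = np.random.default_rng(1)
        res = cl.evaluate(self._model(),
                          self._space(r.random(2000),
                                      np.r_[np.ones(1000), np.zeros(1000)]))
        assert res.auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_test_errors(self):
        with pytest.raises(FederatedError, match="single-class"):
            cl.evaluate(self._model(), self._space([0.5, 0.6], [1, 1]))

    def test_metric_identities_from_confusion_counts(self):
        res = cl.evaluate(self._model(),
                          self._space([0.9, 0.4, 0.8, 0.2, 0.6],
                                      [1, 1, 0, 0, 0]))
        n = res.tp + res.fp + res.tn + res.fn
        assert res.accuracy == (res.tp + res.tn) / n
        assert res.sensitivity == res.tp / (res.tp + res.fn)
        assert res.specificity == res.tn / (res.tn + res.fp)


class TestExperiment:
    def _spaces(self):
        return {f"s{i}": toy_space(10 + i, n=150, space_id=f"s{i}")
                for i in range(3)}

    def test_single_run_summary_equals_run(self):
        spaces = self._spaces()
        plan = cl.TrainingPlan(train_spaces=["s0", "s1"], test_space="s2",
                               algorithm="multinomial_nb", n_runs=1,
                               tune=False)
        s = cl.run_experiment(plan, spaces)
        assert s.sd == {m: 0.0 for m in s.sd}
        assert s.mean["auc"] == s.runs[0].auc

    def test_test_space_must_be_held_out(self):
        with pytest.raises(FederatedError):
            cl.TrainingPlan(train_spaces=["s0", "s1"], test_space="s0")

    def test_leave_one_cohort_out_covers_every_space(self):
        spaces = self._spaces()
        plan = cl.TrainingPlan(train_spaces=["s0", "s1"], test_space="s2",
                               algorithm="multinomial_nb", n_runs=1,
                               tune=False)
        out = cl.leave_one_cohort_out(plan, spaces)
        assert set(out) == {"s0", "s1", "s2"}
        for test_id, summary in out.items():
            assert summary.test_space == test_id
            assert test_id not in summary.train_spaces


class TestRuleExtraction:
    def test_decisive_binary_feature_becomes_root(self):
        r = np.random.default_rng(0)
        n = 200
        flag = r.integers(0, 2, n)
        X = pd.DataFrame({"flag": flag.astype(float),
                          "noise": r.normal(size=n)})
        m = cl.init_fit("xgboost", X, flag,
                        {"rounds": 20, "depth": 2, "eta": 0.3}, 0)
        tree = cl.extract_rules(m, X)
        assert tree.root["feature"] == "flag"

    def test_depth_one_is_a_stump(self):
        sp = toy_space(0)
        m = cl.init_fit("xgboost", sp.X, sp.y,
                        {"rounds": 10, "depth": 2, "eta": 0.3}, 0)
        tree = cl.extract_rules(m, sp.X, max_depth=1)
        assert "feature" in tree.root
        assert "probability" in tree.root["yes"]
        assert "probability" in tree.root["no"]

    def test_non_tree_algorithm_rejected(self):
        sp = toy_space(0)
        m = cl.init_fit("logistic", sp.X, sp.y, None, 0)
        with pytest.raises(FederatedError, match="xgboost only"):
            cl.extract_rules(m, sp.X)
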