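import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from rnam5c import (ClassifierConfig, M5cSitePredictor, compute_metrics,
                    cross_validate, fuse, grid_search, roc_auc)
from rnam5c.evaluation import (EvaluationError, decision_scores,
                               fold_assignments, make_classifier)
from rnam5c.fusion import FeatureMatrix

from oracles import (mcc_missrate_form, oracle_auc_mannwhitney,
                     oracle_metrics)


class TestMetrics:
    def test_perfect_prediction(self):
        y = [1] * 5 + [0] * 5
        m = compute_metrics(y, y)
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_worked_confusion(self):
        # 10 positives with 2 misses, 10 negatives with 3 misses
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 8 + [0] * 2 + [0] * 7 + [1] * 3
        m = compute_metrics(y_true, y_pred)
        assert m.sn == pytest.approx(0.8)
        assert m.sp == pytest.approx(0.7)
        assert m.acc == pytest.approx(0.75)
        assert m.n_fn == 2 and m.n_fp == 3
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))
        assert m.mcc == pytest.approx(
            mcc_missrate_form(m.n_pos, m.n_neg, m.n_fn, m.n_fp))

    def test_all_predicted_positive(self):
        m = compute_metrics([1] * 4 + [0] * 4, [1] * 8)
        assert m.sn == 1.0 and m.sp == 0.0

    def test_single_class_truth_errors(self):
        with pytest.raises(EvaluationError):
            compute_metrics([1, 1, 1], [1, 0, 1])

    def test_zero_denominator_mcc_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="MCC"):
            m = compute_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert m.mcc == 0.0

    def test_agrees_with_contingency_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(4, 60)
            y_true = rng.integers(0, 2, n)
            if y_true.min() == y_true.max():
                continue
            y_pred = rng.integers(0, 2, n)
            m = compute_metrics(y_true, y_pred)
            sn, sp, acc, mcc = oracle_metrics(y_true, y_pred)
            # the two algebraic forms agree to the last ulp
            assert m.sn == pytest.approx(sn, abs=1e-12)
            assert m.sp == pytest.approx(sp, abs=1e-12)
            assert m.acc == pytest.approx(acc, abs=1e-12)
            assert m.mcc == pytest.approx(mcc, abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0


class TestRocAuc:
    def test_perfect_ranking(self):
        _, _, a = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert a == 1.0

    def test_reversed_ranking(self):
        _, _, a = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert a == 0.0

    def test_tie_case_matches_mann_whitney(self):
        scores = [0.5, 0.7, 0.5, 0.3, 0.9, 0.1]
        y = [1, 1, 1, 0, 0, 0]
        _, _, a = roc_auc(scores, y)
        assert a == pytest.approx(oracle_auc_mannwhitney(scores, y))

    def test_matches_u_statistic_on_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # many ties
            _, _, a = roc_auc(scores, y)
            assert a == pytest.approx(oracle_auc_mannwhitney(scores, y),
                                      abs=1e-12)

    def test_roc_endpoints_and_monotone_fpr(self):
        rng = np.random.default_rng(3)
        fpr, tpr, _ = roc_auc(rng.normal(size=40),
                              rng.integers(0, 2, 40) | np.r_[1, np.zeros(39, int)])
        assert fpr[0] == 0.0 and fpr[-1] == 1.0
        assert tpr[0] == 0.0 and tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all()

    def test_constant_scores_warn_half_auc(self):
        with pytest.warns(UserWarning, match="constant"):
            _, _, a = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert a == 0.5


class TestBackends:
    @pytest.mark.parametrize("algo", ["svm_rbf", "random_forest", "adaboost",
                                      "gaussian_nb"])
    def test_all_backends_fit_and_score(self, planted_dataset, algo):
        matrix = fuse(planted_dataset, "Kmer")
        clf = make_classifier(ClassifierConfig(algo, seed=5))
        clf.fit(matrix.X, matrix.labels)
        scores = decision_scores(clf, matrix.X)
        assert scores.shape == (300,)

    def test_default_hyperparameters(self):
        svm = make_classifier(ClassifierConfig("svm_rbf"))
        assert svm.C == 1.5 and svm.gamma == "scale"
        rf = make_classifier(ClassifierConfig("random_forest"))
        assert rf.n_estimators == 100

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(EvaluationError):
            ClassifierConfig("deep_net")


class TestCrossValidate:
    def test_strong_signal_is_nearly_separable(self, planted_dataset):
        rep = cross_validate(planted_dataset, ClassifierConfig(), spec="BEST",
                             folds=5, seed=3)
        assert rep.acc > 0.9
        assert rep.auc > 0.95

    def test_fold_assignment_stratified_and_deterministic(self):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        a1 = fold_assignments(labels, 10, seed=9)
        a2 = fold_assignments(labels, 10, seed=9)
        np.testing.assert_array_equal(a1, a2)
        for f in range(10):
            assert labels[a1 == f].sum() == 5  # 5 positives per fold

    def test_class_smaller_than_k_errors(self):
        labels = np.r_[np.ones(4, int), np.zeros(50, int)]
        with pytest.raises(EvaluationError, match="stratify"):
            fold_assignments(labels, 10, seed=0)

    def test_matches_manual_fold_loop_on_feature_matrix(self, small_dataset):
        """Jackknife-style oracle: leave one per class out with k=10 and
        re-derive every fold's predictions independently."""
        matrix = fuse(small_dataset, "Kmer")
        rep = cross_validate(matrix, ClassifierConfig("gaussian_nb"),
                             folds=10, seed=21)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=21)
        accs = []
        for train, test in skf.split(matrix.X, matrix.labels):
            clf = GaussianNB().fit(matrix.X[train], matrix.labels[train])
            pred = clf.predict(matrix.X[test])
            accs.append(float((pred == matrix.labels[test]).mean()))
        assert rep.acc == pytest.approx(np.mean(accs))

    def test_seeded_reproducibility(self, planted_dataset):
        kw = dict(spec="PseEIIP+PseDNC", folds=5, seed=11)
        r1 = cross_validate(planted_dataset, ClassifierConfig("random_forest"),
                            **kw)
        r2 = cross_validate(planted_dataset, ClassifierConfig("random_forest"),
                            **kw)
        assert r1.acc == r2.acc and r1.auc == r2.auc
        np.testing.assert_array_equal(r1.roc_fpr, r2.roc_fpr)

    def test_per_fold_vs_global_psp_fit_both_run(self, planted_dataset):
        for mode in ("per_fold", "global"):
            rep = cross_validate(planted_dataset, ClassifierConfig(),
                                 spec="PSP", folds=5, seed=2, psp_fit=mode)
            assert 0.0 <= rep.acc <= 1.0

    def test_dataset_requires_spec(self, planted_dataset):
        with pytest.raises(EvaluationError, match="spec"):
            cross_validate(planted_dataset, ClassifierConfig())


class TestGridSearch:
    def test_single_point_grid_returns_it(self, planted_dataset):
        cfg, trace = grid_search(planted_dataset, "Kmer", {"C": [2.0]},
                                 folds=3, seed=1)
        assert cfg.params["C"] == 2.0
        assert len(trace) == 1

    def test_full_mode_equals_exhaustive_reevaluation(self, planted_dataset):
        grid = {"C": [0.5, 2.0], "gamma": [0.01, "scale"]}
        # gamma mix of str/float cannot sort; use numeric-only grid
        grid = {"C": [0.5, 2.0], "gamma": [0.01, 0.1]}
        cfg, trace = grid_search(planted_dataset, "Kmer", grid, folds=3,
                                 seed=4, mode="full")
        assert len(trace) == 4
        best_row = trace.loc[trace["cv_acc"].idxmax()]
        assert cfg.params["C"] == best_row["C"]
        assert cfg.params["gamma"] == best_row["gamma"]
        # argmax property: selected accuracy >= every grid cell
        assert (best_row["cv_acc"] >= trace["cv_acc"] - 1e-12).all()

    def test_axis_mode_runs_one_sweep_per_parameter(self, planted_dataset):
        grid = {"C": [0.5, 1.5], "gamma": [0.01, 0.1]}
        cfg, trace = grid_search(planted_dataset, "Kmer", grid, folds=3,
                                 seed=4, mode="axis")
        assert len(trace) == 4  # 2 + 2 evaluations, not 2x2 with refits
        assert set(cfg.params) == {"C", "gamma"}

    def test_empty_grid_rejected(self, planted_dataset):
        with pytest.raises(EvaluationError):
            grid_search(planted_dataset, "Kmer", {}, folds=2, seed=0)


class TestPredictor:
    def test_fit_predict_evaluate_roundtrip(self, planted_dataset, tmp_path):
        model = M5cSitePredictor(spec="BEST", seed=8).fit(planted_dataset)
        assert model.n_features_in_ == 287
        preds = model.predict(planted_dataset)
        assert set(preds) <= {0, 1}
        rep = model.evaluate(planted_dataset)
        assert rep.acc > 0.9  # training-set fit on separable data
        # artifact round trip
        path = tmp_path / "model.joblib"
        model.save(path)
        back = M5cSitePredictor.load(path)
        np.testing.assert_array_equal(back.predict(planted_dataset), preds)

    def test_scaling_option_is_recorded(self, planted_dataset):
        model = M5cSitePredictor(spec="Kmer", scale=True).fit(planted_dataset)
        assert model.scaler_ is not None
        F = model._features(planted_dataset)
        assert F.min() >= -1e-9 and F.max() <= 1 + 1e-9

    def test_sklearn_get_set_params(self):
        model = M5cSitePredictor()
        params = model.get_params()
        assert params["spec"] == "BEST"
        model.set_params(algorithm="gaussian_nb")
        assert model.algorithm == "gaussian_nb"
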