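"""Classifier training and cross-platform model concordance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micropair.ml import (
    OneVsOneSVM,
    SplitSpec,
    accuracy,
    agreement,
    agreement_kappa,
    bootstrap_ci,
    importance_ranking,
    signature_compare,
    stratified_split,
    sv_agreement,
    tune_and_train,
)


def _labels(n_control, n_hrl, n_crc):
    labels = (["control"] * n_control + ["HRL"] * n_hrl + ["CRC"] * n_crc)
    return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])


class TestStratifiedSplit:
    def test_study_design_sizes(self):
        # 156 samples (51 controls / 54 HRL / 51 CRC), 10 held out per class
        labels = _labels(51, 54, 51)
        train, test = stratified_split(labels, SplitSpec(test_per_class=10, seed=3))
        assert len(train) == 126 and len(test) == 30
        train_counts = labels.loc[train].value_counts()
        test_counts = labels.loc[test].value_counts()
        assert train_counts["control"] == 41
        assert train_counts["HRL"] == 44
        assert train_counts["CRC"] == 41
        assert (test_counts == 10).all()

    def test_balanced_design(self):
        labels = _labels(30, 30, 30)
        train, test = stratified_split(labels, SplitSpec(test_per_class=10, seed=0))
        assert len(train) == 60 and len(test) == 30

    def test_deterministic_under_seed(self):
        labels = _labels(20, 20, 20)
        s1 = stratified_split(labels, SplitSpec(5, seed=7))
        s2 = stratified_split(labels, SplitSpec(5, seed=7))
        assert s1 == s2

    def test_small_class_rejected(self):
        labels = _labels(5, 20, 20)
        with pytest.raises(ValueError, match="control"):
            stratified_split(labels, SplitSpec(test_per_class=10, seed=0))


def _separable_data(rng, n_per_class=15, n_features=10, shift=4.0):
    labels = _labels(n_per_class, n_per_class, n_per_class)
    X = rng.normal(size=(len(labels), n_features))
    X[labels.to_numpy() == "HRL", 0] += shift
    X[labels.to_numpy() == "CRC", 1] += shift
    df = pd.DataFrame(X, index=labels.index,
                      columns=[f"T sp{j}" for j in range(n_features)])
    return df, labels


class TestOneVsOneSVM:
    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X, y = _separable_data(rng)
        model = OneVsOneSVM(cost=1.0).fit_with_members(X, y)
        assert (model.predict(X) == y).all()

    def test_unanimous_vote_wins(self):
        rng = np.random.default_rng(1)
        X, y = _separable_data(rng)
        model = OneVsOneSVM(cost=10.0).fit_with_members(X, y)
        probe = X.loc[y == "control"].iloc[:3]
        assert (model.predict(probe) == "control").all()

    def test_support_vector_table_shape(self):
        rng = np.random.default_rng(2)
        X, y = _separable_data(rng, n_per_class=8)
        model = OneVsOneSVM(cost=1.0).fit_with_members(X, y)
        sv = model.support_vector_table()
        assert list(sv.index) == list(X.index)
        assert sv.shape[1] == 3
        assert sv.to_numpy().any()


class TestTuneAndTrain:
    def test_separable_training_accuracy_100(self):
        rng = np.random.default_rng(3)
        X, y = _separable_data(rng)
        model = tune_and_train(X, y, "SVM", svm_cost_grid=(1.0, 10.0), seed=0)
        assert accuracy(model.fitted_labels, y) == 100.0
        assert model.hyperparameters["cost"] in (1.0, 10.0)

    def test_shuffled_labels_cv_near_chance(self):
        rng = np.random.default_rng(4)
        accs = []
        for seed in range(6):
            X, y = _separable_data(np.random.default_rng(seed), n_per_class=20)
            y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            model = tune_and_train(X, y_shuf, "SVM", svm_cost_grid=(1.0,),
                                   seed=seed)
            accs.append(model.cv_accuracy)
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.08)

    def test_rf_grid_selection_and_importance(self):
        rng = np.random.default_rng(5)
        X, y = _separable_data(rng, n_per_class=12, n_features=6)
        model = tune_and_train(X, y, "RF", rf_trees_grid=(50,), rf_node_grid=(2, 3),
                               seed=0)
        assert model.hyperparameters["n_trees"] == 50
        assert set(model.importance.index) == set(X.columns)
        # informative features dominate the impurity importance
        top2 = set(importance_ranking(model)[:2])
        assert top2 == {"T sp0", "T sp1"}


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy(["a", "b"], ["a", "b"]) == 100.0
        assert bootstrap_ci(["a"] * 30, ["a"] * 30, n_boot=100) == (100.0, 100.0)

    def test_half_correct(self):
        pred = ["a"] * 15 + ["b"] * 15
        truth = ["a"] * 30
        assert accuracy(pred, truth) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])

    def test_random_guessing_ci_width(self):
        # 3-class guessing on 30 samples: bootstrap CI ≈ ±17 points wide
        rng = np.random.default_rng(6)
        pred = rng.choice(list("abc"), 30)
        truth = rng.choice(list("abc"), 30)
        lo, hi = bootstrap_ci(pred, truth, n_boot=2000, seed=0)
        assert 20 < hi - lo < 50


class TestAgreement:
    def test_identical_predictions(self):
        out = agreement_kappa(["a", "b", "c", "a"], ["a", "b", "c", "a"])
        assert out["agreement"] == 1.0
        assert out["kappa"] == pytest.approx(1.0)

    def test_total_disagreement(self):
        assert agreement(["a", "a"], ["b", "b"]) == 0.0

    def test_independent_vectors_chance_level(self):
        rng = np.random.default_rng(7)
        a = rng.choice(list("abc"), 10_000)
        b = rng.choice(list("abc"), 10_000)
        out = agreement_kappa(a, b)
        assert out["agreement"] == pytest.approx(1 / 3, abs=0.02)
        assert out["kappa"] == pytest.approx(0.0, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            agreement(["a"], ["a", "b"])


class TestSvAgreement:
    def _model(self, seed, n_per_class=10):
        X, y = _separable_data(np.random.default_rng(seed), n_per_class=n_per_class)
        return tune_and_train(X, y, "SVM", svm_cost_grid=(1.0,), seed=0)

    def test_identical_models_agree_fully(self):
        m = self._model(0)
        out = sv_agreement(m, m)
        assert (out["agreement"] == 1.0).all()
        np.testing.assert_allclose(out["kappa"], 1.0)

    def test_non_svm_rejected(self):
        X, y = _separable_data(np.random.default_rng(1), n_per_class=8)
        rf = tune_and_train(X, y, "RF", rf_trees_grid=(20,), rf_node_grid=(2,))
        m = self._model(0, n_per_class=8)
        with pytest.raises(ValueError, match="SVM"):
            sv_agreement(m, rf)

    def test_random_memberships_kappa_near_zero(self):
        from micropair.concordance import cohens_kappa

        rng = np.random.default_rng(8)
        a = (rng.uniform(size=10_000) < 0.6).astype(int)
        b = (rng.uniform(size=10_000) < 0.6).astype(int)
        assert abs(cohens_kappa(a, b)) < 0.03


def kendall_bruteforce(a, b):
    """Tau-b by explicit pair counting with tie corrections."""
    n = len(a)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = a[i] - a[j], b[i] - b[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else float("nan")


class TestSignatureCompare:
    def _series(self, values, prefix="T sp"):
        return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])

    def test_identical_rankings(self):
        imp = self._series(np.linspace(1, 0, 20))
        out = signature_compare(imp, imp.copy(), top_k=10, n_boot=50)
        assert out.tau == pytest.approx(1.0)
        assert out.top_k_agreement == 100.0

    def test_reversed_rankings(self):
        imp = self._series(np.linspace(1, 0, 20))
        rev = self._series(np.linspace(0, 1, 20))
        out = signature_compare(imp, rev, top_k=20, n_boot=50)
        assert out.tau == pytest.approx(-1.0)
        assert out.top_k_agreement == 100.0  # k = all shared taxa
        half = signature_compare(imp, rev, top_k=10, n_boot=50)
        assert half.top_k_agreement == 0.0

    def test_tau_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.integers(0, 8, 12).astype(float)
            b = rng.integers(0, 8, 12).astype(float)
            out = signature_compare(self._series(a), self._series(b),
                                    top_k=5, n_boot=0)
            expected = kendall_bruteforce(a, b)
            if np.isnan(expected):
                assert np.isnan(out.tau)
            else:
                assert out.tau == pytest.approx(expected, abs=1e-10)

    def test_random_rankings_expected_topk_overlap(self):
        # two random rankings of 100 taxa: E|top50 ∩ top50| = 25 → 50%
        rng = np.random.default_rng(10)
        agreements = []
        for _ in range(200):
            a = pd.Series(rng.permutation(100).astype(float),
                          index=[f"t{i}" for i in range(100)])
            b = pd.Series(rng.permutation(100).astype(float),
                          index=[f"t{i}" for i in range(100)])
            out = signature_compare(a, b, top_k=50, n_boot=0)
            agreements.append(out.top_k_agreement)
        assert np.mean(agreements) == pytest.approx(50.0, abs=2.0)

    def test_too_few_shared_rejected(self):
        a = self._series([1.0, 2.0])
        with pytest.raises(ValueError, match="shared"):
            signature_compare(a, a, top_k=2)
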