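"""ANOVA ranking, stratified splitting and the classifier sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import latentsurv as ls
from latentsurv.matrix import ExpressionMatrix, RNA, MIRNA
from latentsurv.rankclassify import SHOWCASE_COMBINATIONS


def labeled_matrix(n=100, n_rna=40, n_mirna=12, n_signal=10, effect=3.0,
                   seed=0, balance=0.5):
    """Standardized matrix with planted class-differential features."""
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n) < balance, ls.HIGH_RISK, ls.LOW_RISK)
    d = n_rna + n_mirna
    X = rng.normal(size=(n, d))
    hi = labels == ls.HIGH_RISK
    X[hi, :n_signal // 2] += effect                       # RNA signal
    X[hi, n_rna:n_rna + n_signal // 2] += effect          # miRNA signal
    cols = [f"g{i}" for i in range(n_rna)] + [f"m{i}" for i in range(n_mirna)]
    classes = pd.Series([RNA] * n_rna + [MIRNA] * n_mirna, index=cols)
    pats = [f"p{i}" for i in range(n)]
    em = ExpressionMatrix(pd.DataFrame(X, index=pats, columns=cols), classes)
    return em, pd.Series(labels, index=pats)


class TestAnovaRank:
    def test_hand_example_f_equals_1_5(self):
        """Groups (1,2,3) vs (2,3,4): SSB=1.5, MSW=1 -> F=1.5."""
        cols = ["g0"]
        em = ExpressionMatrix(
            pd.DataFrame([[1], [2], [3], [2], [3], [4]], dtype=float,
                         index=[f"p{i}" for i in range(6)], columns=cols),
            pd.Series(RNA, index=cols))
        labels = pd.Series([ls.HIGH_RISK] * 3 + [ls.LOW_RISK] * 3, index=em.patients)
        table = ls.anova_rank(em, labels)
        assert table.loc["g0", "F"] == pytest.approx(1.5, abs=1e-12)

    def test_identical_groups_give_zero_f(self):
        cols = ["g0"]
        em = ExpressionMatrix(
            pd.DataFrame([[1], [2], [1], [2]], dtype=float,
                         index=list("abcd"), columns=cols),
            pd.Series(RNA, index=cols))
        labels = pd.Series([ls.HIGH_RISK, ls.HIGH_RISK, ls.LOW_RISK, ls.LOW_RISK],
                           index=em.patients)
        assert ls.anova_rank(em, labels).loc["g0", "F"] == pytest.approx(0.0)

    def test_f_equals_squared_pooled_t(self):
        """For two groups, F is the square of the equal-variance t statistic."""
        em, labels = labeled_matrix(seed=1)
        table = ls.anova_rank(em, labels)
        hi = (labels == ls.HIGH_RISK).to_numpy()
        for feat in list(em.features)[:8]:
            v = em.values[feat].to_numpy()
            t, _ = stats.ttest_ind(v[hi], v[~hi], equal_var=True)
            assert table.loc[feat, "F"] == pytest.approx(t ** 2, abs=1e-10)

    def test_classes_ranked_separately(self):
        em, labels = labeled_matrix(seed=2)
        table = ls.anova_rank(em, labels)
        for cls in (RNA, MIRNA):
            ranks = table.loc[table["feature_class"] == cls, "rank"]
            assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_single_class_rejected(self):
        em, labels = labeled_matrix(seed=3)
        labels[:] = ls.HIGH_RISK
        with pytest.raises(ValueError, match="single class"):
            ls.anova_rank(em, labels)


class TestSplit:
    def test_proportions_preserved(self):
        rng = np.random.default_rng(4)
        pats = [f"p{i}" for i in range(100)]
        labels = pd.Series([ls.HIGH_RISK] * 60 + [ls.LOW_RISK] * 40, index=pats)
        train, test = ls.stratified_split(pats, labels, ls.SplitSpec(seed=0))
        n_hi = (labels.loc[train] == ls.HIGH_RISK).sum()
        assert abs(n_hi - 36) <= 1
        assert abs((labels.loc[test] == ls.HIGH_RISK).sum() - 24) <= 1

    def test_partition_and_determinism(self):
        pats = [f"p{i}" for i in range(50)]
        labels = pd.Series([ls.HIGH_RISK, ls.LOW_RISK] * 25, index=pats)
        t1 = ls.stratified_split(pats, labels, ls.SplitSpec(seed=3))
        t2 = ls.stratified_split(pats, labels, ls.SplitSpec(seed=3))
        assert t1 == t2
        train, test = t1
        assert set(train) | set(test) == set(pats)
        assert set(train) & set(test) == set()

    def test_tiny_class_rejected(self):
        pats = ["a", "b", "c"]
        labels = pd.Series([ls.HIGH_RISK, ls.HIGH_RISK, ls.LOW_RISK], index=pats)
        with pytest.raises(ValueError, match="class too small"):
            ls.stratified_split(pats, labels, ls.SplitSpec())


class TestTrainEval:
    def test_separable_data_perfect_accuracy(self):
        em, labels = labeled_matrix(effect=6.0, seed=5)
        train, test = ls.stratified_split(em.patients, labels, ls.SplitSpec(seed=0))
        ranking = ls.anova_rank(em.subset_patients(train), labels.loc[train])
        for family in ("svm", "knn", "rf", "lr"):
            res = ls.train_eval(em, labels, train, test, ranking, 5, 5,
                                ls.ClassifierSpec(family))
            assert res.test_accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        """Labels shuffled before training: test accuracy within 99% binomial
        bounds of 0.5 on a balanced 500-patient fixture."""
        em, labels = labeled_matrix(n=500, effect=3.0, seed=6)
        rng = np.random.default_rng(7)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        train, test = ls.stratified_split(em.patients, permuted, ls.SplitSpec(seed=1))
        ranking = ls.anova_rank(em.subset_patients(train), permuted.loc[train])
        res = ls.train_eval(em, permuted, train, test, ranking, 5, 10,
                            ls.ClassifierSpec("svm"))
        n_test = len(test)
        half_width = 2.576 * np.sqrt(0.25 / n_test)
        assert abs(res.test_accuracy - 0.5) < half_width + 0.02

    def test_confusion_matrix_accuracy_identity(self):
        em, labels = labeled_matrix(seed=8)
        train, test = ls.stratified_split(em.patients, labels, ls.SplitSpec(seed=2))
        ranking = ls.anova_rank(em.subset_patients(train), labels.loc[train])
        res = ls.train_eval(em, labels, train, test, ranking, 4, 8)
        assert res.tp + res.fn + res.fp + res.tn == len(test)
        assert res.test_accuracy == pytest.approx(res.accuracy_from_confusion)

    def test_requesting_too_many_features_rejected(self):
        em, labels = labeled_matrix(seed=9)
        train, test = ls.stratified_split(em.patients, labels, ls.SplitSpec(seed=0))
        ranking = ls.anova_rank(em.subset_patients(train), labels.loc[train])
        with pytest.raises(ValueError, match="available"):
            ls.train_eval(em, labels, train, test, ranking, 500, 5)


class TestSweepAndGrids:
    @pytest.fixture(scope="class")
    def setup(self):
        em, labels = labeled_matrix(n=120, n_rna=60, n_mirna=25,
                                    n_signal=20, effect=2.0, seed=10)
        train, test = ls.stratified_split(em.patients, labels, ls.SplitSpec(seed=0))
        ranking = ls.anova_rank(em.subset_patients(train), labels.loc[train])
        return em, labels, train, test, ranking

    def test_sweep_cardinality_and_showcase_order(self, setup):
        em, labels, train, test, ranking = setup
        sweep = ls.sweep_feature_counts(em, labels, train, test, ranking)
        assert len(sweep) == 24 + 6
        showcase = sweep[sweep["showcase"]]
        assert list(showcase["n_features"]) == [10, 20, 30, 40, 45, 50]
        assert [tuple(r) for r in showcase[["n_mirna", "n_rna"]].to_numpy()] \
            == list(SHOWCASE_COMBINATIONS)

    def test_grid_shapes(self, setup):
        em, labels, train, test, ranking = setup
        sizes = {"knn": 20, "rf": 20, "lr": 14}
        for family, n_cells in sizes.items():
            grid = ls.hyperparameter_grid(em, labels, train, test, ranking,
                                          family, 10, 15)
            assert len(grid) == n_cells
            best = grid[grid["best"]]
            assert len(best) == 1
            assert best["test_accuracy"].iloc[0] == grid["test_accuracy"].max()

    def test_knn_k1_on_training_set_is_perfect(self, setup):
        em, labels, train, _, ranking = setup
        res = ls.train_eval(em, labels, train, train, ranking, 5, 5,
                            ls.ClassifierSpec("knn", {"k": 1}))
        assert res.test_accuracy == 1.0

    def test_unknown_family_rejected(self, setup):
        em, labels, train, test, ranking = setup
        with pytest.raises(ValueError, match="unknown family"):
            ls.hyperparameter_grid(em, labels, train, test, ranking, "xgb")

    def test_ranking_uses_training_split_only(self, setup):
        em, labels, train, test, ranking = setup
        again = ls.anova_rank(em.subset_patients(train), labels.loc[train])
        assert ranking.equals(again)
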