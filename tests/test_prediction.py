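"""SMOTE, regression benchmarking, RF prediction reports and RRMSE protocol."""
import numpy as np
import pandas as pd
import pytest

from bioind.prediction import (
    PredictionReport,
    RFRegressorSpec,
    SmoteSpec,
    benchmark_regressors,
    replicate_rrmse,
    rf_regress,
    rrmse,
    select_nonhrt_bioindicators,
    smote_oversample,
    time_independent_set,
)
from bioind.selection import BioindicatorSet
from bioind.tables import TableError


class TestRRMSE:
    def test_hand_values(self):
        assert rrmse([10, 10], [11, 9]) == pytest.approx(10.0, abs=1e-12)
        assert rrmse([5, 5, 5], [5, 5, 5]) == 0.0

    def test_scale_invariance(self, rng):
        m = rng.uniform(1, 10, 20)
        p = m + rng.normal(0, 1, 20)
        assert rrmse(m, p) == pytest.approx(rrmse(7.3 * m, 7.3 * p), rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(TableError):
            rrmse([0, 0], [1, -1])

    def test_accuracy_duality(self, rng):
        m = rng.uniform(5, 10, 15)
        p = m * (1 + rng.normal(0, 0.02, 15))
        assert 100 - rrmse(m, p) > 90


class TestSmote:
    def _imbalanced(self, rng, n_min=7, n_maj=20, p=4):
        X = pd.DataFrame(rng.normal(size=(n_min + n_maj, p)),
                         columns=list("wxyz"))
        X.iloc[:n_min] += 5.0
        y = np.array(["HRT8"] * n_min + ["HRT2"] * n_maj)
        return X, y

    def test_counts_near_balance_and_originals_kept(self, rng):
        X, y = self._imbalanced(rng)
        bx, by = smote_oversample(X, y, SmoteSpec(k_neighbors=5, target_total=100, seed=0))
        counts = pd.Series(by).value_counts()
        assert abs(counts["HRT8"] - 50) <= 5 and abs(counts["HRT2"] - 50) <= 5
        np.testing.assert_array_equal(bx.iloc[:len(X)].to_numpy(), X.to_numpy())

    def test_synthetic_points_lie_between_class_extremes(self, rng):
        X, y = self._imbalanced(rng, n_min=10, n_maj=30)
        bx, by = smote_oversample(X, y, SmoteSpec(k_neighbors=3, target_total=100, seed=1))
        new = bx.iloc[len(X):]
        new_y = by[len(X):]
        for cls in np.unique(new_y):
            orig = X[y == cls]
            sub = new[new_y == cls]
            assert (sub.min() >= orig.min() - 1e-9).all()
            assert (sub.max() <= orig.max() + 1e-9).all()

    def test_balanced_input_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)))
        y = np.array(["a"] * 50 + ["b"] * 50)
        bx, by = smote_oversample(X, y, SmoteSpec(target_total=100, seed=0))
        assert len(bx) == 100

    def test_minority_smaller_than_k_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 3)))
        y = np.array(["a"] * 4 + ["b"] * 20)
        with pytest.raises(TableError, match="smaller k"):
            smote_oversample(X, y, SmoteSpec(k_neighbors=5, target_total=100))


class TestBenchmark:
    def test_linear_target_solved_by_linear_model(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 3.0 * X["a"] - 1.0
        out = benchmark_regressors(X, y, RFRegressorSpec(n_trees=50, seed=0))
        lin = out[(out.algorithm == "linear")]["rmse"]
        assert lin.max() < 1e-8
        assert set(out.algorithm) == {"linear", "svm_radial", "rf"}
        assert (out.groupby(["algorithm", "dataset"]).size() == 5).all()

    def test_balanced_dataset_included_when_labels_given(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 3)), columns=list("abc"))
        y = X["a"] * 2
        labels = np.array(["m"] * 7 + ["M"] * 20)
        out = benchmark_regressors(X, y, RFRegressorSpec(n_trees=30, seed=0),
                                   smote_labels=labels,
                                   smote_spec=SmoteSpec(5, 100, 0))
        assert set(out.dataset) == {"original", "balanced"}

    def test_constant_target_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        with pytest.raises(TableError):
            benchmark_regressors(X, np.ones(20), RFRegressorSpec(10, seed=0))


class TestRFRegress:
    def test_noise_free_monotone_relation_predicts_well(self, rng):
        x = rng.uniform(0, 1, 60)
        X_tr = pd.DataFrame({"f": x[:40]})
        X_te = pd.DataFrame({"f": x[40:]})
        y = 10 + 20 * x
        rep = rf_regress(X_tr, y[:40], X_te, y[40:],
                         RFRegressorSpec(n_trees=300, seed=0), parameter="toy")
        assert rep.rrmse < 5
        assert rep.r_squared > 0.95
        assert rep.explained_variance_train > 80

    def test_constant_target_flagged_unpredictable(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        rep = rf_regress(X, np.full(20, 3.0), X, np.full(20, 3.0),
                         RFRegressorSpec(50, seed=0))
        assert rep.explained_variance_train == float("-inf")

    def test_missing_targets_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        y = np.r_[np.ones(9), np.nan]
        with pytest.raises(TableError):
            rf_regress(X, y, X, y, RFRegressorSpec(10, seed=0))


class TestNonHrtSelection:
    def test_coupled_features_dominate_ranking(self, rng):
        n, p = 50, 20
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"ASV{i:02d}" for i in range(p)])
        y = 5 * X["ASV00"] + 3 * X["ASV01"] + rng.normal(0, 0.1, n)
        s = select_nonhrt_bioindicators(X, y, RFRegressorSpec(300, seed=0), k=5)
        assert {"ASV00", "ASV01"} <= set(s.asv_ids)

    def test_permuted_target_breaks_ranking(self):
        agree = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(40, 10)),
                             columns=[f"a{i}" for i in range(10)])
            y = 4 * X["a0"] + r.normal(0, 0.1, 40)
            s_perm = select_nonhrt_bioindicators(
                X, r.permutation(y), RFRegressorSpec(200, seed=seed), k=1)
            agree += s_perm.asv_ids[0] == "a0"
        assert agree <= 2  # permutation destroys the association

    def test_returns_k_members(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 20)))
        X.columns = [f"x{i}" for i in range(20)]
        y = X["x3"] + rng.normal(0, 0.5, 30)
        assert len(select_nonhrt_bioindicators(X, y, RFRegressorSpec(50, seed=0),
                                               k=15)) == 15


class TestTimeIndependent:
    def _set(self, ids, target="HRT"):
        return BioindicatorSet(list(ids), "A", target, {i: 1.0 for i in ids})

    def test_set_algebra(self):
        hrt = self._set(["a", "b", "c", "d"])
        nh1 = self._set(["b", "x"], "prod_C6")
        nh2 = self._set(["c", "y"], "prod_C8")
        out = time_independent_set(hrt, [nh1, nh2])
        assert out.asv_ids == ["a", "d"]  # order preserved from hrt set

    def test_full_coverage_gives_empty(self):
        hrt = self._set(["a", "b"])
        out = time_independent_set(hrt, [self._set(["a", "b", "c"], "p")])
        assert out.asv_ids == []

    def test_disjoint_keeps_all(self):
        hrt = self._set(["a", "b"])
        out = time_independent_set(hrt, [self._set(["x"], "p")])
        assert out.asv_ids == ["a", "b"]


class TestReplicateProtocol:
    def test_exhaustive_subsample_varies_only_by_forest_seed(self, rng):
        X_tr = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y_tr = 2 * X_tr["a"] + rng.normal(0, 0.1, 30)
        X_te = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y_te = 2 * X_te["a"] + 10  # positive mean for RRMSE
        s = BioindicatorSet(list("abcd"), "A", "HRT", {c: 1.0 for c in "abcd"})
        rep = replicate_rrmse(X_tr, y_tr, X_te, y_te, s,
                              RFRegressorSpec(50, seed=0),
                              n_replicates=6, subsample_size=4)
        assert rep.rrmse_values.std() < rep.rrmse_values.mean()
        assert rep.mean_rrmse == pytest.approx(rep.rrmse_values.mean())

    def test_subsample_larger_than_set_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        s = BioindicatorSet(["a", "b"], "A", "HRT")
        with pytest.raises(TableError):
            replicate_rrmse(X, np.ones(10), X, np.ones(10), s,
                            RFRegressorSpec(10, seed=0), subsample_size=3)
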