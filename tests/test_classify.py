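import numpy as np
import pytest

from emgknee import (
    ClassifierSpec,
    FeatureVector,
    anova_by_motion,
    compare_feature_sets,
    fit_svm,
    paired_ttest,
    repeated_cv,
    select_C,
)
from emgknee.errors import (
    ConfigurationError,
    DegenerateDataError,
    ParameterError,
    StratificationError,
    ValidationError,
)


def vectors_from_xy(X, y, names=("f1", "f2")):
    return [FeatureVector(names=names, values=row, label=lab)
            for row, lab in zip(X, y)]


def separable_data(n=40, gap=20.0, rng=None):
    rng = rng or np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(gap, 1, (n, 2))])
    y = ["stance"] * n + ["swing"] * n
    return vectors_from_xy(X, y)


class TestFitSvm:
    def test_separable_training_accuracy(self):
        data = separable_data()
        model = fit_svm(data)
        assert model.score(data, [v.label for v in data]) == 1.0

    def test_xor_pattern_rbf(self, rng):
        centers = [(1, 1), (-1, -1), (1, -1), (-1, 1)]
        labels = ["stance", "stance", "swing", "swing"]
        X, y = [], []
        for (cx, cy), lab in zip(centers, labels):
            pts = rng.normal(0, 0.15, (25, 2)) + [cx, cy]
            X.append(pts)
            y += [lab] * 25
        data = vectors_from_xy(np.vstack(X), y)
        model = fit_svm(data, ClassifierSpec(C=10.0))
        assert model.score(data, y) >= 0.95

    def test_single_class_rejected(self):
        data = vectors_from_xy(np.random.default_rng(0).normal(size=(10, 2)),
                               ["swing"] * 10)
        with pytest.raises(DegenerateDataError):
            fit_svm(data)

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            ClassifierSpec(C=-1.0)
        with pytest.raises(ParameterError):
            ClassifierSpec(kernel="sigmoid")


class TestSelectC:
    def test_single_value_grid(self):
        assert select_C(separable_data(), grid=[7.5], seed=0) == 7.5

    def test_tie_breaks_to_smallest(self):
        # trivially separable: every C is equally good
        c = select_C(separable_data(), grid=[0.01, 1.0, 100.0], seed=0)
        assert c == 0.01

    def test_returned_c_maximizes_inner_cv(self, rng):
        # noisy overlap so the grid members genuinely differ
        X = np.vstack([rng.normal(0, 1.5, (30, 2)), rng.normal(1.5, 1.5, (30, 2))])
        data = vectors_from_xy(X, ["stance"] * 30 + ["swing"] * 30)
        grid = [0.01, 1.0, 100.0]

        def inner_cv_acc(c):
            from sklearn.model_selection import StratifiedKFold
            from emgknee.types import feature_matrix
            from emgknee.classify import _fit_xy
            Xm, ym, _ = feature_matrix(data)
            skf = StratifiedKFold(5, shuffle=True, random_state=3)
            accs = [
                np.mean(_fit_xy(Xm[tr], ym[tr], ClassifierSpec(C=c)).predict(Xm[te]) == ym[te])
                for tr, te in skf.split(Xm, ym)
            ]
            return np.mean(accs)

        best = select_C(data, grid=grid, seed=3)
        oracle = {c: inner_cv_acc(c) for c in grid}
        assert oracle[best] == max(oracle.values())

    def test_invalid_grid(self):
        with pytest.raises(ParameterError):
            select_C(separable_data(), grid=[])
        with pytest.raises(ParameterError):
            select_C(separable_data(), grid=[-1.0, 1.0])


class TestRepeatedCv:
    def class_coded_vectors(self, counts={"standing": 10, "sitting": 10,
                                          "stance": 10, "swing": 10}):
        out = []
        for i, (lab, n) in enumerate(counts.items()):
            for _ in range(n):
                out.append(FeatureVector(names=("f",), values=[float(i)], label=lab))
        return out

    def test_perfect_features_give_accuracy_one(self):
        rep = repeated_cv(self.class_coded_vectors(), n_repeats=3, seed=0)
        assert rep.mean_accuracy == 1.0
        assert rep.std_accuracy == 0.0

    def test_shape_and_determinism(self):
        data = separable_data(n=20)
        r1 = repeated_cv(data, n_repeats=4, n_folds=5, seed=42)
        r2 = repeated_cv(data, n_repeats=4, n_folds=5, seed=42)
        assert r1.accuracies.shape == (4, 5)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        np.testing.assert_array_equal(r1.fold_ids, r2.fold_ids)
        r3 = repeated_cv(data, n_repeats=4, n_folds=5, seed=43)
        assert not np.array_equal(r1.fold_ids, r3.fold_ids)

    def test_stratification_error_for_small_class(self):
        data = self.class_coded_vectors({"standing": 3, "sitting": 10,
                                         "stance": 10, "swing": 10})
        with pytest.raises(StratificationError):
            repeated_cv(data, n_folds=5, n_repeats=2, seed=0)

    def test_folds_are_stratified(self):
        data = self.class_coded_vectors({"standing": 10, "sitting": 10,
                                         "stance": 20, "swing": 20})
        rep = repeated_cv(data, n_repeats=2, n_folds=5, seed=1)
        labels = np.array([v.label for v in data])
        for r in range(2):
            for f in range(5):
                in_fold = labels[rep.fold_ids[r] == f]
                assert set(in_fold) == {"standing", "sitting", "stance", "swing"}


class TestCompareFeatureSets:
    def test_single_set(self, default_dataset):
        reports = compare_feature_sets(default_dataset, sets=["freq"],
                                       seed=5, n_repeats=2)
        assert len(reports) == 1
        assert reports[0].feature_set_name == "freq"

    def test_identical_partitions_across_sets(self, default_dataset):
        reports = compare_feature_sets(default_dataset, sets=["time", "freq"],
                                       seed=5, n_repeats=2)
        np.testing.assert_array_equal(reports[0].fold_ids, reports[1].fold_ids)

    def test_unknown_set_rejected(self, default_dataset):
        with pytest.raises(ConfigurationError):
            compare_feature_sets(default_dataset, sets=["cepstral"], n_repeats=1)


class TestAnova:
    def make_features(self, means, n=50, rng=None):
        rng = rng or np.random.default_rng(0)
        out = []
        for lab, mu in zip(("standing", "sitting", "stance", "swing"), means):
            for _ in range(n):
                out.append(FeatureVector(names=("MAV",),
                                         values=[mu + rng.normal()], label=lab))
        return out

    def test_large_effect_detected(self):
        res = anova_by_motion(self.make_features([0, 1, 2, 3]), "MAV")
        assert res.pvalue < 1e-3
        assert res.statistic > 0

    def test_type_one_error_rate(self, rng):
        """Under the null (all groups from one distribution), p < 0.05 in
        roughly 5% of simulated runs."""
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            feats = self.make_features([0, 0, 0, 0], n=20, rng=rng)
            if anova_by_motion(feats, "MAV").pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_degenerate_groups_rejected(self):
        feats = [FeatureVector(names=("MAV",), values=[1.0], label=lab)
                 for lab in ("standing", "standing", "sitting", "sitting")]
        with pytest.raises(DegenerateDataError):
            anova_by_motion(feats, "MAV")

    def test_absent_feature_rejected(self):
        feats = self.make_features([0, 1, 2, 3], n=3)
        with pytest.raises(ConfigurationError):
            anova_by_motion(feats, "RMS")


class TestPairedTtest:
    def test_identical_pairs(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_large_shift_detected(self, rng):
        a = rng.normal(size=30)
        b = a + 1.0 + rng.normal(scale=0.01, size=30)
        assert paired_ttest(b, a).pvalue < 1e-6

    def test_length_mismatch_and_single_pair(self):
        with pytest.raises(ValidationError):
            paired_ttest([1.0, 2.0], [1.0])
        with pytest.raises(ValidationError):
            paired_ttest([1.0], [2.0])
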