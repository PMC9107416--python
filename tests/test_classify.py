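"""Linear SVM training, LOOCV metrics, and the SFFS subset search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from falffmvpa.classify import (
    _confusion_metrics,
    _loocv_core,
    encode_labels,
    exhaustive_search,
    loocv,
    sffs,
    train_linear_margin_classifier,
)
from falffmvpa.synth import CohortSpec, cohort_features, generate_cohort


def _informative_dataset(seed, n_per_group=10, n_noise=4, sep=3.0):
    """1 informative + n_noise pure-noise features."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    y = np.r_[np.ones(n_per_group, int), np.zeros(n_per_group, int)]
    X = rng.normal(size=(n, 1 + n_noise))
    X[:n_per_group, 0] += sep
    cols = ["signal"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestTrainClassifier:
    def test_separable_1d_boundary_near_zero(self):
        X = np.r_[np.full(5, -1.0), np.full(5, 1.0)][:, None]
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        clf = train_linear_margin_classifier(X, y)
        assert np.all(clf.predict(X) == y)  # 100% training accuracy
        boundary = -clf.intercept_[0] / clf.coef_[0, 0]
        assert abs(boundary) < 0.2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_linear_margin_classifier(np.zeros((4, 2)), np.ones(4, int))

    def test_duplicated_column_preserves_predictions(self):
        # oracle: fit both designs, compare predicted labels
        X, y = _informative_dataset(0, n_noise=1)
        single = train_linear_margin_classifier(X[["signal"]], y)
        doubled = train_linear_margin_classifier(
            pd.concat([X[["signal"]], X[["signal"]].rename(
                columns={"signal": "copy"})], axis=1), y)
        Xs = X[["signal"]].to_numpy()
        assert np.array_equal(single.predict(Xs),
                              doubled.predict(np.c_[Xs, Xs]))

    def test_label_flip_negates_decision_function(self):
        X, y = _informative_dataset(1)
        a = train_linear_margin_classifier(X, y)
        b = train_linear_margin_classifier(X, 1 - y)
        # libsvm converges to the mirrored solution within its tolerance
        assert np.allclose(a.decision_function(X.to_numpy()),
                           -b.decision_function(X.to_numpy()), atol=1e-2)
        assert np.array_equal(a.predict(X.to_numpy()),
                              1 - b.predict(X.to_numpy()))

    def test_label_encoding(self):
        assert np.array_equal(encode_labels(["tVNS", "sham", "tVNS"]), [1, 0, 1])
        with pytest.raises(ValueError):
            encode_labels(["tVNS", "mystery"])
        with pytest.raises(ValueError):
            encode_labels([0, 2])


class TestConfusionMetrics:
    def test_printed_accuracy_formula(self):
        # 27 right predictions of 34 tests
        y = np.r_[np.ones(17, int), np.zeros(17, int)]
        pred = y.copy()
        pred[[0, 1, 2, 3, 17, 18, 19]] = 1 - pred[[0, 1, 2, 3, 17, 18, 19]]
        m = _confusion_metrics(y, pred)
        assert m["ca"] == pytest.approx(79.41, abs=0.005)

    def test_balanced_accuracy_is_mean_of_sens_and_spec(self):
        # the identity behind the printed BA values, e.g. (0.92+0.73)/2
        assert (0.92 + 0.73) / 2 == pytest.approx(0.83, abs=0.0051)
        assert (1.00 + 0.90) / 2 == pytest.approx(0.95, abs=1e-12)

    def test_dor_from_two_by_two_identities(self):
        # sens 0.9, spec 0.8 from tp=9 fn=1 tn=8 fp=2 -> DOR 36
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        pred = y.copy()
        pred[0] = 0          # one miss
        pred[[10, 11]] = 1   # two false alarms
        m = _confusion_metrics(y, pred)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["dor"] == pytest.approx(36.0)

    def test_zero_cell_uses_continuity_correction(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        m = _confusion_metrics(y, y)  # perfect prediction: fn = fp = 0
        assert np.isfinite(m["dor"]) and m["dor"] > 1

    @pytest.mark.parametrize("seed", range(8))
    def test_identities_hold_on_random_outcomes(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pred = rng.integers(0, 2, 30)
        m = _confusion_metrics(y, pred)
        n = m["tp"] + m["fn"] + m["tn"] + m["fp"]
        assert n == 30
        assert m["ca"] == pytest.approx(100 * (m["tp"] + m["tn"]) / n)
        assert m["sensitivity"] == pytest.approx(m["tp"] / (m["tp"] + m["fn"]))
        assert m["specificity"] == pytest.approx(m["tn"] / (m["tn"] + m["fp"]))
        assert m["balanced_accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2)


class TestLOOCV:
    def test_fold_loop_matches_independent_refit(self):
        # independent oracle: per-fold refit written from scratch
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(16, 3))
            y = rng.integers(0, 2, 16)
            if y.sum() < 2 or y.sum() > 14:
                continue
            naive = []
            for i in range(16):
                tr = np.arange(16) != i
                clf = SVC(kernel="linear", C=1.0,
                          class_weight="balanced").fit(X[tr], y[tr])
                naive.append(int(clf.predict(X[i:i + 1])[0]))
            res = _loocv_core(X, y, ("a", "b", "c"), 1.0)
            assert list(res.per_fold_predictions) == naive

    def test_row_order_invariance(self, effect_features):
        y = effect_features["group"]
        base = loocv(effect_features, y, subset=["ROI00", "ROI01"])
        perm = np.random.default_rng(4).permutation(len(effect_features))
        shuffled = effect_features.iloc[perm]
        res = loocv(shuffled, shuffled["group"], subset=["ROI00", "ROI01"])
        assert res.ca == base.ca
        assert np.array_equal(np.asarray(res.per_fold_predictions),
                              np.asarray(base.per_fold_predictions)[perm])

    def test_treatment_is_positive_class(self, effect_features):
        res = loocv(effect_features, effect_features["group"],
                    subset=["ROI00", "ROI01", "ROI02"])
        n_treated = (effect_features["group"] == "tVNS").sum()
        assert res.tp + res.fn == n_treated

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            loocv(np.zeros((3, 2)), [0, 1, 0])

    def test_unknown_subset_feature(self, effect_features):
        with pytest.raises(KeyError):
            loocv(effect_features, effect_features["group"], subset=["nope"])


class TestSFFS:
    def test_finds_the_informative_feature(self):
        X, y = _informative_dataset(0)
        trace, best = sffs(X, y)
        assert "signal" in best.subset
        # oracle: exhaustive search over all 31 subsets
        exh = exhaustive_search(X, y)
        assert best.ca == exh.ca

    @pytest.mark.parametrize("seed", range(5))
    def test_never_beats_exhaustive_search(self, seed):
        X, y = _informative_dataset(seed, n_per_group=8, n_noise=4, sep=1.0)
        _, best = sffs(X, y)
        exh = exhaustive_search(X, y)
        assert best.ca <= exh.ca

    def test_never_below_best_single_feature(self, effect_features):
        y = effect_features["group"]
        _, best = sffs(effect_features, y)
        singles = max(
            loocv(effect_features, y, subset=[c]).ca
            for c in effect_features.columns if c != "group")
        assert best.ca >= singles

    def test_trace_removals_strictly_improve(self):
        X, y = _informative_dataset(2, n_per_group=8, sep=1.0)
        trace, best = sffs(X, y)
        sizes = {}
        for step in trace.steps:
            if step.action == "remove":
                k = len(step.subset)
                assert step.criterion > sizes[k]
            sizes[len(step.subset)] = max(
                sizes.get(len(step.subset), -np.inf), step.criterion)
        k_best = len(best.subset)
        assert trace.best_per_size[k_best][1] == best.ca

    def test_best_prefers_smaller_subsets_on_ties(self):
        # a perfectly separable single feature: adding more cannot help
        X, y = _informative_dataset(3, sep=10.0)
        _, best = sffs(X, y)
        assert best.subset == ("signal",)
        assert best.ca == 100.0

    def test_selection_optimism_on_pure_noise(self):
        # best-of-search CA sits well above chance even with no signal
        cas = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(20, 6)),
                             columns=[f"n{i}" for i in range(6)])
            y = np.r_[np.ones(10, int), np.zeros(10, int)]
            _, best = sffs(X, y)
            cas.append(best.ca)
        assert np.mean(cas) > 55.0

    def test_max_size_validation(self, effect_features):
        with pytest.raises(ValueError):
            sffs(effect_features, effect_features["group"], max_size=0)
        with pytest.raises(ValueError):
            sffs(effect_features, effect_features["group"], max_size=99)
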