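"""Split, scaling, AUC, Youden thresholding, metrics, and CV tuning, each
checked against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold

import sepsis_audit as sa
from sepsis_audit.models import (
    ScalingBounds,
    inverse_scaler,
    youden_threshold,
)
from tests.conftest import random_score_label_fixture


def brute_force_auc(scores, labels):
    """Exhaustive positive/negative pair counting, ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive scan over the candidate thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    u = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2, [np.inf]))
    best_j, best_t = -np.inf, None
    for t in candidates:
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if j > best_j:  # strict: ties keep the lowest candidate
            best_j, best_t = j, t
    return best_t, best_j


class TestSplit:
    def test_reference_cohort_split_sizes(self, small_cohort):
        """round(0.7 * 5783) = 4048 / 1735, the reference column sums."""
        df = pd.DataFrame({"patient_id": range(5783), "x": 0.0})
        train, test = sa.split_cohort(df, seed=0)
        assert (len(train), len(test)) == (4048, 1735)

    def test_partition_is_disjoint_and_exhaustive(self, small_cohort):
        train, test = sa.split_cohort(small_cohort, seed=1)
        ids = set(train["patient_id"]) | set(test["patient_id"])
        assert not (set(train["patient_id"]) & set(test["patient_id"]))
        assert ids == set(small_cohort["patient_id"])

    def test_degenerate_fractions_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sa.split_cohort(small_cohort, train_fraction=1.0)
        with pytest.raises(ValueError):
            sa.split_cohort(small_cohort.head(1))

    def test_same_seed_identical_partition(self, small_cohort):
        a = sa.split_cohort(small_cohort, seed=5)
        b = sa.split_cohort(small_cohort, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])


class TestScaler:
    def test_affine_map_on_known_column(self):
        df = pd.DataFrame({"sofa_24h": [2, 4, 6], "sirs_24h": [0, 1, 4],
                           "age": [20, 50, 90]})
        bounds = sa.fit_scaler(df)
        X = sa.apply_scaler(bounds, df)
        assert X[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_test_value_beyond_training_bounds_passes_through(self):
        train = pd.DataFrame({"sofa_24h": [0, 10], "sirs_24h": [0, 4],
                              "age": [20, 80]})
        test = pd.DataFrame({"sofa_24h": [20], "sirs_24h": [2], "age": [50]})
        bounds = sa.fit_scaler(train)
        assert sa.apply_scaler(bounds, test)[0, 0] == pytest.approx(2.0)

    def test_round_trip_recovers_inputs(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 3)),
                          columns=["sofa_24h", "sirs_24h", "age"])
        bounds = sa.fit_scaler(df)
        back = inverse_scaler(bounds, sa.apply_scaler(bounds, df))
        np.testing.assert_allclose(back, df.to_numpy(), atol=1e-12)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"sofa_24h": [3, 3, 3], "sirs_24h": [0, 1, 2],
                           "age": [20, 30, 40]})
        with pytest.raises(ValueError, match="sofa_24h"):
            sa.fit_scaler(df)


class TestAUC:
    def test_perfect_ranking(self):
        assert sa.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert sa.auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_pair_counting_example(self):
        assert sa.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_returns_undefined_signal(self):
        assert np.isnan(sa.auc([0.1, 0.2], [1, 1]))

    def test_matches_brute_force_and_sklearn_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores, labels = random_score_label_fixture(rng, n)
            if rng.random() < 0.5:
                scores = np.round(scores, 1)  # induce ties
            ours = sa.auc(scores, labels)
            assert ours == pytest.approx(brute_force_auc(scores, labels))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_score_label_fixture(rng, 30)
        transformed = np.exp(3 * scores) + 7
        assert sa.auc(scores, labels) == pytest.approx(sa.auc(transformed, labels))

    def test_label_swap_symmetry_without_ties(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert sa.auc(scores, 1 - labels) == pytest.approx(1 - sa.auc(scores, labels))


class TestYouden:
    def test_perfect_separation_returns_lowest_maximizing_midpoint(self):
        t = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.2], [1, 1])

    def test_uninformative_scores_give_near_zero_j(self, rng):
        scores, labels = random_score_label_fixture(rng, 4000, informative=False)
        t = youden_threshold(scores, labels)
        pred = scores >= t
        labels = labels.astype(bool)
        j = (pred & labels).sum() / labels.sum() + (
            (~pred & ~labels).sum() / (~labels).sum()
        ) - 1
        assert 0 <= j < 0.1

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores, labels = random_score_label_fixture(rng, n)
            if rng.random() < 0.5:
                scores = np.round(scores, 1)
            t_oracle, j_oracle = brute_force_youden(scores, labels)
            t = youden_threshold(scores, labels)
            assert t == pytest.approx(t_oracle)


class TestMetrics:
    def test_threshold_minus_inf_predicts_all_positive(self, rng):
        scores, labels = random_score_label_fixture(rng, 50)
        ms = sa.compute_metrics(scores, -np.inf, labels)
        assert ms.recall == 1.0 and ms.specificity == 0.0

    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        ms = sa.compute_metrics(scores, 0.5, labels)
        assert ms.precision == pytest.approx(0.75)
        assert ms.recall == pytest.approx(0.75)
        assert ms.specificity == pytest.approx(5 / 6)
        assert ms.accuracy == pytest.approx(0.8)

    def test_accuracy_decomposition_identity(self, rng):
        """accuracy = prevalence*recall + (1-prevalence)*specificity."""
        import warnings

        for _ in range(100):
            scores, labels = random_score_label_fixture(rng, 40)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                ms = sa.compute_metrics(scores, float(rng.normal()), labels)
            prev = np.mean(labels)
            assert ms.accuracy == pytest.approx(
                prev * ms.recall + (1 - prev) * ms.specificity
            )
            if ms.precision + ms.recall > 0:
                assert ms.f1_binary == pytest.approx(
                    2 * ms.precision * ms.recall / (ms.precision + ms.recall)
                )

    def test_no_predicted_positive_flags_precision(self, rng):
        scores, labels = random_score_label_fixture(rng, 20)
        with pytest.warns(UserWarning, match="precision"):
            ms = sa.compute_metrics(scores, np.inf, labels)
        assert ms.precision == 0.0 and ms.precision_undefined


class TestTuneAndFit:
    def test_grid_of_size_one_is_fitted_without_search(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + rng.normal(size=60) > 0).astype(int)
        spec = sa.ModelSpec(name="lr", estimator=LogisticRegression(max_iter=200),
                            hyperparameter_grid={"C": [1.0]}, seed=0)
        fitted = sa.tune_and_fit(spec, X, y)
        assert fitted.chosen_hyperparameters == {"C": 1.0}
        assert fitted.model.cv_results_ is None

    def test_separable_data_training_auc_one(self, rng):
        sofa = np.arange(40, dtype=float)
        X = np.column_stack([sofa, rng.normal(size=40), rng.normal(size=40)])
        y = (sofa >= 20).astype(int)
        spec = sa.ModelSpec(name="lr", estimator=LogisticRegression(max_iter=500),
                            hyperparameter_grid={}, seed=0)
        fitted = sa.tune_and_fit(spec, X, y)
        assert sa.auc(fitted.score_rows(X), y) == 1.0

    def test_single_class_training_labels_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        spec = sa.ModelSpec(name="lr", estimator=LogisticRegression(),
                            hyperparameter_grid={}, seed=0)
        with pytest.raises(ValueError):
            sa.tune_and_fit(spec, X, np.ones(20, dtype=int))

    def test_cv_winner_matches_independent_fold_loop_oracle(self, rng):
        """60-patient fixture: exhaustive re-evaluation of every grid point
        with the same fold assignment must pick the same winner."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + 0.8 * rng.normal(size=60) > 0).astype(int)
        grid = {"C": [0.01, 0.1, 1.0, 10.0]}
        seed = 123
        spec = sa.ModelSpec(name="lr", estimator=LogisticRegression(max_iter=500),
                            hyperparameter_grid=grid, cv_folds=5, seed=seed)
        fitted = sa.tune_and_fit(spec, X, y)

        folds = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        splits = list(folds.split(X, y))
        means = []
        for params in ParameterGrid(grid):
            aucs = []
            for tr, te in splits:
                est = LogisticRegression(max_iter=500, **params).fit(X[tr], y[tr])
                aucs.append(sa.auc(est.decision_function(X[te]), y[te]))
            means.append(np.mean(aucs))
        winner = list(ParameterGrid(grid))[int(np.argmax(means))]
        assert fitted.chosen_hyperparameters == winner

    def test_youden_threshold_chosen_on_training_scores(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + rng.normal(size=80) > 0).astype(int)
        spec = sa.ModelSpec(name="lr", estimator=LogisticRegression(max_iter=500),
                            hyperparameter_grid={}, seed=0)
        fitted = sa.tune_and_fit(spec, X, y)
        expected = youden_threshold(fitted.score_rows(X), y)
        assert fitted.threshold == pytest.approx(expected)


def test_sixteen_default_specs_have_unique_names():
    specs = sa.default_model_specs(seed=0)
    names = [s.name for s in specs]
    assert len(names) == 16 and len(set(names)) == 16
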