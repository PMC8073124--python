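"""Kennard–Stone splitting, PLS core, LOOCV, LV selection, metrics."""

import itertools

import numpy as np
import pytest

import ftirgrid as fg
from ftirgrid.chemometrics import (
    _class_order_of,
    _kennard_stone_indices,
    accuracy,
    membership_matrix,
    regression_target,
    rmsep,
)


def _labeled_set(matrix, labels):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    return fg.SpectraSet(
        fg.WavenumberAxis(np.linspace(1000.0, 2000.0, matrix.shape[1])),
        matrix,
        np.asarray(labels),
        np.array([f"s{i}" for i in range(matrix.shape[0])], dtype=object),
    )


class TestKennardStone:
    def test_study_split_sizes(self, study):
        split = fg.kennard_stone_split(study)
        assert len(split.model_ids) == 34
        assert len(split.test_ids) == 14
        # per-class: floor(0.75·n) in the model set
        model_labels = study.select_ids(split.model_ids).labels
        labels, counts = np.unique(model_labels, return_counts=True)
        assert dict(zip(labels, counts)) == {"RWPE-1": 10, "22Rv1": 5, "PC3": 5, "Du145": 7, "LNCaP": 7}

    def test_deterministic(self, study):
        a = fg.kennard_stone_split(study)
        b = fg.kennard_stone_split(study)
        assert a == b

    def test_collinear_points_match_exhaustive_maxmin(self):
        # 5 collinear points, select 3: the greedy picks both extremes then
        # the point maximizing min distance — equal to the exhaustive optimum
        x = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        chosen = set(_kennard_stone_indices(x, 3))
        best, best_score = None, -1.0
        for subset in itertools.combinations(range(5), 3):
            score = min(abs(x[a, 0] - x[b, 0]) for a, b in itertools.combinations(subset, 2))
            if score > best_score:
                best, best_score = set(subset), score
        assert chosen == best

    def test_singleton_class_rejected(self):
        s = _labeled_set(np.random.default_rng(0).random((3, 8)), ["a", "a", "b"])
        with pytest.raises(ValueError):
            fg.kennard_stone_split(s)


class TestPLSCore:
    def test_exact_recovery_of_low_rank_linear_map(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(3, 20))
        scores = rng.normal(size=(30, 3))
        x = scores @ basis
        b = rng.normal(size=20)
        y = x @ b
        model = fg.pls_fit(x, y, 3)
        assert np.abs(fg.pls_predict(model, x) - y).max() < 1e-8

    def test_full_rank_beta_equals_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        model = fg.pls_fit(x, y, 6)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        beta_ols = np.linalg.lstsq(xc, yc, rcond=None)[0]
        assert np.abs(model.beta[0] - beta_ols).max() < 1e-8

    def test_prediction_at_training_mean_is_response_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        model = fg.pls_fit(x, y, 4)
        assert abs(fg.pls_predict(model, x.mean(axis=0))[0] - y.mean()) < 1e-10

    def test_agrees_with_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        x = rng.normal(size=(25, 40))
        y = x @ rng.normal(size=40) + 0.1 * rng.normal(size=25)
        for k in (1, 3, 5):
            mine = fg.pls_predict(fg.pls_fit(x, y, k), x)
            sk = PLSRegression(n_components=k, scale=False).fit(x, y).predict(x).ravel()
            assert np.abs(mine - sk).max() < 1e-8

    def test_shape_guards(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            fg.pls_fit(x, y, 20)
        model = fg.pls_fit(x, y, 2)
        with pytest.raises(ValueError):
            fg.pls_predict(model, np.zeros((2, 7)))


class TestLOOCVRegression:
    def test_constant_response_near_zero_error(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 6))
        curve = fg.loocv_curve_regression(x, np.full(12, 2.0), lv_max=4)
        assert np.all(curve < 1e-8)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 6))
        y = x @ rng.normal(size=6) + 0.2 * rng.normal(size=10)
        lv_max = 4
        curve = fg.loocv_curve_regression(x, y, lv_max)
        # oracle: separate fit for every (fold, LV) pair
        oracle = np.zeros((lv_max, 10))
        for k in range(1, lv_max + 1):
            for i in range(10):
                mask = np.arange(10) != i
                m = fg.pls_fit(x[mask], y[mask], k)
                oracle[k - 1, i] = float(fg.pls_predict(m, x[i])[0] - y[i]) ** 2
        assert np.abs(curve - np.sqrt(oracle.mean(axis=1))).max() < 1e-10

    def test_single_direction_signal_recovered_within_noise(self):
        rng = np.random.default_rng(8)
        direction = rng.normal(size=30)
        t = rng.normal(size=30)
        sigma = 0.1
        x = np.outer(t, direction) + 0.01 * rng.normal(size=(30, 30))
        y = 2.0 * t + rng.normal(0, sigma, 30)
        curve = fg.loocv_curve_regression(x, y, lv_max=4)
        assert curve[0] < 2 * sigma

    def test_lv_max_clamped(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(6, 10))
        with pytest.warns(UserWarning):
            curve = fg.loocv_curve_regression(x, rng.normal(size=6), lv_max=8)
        assert curve.size == 4

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        a = fg.loocv_curve_regression(x, y, 3)
        b = fg.loocv_curve_regression(x[perm], y[perm], 3)
        assert np.allclose(a, b, atol=1e-12)


class TestSelectLV:
    def test_decreasing_curve_selects_last(self):
        assert fg.select_lv_regression(np.linspace(5, 1, 8)) == 8

    def test_increasing_curve_selects_first(self):
        assert fg.select_lv_regression(np.linspace(1, 5, 8)) == 1

    def test_local_minimum_override(self):
        # LV 3 (value 2) is followed by 2.5 and 2.6, both strictly higher,
        # so it wins over the global minimum at LV 8
        curve = np.array([5, 3, 2, 2.5, 2.6, 1.9, 1.8, 1.7])
        assert fg.select_lv_regression(curve) == 3

    def test_classification_argmax_with_tie_to_smaller(self):
        assert fg.select_lv_classification(np.array([0.5, 0.9, 0.9, 0.8, 0.8, 0.8, 0.8, 0.8])) == 2
        assert fg.select_lv_classification(np.linspace(0.1, 0.9, 8)) == 8
        assert fg.select_lv_classification(np.full(8, 0.7)) == 1


class TestLOOCVClassification:
    def test_separable_two_class_toy_perfect_at_lv1(self):
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 0.1, (8, 5)) + [5, 0, 0, 0, 0], rng.normal(0, 0.1, (8, 5))])
        labels = np.array(["a"] * 8 + ["b"] * 8)
        acc = fg.loocv_curve_classification(x, labels, lv_max=2)
        assert acc[0] == 1.0

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(40, 30))
        labels = np.array((["a", "b", "c", "d"] * 10))
        acc = fg.loocv_curve_classification(x, labels, lv_max=3)
        assert abs(acc.mean() - 0.25) < 0.15

    def test_matches_double_loop_oracle_on_small_toy(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(8, 5))
        labels = np.array(["a", "a", "b", "b", "a", "b", "a", "b"])
        lv_max = 3
        acc = fg.loocv_curve_classification(x, labels, lv_max)
        order = _class_order_of(labels)
        y = membership_matrix(labels, order)
        oracle = np.zeros((lv_max, 8))
        for k in range(1, lv_max + 1):
            for i in range(8):
                mask = np.arange(8) != i
                m = fg.pls_fit(x[mask], y[mask], k)
                pred = fg.pls_predict(m, x[i])
                oracle[k - 1, i] = order[int(np.argmax(pred))] == labels[i]
        assert np.allclose(acc, oracle.mean(axis=1))


class TestAssignmentAndMetrics:
    def test_membership_matrix_rows_one_hot(self, study):
        y = membership_matrix(study.labels)
        assert y.shape == (48, 5)
        assert np.all(y.sum(axis=1) == 1.0)
        assert set(np.unique(y)) == {0.0, 1.0}

    def test_progression_coding(self):
        y = regression_target(["RWPE-1", "22Rv1", "PC3", "Du145", "LNCaP"])
        assert list(y) == [-2, -1, 0, 1, 2]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            regression_target(["HeLa"])

    def test_argmax_assignment(self):
        pred = np.array([[0.9, 0.1, 0.2, 0.3, 0.1], [0.0, 0.0, 0.8, 0.1, 0.2]])
        assert list(fg.plsda_assign(pred)) == ["RWPE-1", "PC3"]

    def test_tie_goes_to_lowest_class_index(self):
        pred = np.array([[0.4, 0.4, 0.1, 0.1, 0.0]])
        assert fg.plsda_assign(pred)[0] == "RWPE-1"

    def test_rmsep_and_accuracy_arithmetic(self):
        assert rmsep([0.0, 0.0], [1.0, -1.0]) == 1.0
        assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert accuracy(["a", "b", "c", "d"], ["a", "b", "c", "x"]) == 0.75
        with pytest.raises(ValueError):
            rmsep([1.0], [1.0, 2.0])


def test_full_pipeline_on_clean_study_separable(clean_study):
    # end-to-end separability bound: in-grid denoiser + ALS + CON
    from ftirgrid.grid import MethodSpec, preprocess_set

    triple = (
        MethodSpec("denoise", "EIL", (("lambda", 2),)),
        MethodSpec("baseline", "ALS", (("lambda", 1e6),)),
        MethodSpec("normalize", "CON"),
    )
    processed = preprocess_set(clean_study, triple)
    acc = fg.loocv_curve_classification(processed.absorbance, processed.labels)
    assert acc.max() >= 0.9


def test_plsr_parameter_recovery_on_synthetic_trend(clean_study):
    # class-ordered trend must be recoverable: RMSEP ≤ 2× injected noise
    rng = np.random.default_rng(14)
    y = regression_target(clean_study.labels)
    sigma = 0.1
    y_noisy = y + rng.normal(0, sigma, y.size)
    split = fg.kennard_stone_split(clean_study)
    model_set = clean_study.select_ids(split.model_ids)
    test_set = clean_study.select_ids(split.test_ids)
    y_model = regression_target(model_set.labels) + rng.normal(0, sigma, 34)
    curve = fg.loocv_curve_regression(model_set.absorbance, y_model)
    lv = fg.select_lv_regression(curve)
    model = fg.pls_fit(model_set.absorbance, y_model, lv)
    pred = fg.pls_predict(model, test_set.absorbance)
    err = rmsep(regression_target(test_set.labels), pred)
    assert err <= 2 * max(sigma, curve.min())


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 10.0), min_size=8, max_size=8))
def test_regression_lv_rule_never_beats_local_minimum(curve):
    # the chosen LV is either a genuine local minimum (two strictly
    # higher successors) or the global minimum of the curve
    r = np.asarray(curve)
    lv = fg.select_lv_regression(r)
    m = lv - 1
    is_local = m + 2 < len(r) and r[m] < r[m + 1] and r[m] < r[m + 2]
    assert is_local or np.isclose(r[m], r.min())
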