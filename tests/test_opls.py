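import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import sersdx
from sersdx import (
    cross_validated_q2,
    dummy_response,
    fit_opls,
    predict_opls,
    scores_for_plot,
)


def two_class_data(n=16, p=6, sep=3.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, noise, size=(n, p))
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
    X[labels == "b", :2] += sep
    return X, labels


def test_dummy_response_rows_sum_to_one():
    Y = dummy_response(["a", "b", "a", "c"], ["a", "b", "c"])
    assert Y.shape == (4, 3)
    assert np.array_equal(Y.sum(axis=1), np.ones(4))
    with pytest.raises(ValueError, match="not in class order"):
        dummy_response(["a", "z"], ["a", "b"])


def test_opls_without_orthogonal_components_equals_plain_nipals_pls():
    """With 0 orthogonal components the predictive part is ordinary PLS."""
    X, labels = two_class_data(n=20, p=8, seed=3)
    model = fit_opls(X, labels, n_predictive=2, n_orthogonal=0, cv_folds=4, seed=0)
    Y = dummy_response(labels, model.class_labels)
    ref = PLSRegression(n_components=2, scale=False).fit(X, Y - Y.mean(axis=0))
    for a in range(2):
        t_ours, t_ref = model.scores[:, a], ref.x_scores_[:, a]
        sign = np.sign(t_ours @ t_ref)
        assert np.allclose(t_ours, sign * t_ref, atol=1e-8)
        assert np.allclose(model.weights[:, a], sign * ref.x_weights_[:, a], atol=1e-8)


def test_q2_matches_brute_force_leave_one_out():
    """Q2 with n folds equals explicit per-sample refit PRESS accumulation."""
    X, labels = two_class_data(n=10, p=5, sep=2.0, seed=7)
    order = ["a", "b"]
    Y = dummy_response(labels, order)

    # independent oracle: 1-component PLS via SVD of X'Y, refit per left-out row
    press, idx = 0.0, np.arange(10)
    for i in idx:
        tr = idx != i
        xm, ym = X[tr].mean(axis=0), Y[tr].mean(axis=0)
        Xc, Yc = X[tr] - xm, Y[tr] - ym
        u, _, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        w = u[:, 0]
        t = Xc @ w
        q = Yc.T @ t / (t @ t)
        t_new = (X[i] - xm) @ w
        press += float(np.sum((Y[i] - ym - t_new * q) ** 2))
    ss0 = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    q2_oracle = 1.0 - press / ss0

    q2 = cross_validated_q2(
        X, labels, n_predictive=1, n_orthogonal=0, cv_folds=10, seed=0, class_order=order
    )
    assert q2 == pytest.approx(q2_oracle, abs=1e-8)


def test_permuted_labels_destroy_predictivity():
    """Random label permutations give Q2 at or below the 0.05 validity line."""
    rng = np.random.default_rng(123)
    X, labels = two_class_data(n=100, p=15, sep=3.0, seed=5)
    below = 0
    n_rep = 30
    for _ in range(n_rep):
        perm = rng.permutation(labels.size)
        q2 = cross_validated_q2(
            X, labels[perm], 1, 0, cv_folds=5, seed=0, class_order=["a", "b"]
        )
        below += q2 <= 0.05
    assert below >= 0.9 * n_rep


def test_self_classification_on_separable_classes(separable_blobs):
    X, labels = separable_blobs
    model = fit_opls(X, labels, n_orthogonal=1, cv_folds=5, seed=0)
    _, pred = predict_opls(model, X)
    assert np.array_equal(pred, labels)


def test_prediction_of_training_row_matches_in_fit_scores(separable_blobs):
    X, labels = separable_blobs
    model = fit_opls(X, labels, n_orthogonal=1, cv_folds=5, seed=0)
    all_scores, _ = predict_opls(model, X)
    one_score, _ = predict_opls(model, X[7])
    assert np.allclose(one_score[0], all_scores[7])


def test_balanced_binary_scores_sum_to_about_one(separable_blobs):
    X, labels = separable_blobs
    model = fit_opls(X, labels, n_orthogonal=0, cv_folds=5, seed=0)
    scores, _ = predict_opls(model, X)
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-8)


def test_deflation_conserves_x_sum_of_squares(preprocessed_cohort, class_order):
    sset = preprocessed_cohort
    model = fit_opls(
        sset.intensities, sset.labels, n_orthogonal=1, seed=1,
        class_order=class_order, compute_q2=False,
    )
    Xc = sset.intensities - model.x_mean
    ss_total = np.sum(Xc**2)
    explained = sum(
        np.sum(np.outer(model.scores[:, a], model.loadings[:, a]) ** 2)
        for a in range(model.n_predictive)
    ) + sum(
        np.sum(np.outer(model.ortho_scores[:, a], model.ortho_loadings[:, a]) ** 2)
        for a in range(model.n_orthogonal)
    )
    assert explained / ss_total == pytest.approx(model.r2x_cum, abs=1e-6)
    assert 0.0 <= model.r2x_cum <= 1.0
    assert 0.0 <= model.r2y_cum <= 1.0


def test_orthogonal_scores_uncorrelated_with_response(preprocessed_cohort, class_order):
    sset = preprocessed_cohort
    model = fit_opls(
        sset.intensities, sset.labels, n_orthogonal=2, seed=1,
        class_order=class_order, compute_q2=False,
    )
    Y = dummy_response(sset.labels, model.class_labels)
    for a in range(model.n_orthogonal):
        for j in range(Y.shape[1]):
            r = np.corrcoef(model.ortho_scores[:, a], Y[:, j])[0, 1]
            assert abs(r) < 1e-6


def test_r2y_non_decreasing_in_predictive_components(preprocessed_cohort, class_order):
    sset = preprocessed_cohort
    r2 = [
        fit_opls(
            sset.intensities, sset.labels, n_predictive=a, n_orthogonal=0,
            seed=1, class_order=class_order, compute_q2=False,
        ).r2y_cum
        for a in (1, 2, 3)
    ]
    assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12


def test_predictive_loadings_recover_injected_bands(preprocessed_cohort, class_order):
    """Top |loading| wavenumbers of the predictive components cover the
    injected effect bands (each class contrast loads on one component)."""
    sset = preprocessed_cohort
    model = fit_opls(
        sset.intensities, sset.labels, n_orthogonal=1, seed=1,
        class_order=class_order, compute_q2=False,
    )
    strength = np.abs(model.loadings).max(axis=1)
    top = sset.wavenumbers[np.argsort(strength)[::-1][:60]]
    for band in (637, 722, 888, 1134, 1203, 1432, 1652):
        assert np.min(np.abs(top - band)) <= 8.0, f"band {band} not in top loadings"


def test_first_component_loadings_recover_bands_in_binary_model(preprocessed_cohort):
    """With one class contrast the first (only) predictive component's top
    loadings pick out the bands separating stone patients from controls."""
    sset = preprocessed_cohort.select_classes([sersdx.HEALTHY, sersdx.STONE])
    model = fit_opls(
        sset.intensities, sset.labels, n_predictive=1, n_orthogonal=1,
        seed=1, compute_q2=False, cv_folds=10,
    )
    top = sset.wavenumbers[np.argsort(np.abs(model.loadings[:, 0]))[::-1][:60]]
    for band in (637, 722, 888, 1203, 1652):  # stone-vs-healthy effect bands
        assert np.min(np.abs(top - band)) <= 8.0, f"band {band} not in top loadings"


def test_score_plot_table_and_hotelling_ellipse(preprocessed_cohort, class_order):
    sset = preprocessed_cohort
    model = fit_opls(
        sset.intensities, sset.labels, n_orthogonal=1, seed=1,
        class_order=class_order, compute_q2=False,
    )
    table, ellipse = scores_for_plot(model)
    assert len(table) == sset.n_samples
    inside = (
        (table.t1 / ellipse["semi_axis_1"]) ** 2
        + (table.t2 / ellipse["semi_axis_2"]) ** 2
    ) <= 1.0
    assert inside.mean() >= 0.93  # nominal 95% coverage
    # separable classes: centroids further apart than typical within-class spread
    cents = {c: table.loc[table.label == c, ["t1", "t2"]].mean().to_numpy() for c in class_order}
    within = np.mean(
        [
            np.linalg.norm(
                table.loc[table.label == c, ["t1", "t2"]].to_numpy() - cents[c], axis=1
            ).mean()
            for c in class_order
        ]
    )
    between = np.mean(
        [
            np.linalg.norm(cents[a] - cents[b])
            for i, a in enumerate(class_order)
            for b in class_order[i + 1 :]
        ]
    )
    assert between > within


def test_fit_errors():
    X, labels = two_class_data(n=12, p=4)
    with pytest.raises(ValueError, match="cv_folds"):
        fit_opls(X, labels, cv_folds=10)
    with pytest.raises(ValueError, match="n_orthogonal"):
        fit_opls(X, labels, n_orthogonal=-1, cv_folds=3)
    with pytest.raises(ValueError, match="2 classes"):
        fit_opls(X, ["a"] * 12, cv_folds=3)
    with pytest.raises(ValueError, match="no variation"):
        fit_opls(np.ones((12, 4)), labels, cv_folds=3)
    model = fit_opls(X, labels, n_orthogonal=0, cv_folds=3)
    with pytest.raises(ValueError, match="variables"):
        predict_opls(model, np.zeros((2, 5)))


def test_automatic_orthogonal_selection_is_bounded(separable_blobs):
    X, labels = separable_blobs
    model = fit_opls(X, labels, n_orthogonal=None, cv_folds=5, seed=0, max_orthogonal=3)
    assert 0 <= model.n_orthogonal <= 3
    assert model.q2_cum <= 1.0
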