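"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

OPLS-DA is PLS regression of a dummy-coded class matrix ``Y`` on the
spectral matrix ``X`` in which, before the predictive components are
extracted, the structured variation in ``X`` that is *uncorrelated* with
``Y`` is removed as "orthogonal" components.  The predictive part then
concentrates the between-class variation in few components, making score
plots directly interpretable.

Implementation outline (NIPALS throughout, mean-centered X and Y):

* orthogonal component: take the converged NIPALS weight ``w`` for the
  current ``(X, Y)``, its loading ``p``; the orthogonal weight is the part
  of ``p`` not aligned with ``w`` (``w_o = p - (w'p) w``, normalized),
  with score ``t_o = X w_o`` and loading ``p_o``; ``X`` is deflated by
  ``t_o p_o'``.
* predictive components: plain multi-response NIPALS PLS on the filtered
  ``X`` with deflation of both blocks.

Fit quality is summarised by R2X(cum) and R2Y(cum) (fractions of the
centered X / Y sum of squares explained by all extracted components) and
Q2(cum), the cross-validated predictive fraction computed from stratified
k-fold cross-validation as ``1 - prod_a PRESS_a / SS_{a-1}`` over the
predictive components (the cumulative-product convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


def dummy_response(labels: Sequence, class_order: Sequence[str]) -> np.ndarray:
    """One-hot class membership matrix; each row sums to one."""
    labels = np.asarray(labels, dtype=object).astype(str)
    class_order = [str(c) for c in class_order]
    unknown = set(labels) - set(class_order)
    if unknown:
        raise ValueError(f"labels not in class order: {sorted(unknown)}")
    return (labels[:, None] == np.array(class_order)[None, :]).astype(float)


@dataclass
class OPLSModel:
    """Fitted OPLS-DA model (weights, loadings, scores, fit statistics)."""

    class_labels: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # predictive weights, (p, A)
    loadings: np.ndarray  # predictive X loadings, (p, A)
    y_loadings: np.ndarray  # (c, A)
    scores: np.ndarray  # predictive scores, (n, A)
    ortho_weights: np.ndarray  # (p, A_o)
    ortho_loadings: np.ndarray  # (p, A_o)
    ortho_scores: np.ndarray  # (n, A_o)
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    n_predictive: int
    n_orthogonal: int
    cv_folds: int
    seed: int
    labels: np.ndarray = field(default=None, repr=False)  # training labels
    sample_ids: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": self.class_labels,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "ortho_weights": self.ortho_weights.tolist(),
            "ortho_loadings": self.ortho_loadings.tolist(),
            "r2x_cum": self.r2x_cum,
            "r2y_cum": self.r2y_cum,
            "q2_cum": self.q2_cum,
            "n_predictive": self.n_predictive,
            "n_orthogonal": self.n_orthogonal,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _nipals_weight(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Converged NIPALS weight/score/y-loading for the current blocks."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not np.any(u):
        u = Y[:, 0].copy()
    t_old = None
    for _ in range(_NIPALS_MAX_ITER):
        w = X.T @ u / (u @ u)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate data: zero NIPALS weight (constant X rows?)")
        w /= norm
        t = X @ w
        q = Y.T @ t / (t @ t)
        u = Y @ q / (q @ q)
        if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
            break
        t_old = t
    return w, t, q


def _y_weight_basis(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(X'Y): the Y-correlated weight subspace."""
    C = X.T @ Y
    u, s, _ = np.linalg.svd(C, full_matrices=False)
    keep = s > max(1e-12 * s[0], 1e-300) if s.size and s[0] > 0 else s > 0
    return u[:, keep]


def _extract_orthogonal(X: np.ndarray, Y: np.ndarray):
    """One orthogonal component; returns (w_o, t_o, p_o, deflated X).

    The candidate direction is the loading of the leading NIPALS
    component, orthogonalized against the whole span of ``X'Y`` so that
    the orthogonal score ``t_o = X w_o`` has exactly zero covariance
    with every dummy-response column.
    """
    w, t, _ = _nipals_weight(X, Y)
    p = X.T @ t / (t @ t)
    basis = _y_weight_basis(X, Y)
    w_o = p - basis @ (basis.T @ p)
    norm = np.linalg.norm(w_o)
    if norm < 1e-12:
        return None
    w_o /= norm
    t_o = X @ w_o
    p_o = X.T @ t_o / (t_o @ t_o)
    return w_o, t_o, p_o, X - np.outer(t_o, p_o)


def _fit_core(
    Xc: np.ndarray, Yc: np.ndarray, n_predictive: int, n_orthogonal: int
) -> dict:
    """Extract orthogonal then predictive components from centered blocks."""
    p = Xc.shape[1]
    W_o, T_o, P_o = [], [], []
    X = Xc.copy()
    for _ in range(n_orthogonal):
        result = _extract_orthogonal(X, Yc)
        if result is None:
            break
        w_o, t_o, p_o, X = result
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    W, T, P, Q = [], [], [], []
    Y = Yc.copy()
    ss_y = [float(np.sum(Yc**2))]  # residual Y SS after 0,1,...,A components
    for _ in range(n_predictive):
        w, t, q = _nipals_weight(X, Y)
        pl = X.T @ t / (t @ t)
        X = X - np.outer(t, pl)
        Y = Y - np.outer(t, q)
        W.append(w)
        T.append(t)
        P.append(pl)
        Q.append(q)
        ss_y.append(float(np.sum(Y**2)))

    stack = lambda vs, width: (
        np.column_stack(vs) if vs else np.empty((width, 0))
    )
    return {
        "weights": stack(W, p),
        "loadings": stack(P, p),
        "y_loadings": stack(Q, Yc.shape[1]),
        "scores": stack(T, Xc.shape[0]),
        "ortho_weights": stack(W_o, p),
        "ortho_loadings": stack(P_o, p),
        "ortho_scores": stack(T_o, Xc.shape[0]),
        "x_residual": X,
        "y_residual": Y,
        "ss_y": ss_y,
    }


def _filter_orthogonal(X: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> np.ndarray:
    for a in range(W_o.shape[1]):
        t_o = X @ W_o[:, a]
        X = X - np.outer(t_o, P_o[:, a])
    return X


def _predict_core(Xc: np.ndarray, core: dict) -> np.ndarray:
    """Predict centered Y from centered X with a fitted component set."""
    X = _filter_orthogonal(Xc.copy(), core["ortho_weights"], core["ortho_loadings"])
    W, P, Q = core["weights"], core["loadings"], core["y_loadings"]
    Yhat = np.zeros((X.shape[0], Q.shape[0]))
    for a in range(W.shape[1]):
        t = X @ W[:, a]
        X = X - np.outer(t, P[:, a])
        Yhat += np.outer(t, Q[:, a])
    return Yhat


def cross_validated_q2(
    X: np.ndarray,
    labels: np.ndarray,
    n_predictive: int,
    n_orthogonal: int,
    cv_folds: int,
    seed: int,
    class_order: Sequence[str],
) -> float:
    """Q2(cum) from stratified k-fold CV, cumulative-product convention.

    ``PRESS_a`` pools the squared out-of-fold prediction error of the
    dummy response using the first ``a`` predictive components (each fold
    refits centering, orthogonal filtering and components on its training
    part); ``SS_{a-1}`` is the residual Y sum of squares of the full-data
    fit after ``a - 1`` components.  With ``cv_folds`` equal to the sample
    count this is leave-one-out.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    Y = dummy_response(labels, class_order)
    if cv_folds >= labels.size:  # leave-one-out; stratification is moot
        splits = LeaveOneOut().split(X)
    else:
        splits = StratifiedKFold(
            n_splits=cv_folds, shuffle=True, random_state=seed
        ).split(X, labels)
    press = np.zeros(n_predictive)
    for train, test in splits:
        x_mean = X[train].mean(axis=0)
        y_mean = Y[train].mean(axis=0)
        core = _fit_core(X[train] - x_mean, Y[train] - y_mean, n_predictive, n_orthogonal)
        Xt = _filter_orthogonal(
            X[test] - x_mean, core["ortho_weights"], core["ortho_loadings"]
        )
        W, P, Q = core["weights"], core["loadings"], core["y_loadings"]
        Yhat = np.zeros((len(test), Y.shape[1]))
        for a in range(W.shape[1]):
            t = Xt @ W[:, a]
            Xt = Xt - np.outer(t, P[:, a])
            Yhat += np.outer(t, Q[:, a])
            press[a] += float(np.sum((Y[test] - y_mean - Yhat) ** 2))
    full = _fit_core(X - X.mean(axis=0), Y - Y.mean(axis=0), n_predictive, n_orthogonal)
    ss = np.asarray(full["ss_y"][: n_predictive])  # SS_0 ... SS_{A-1}
    actual = full["weights"].shape[1]
    ratio = press[:actual] / ss[:actual]
    return float(1.0 - np.prod(ratio))


def fit_opls(
    X: np.ndarray,
    labels: Sequence,
    n_predictive: int | None = None,
    n_orthogonal: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    class_order: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
    compute_q2: bool = True,
    max_orthogonal: int = 5,
    q2_improvement: float = 0.01,
) -> OPLSModel:
    """Fit an OPLS-DA model on preprocessed spectra.

    Parameters
    ----------
    X
        Sample-by-variable matrix (mean-centered internally; no variance
        scaling by default, appropriate for vector-normalized spectra).
    labels
        Class label per row; at least 2 classes with >= 3 samples each.
    n_predictive
        Predictive component count; default ``n_classes - 1`` for more
        than two classes, 1 for binary problems.
    n_orthogonal
        Orthogonal component count; if ``None``, components are added
        while cross-validated Q2 improves by more than ``q2_improvement``
        (capped at ``max_orthogonal``).
    cv_folds, seed
        Stratified CV used for Q2; must not exceed the smallest class.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("X must be 2-D with one row per label")
    order = [str(c) for c in class_order] if class_order is not None else sorted(set(labels))
    counts = {c: int(np.sum(labels == c)) for c in order}
    if len(order) < 2:
        raise ValueError("need at least 2 classes")
    if any(n < 3 for n in counts.values()):
        raise ValueError(f"every class needs >= 3 samples, got {counts}")
    if compute_q2 and cv_folds > min(counts.values()) and cv_folds < labels.size:
        raise ValueError(
            f"cv_folds ({cv_folds}) exceeds the smallest class ({min(counts.values())})"
        )
    if n_orthogonal is not None and n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate data: X has no variation")

    if n_predictive is None:
        n_predictive = max(1, len(order) - 1)
    Y = dummy_response(labels, order)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean

    if n_orthogonal is None:
        if not compute_q2:
            raise ValueError("automatic n_orthogonal selection requires compute_q2")
        n_orthogonal = 0
        best = cross_validated_q2(X, labels, n_predictive, 0, cv_folds, seed, order)
        for a_o in range(1, max_orthogonal + 1):
            q2 = cross_validated_q2(X, labels, n_predictive, a_o, cv_folds, seed, order)
            if q2 > best + q2_improvement:
                best, n_orthogonal = q2, a_o
            else:
                break
        logger.info("selected %d orthogonal component(s), Q2=%.3f", n_orthogonal, best)

    core = _fit_core(Xc, Yc, n_predictive, n_orthogonal)
    ss_x = float(np.sum(Xc**2))
    r2x = 1.0 - float(np.sum(core["x_residual"] ** 2)) / ss_x if ss_x else 0.0
    r2y = 1.0 - core["ss_y"][-1] / core["ss_y"][0]
    q2 = (
        cross_validated_q2(X, labels, n_predictive, n_orthogonal, cv_folds, seed, order)
        if compute_q2
        else float("nan")
    )
    return OPLSModel(
        class_labels=order,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=core["weights"],
        loadings=core["loadings"],
        y_loadings=core["y_loadings"],
        scores=core["scores"],
        ortho_weights=core["ortho_weights"],
        ortho_loadings=core["ortho_loadings"],
        ortho_scores=core["ortho_scores"],
        r2x_cum=r2x,
        r2y_cum=r2y,
        q2_cum=q2,
        n_predictive=core["weights"].shape[1],
        n_orthogonal=core["ortho_weights"].shape[1],
        cv_folds=cv_folds,
        seed=seed,
        labels=labels,
        sample_ids=None if sample_ids is None else np.asarray(sample_ids, dtype=object),
    )


def predict_opls(model: OPLSModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous class scores and hard labels for new spectra.

    Scores are the reconstructed dummy-response estimates (per sample,
    roughly summing to 1 across classes); the label is the class of the
    maximum score, ties broken by class order with a logged warning.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} variables, model was trained on "
            f"{model.x_mean.size}"
        )
    core = {
        "ortho_weights": model.ortho_weights,
        "ortho_loadings": model.ortho_loadings,
        "weights": model.weights,
        "loadings": model.loadings,
        "y_loadings": model.y_loadings,
    }
    scores = _predict_core(X_new - model.x_mean, core) + model.y_mean
    is_max = scores == scores.max(axis=1, keepdims=True)
    if np.any(is_max.sum(axis=1) > 1):
        logger.warning("tied class scores; breaking ties by class order")
    labels = np.array([model.class_labels[i] for i in np.argmax(scores, axis=1)], dtype=object)
    return scores, labels


def scores_for_plot(model: OPLSModel, alpha: float = 0.95) -> tuple[pd.DataFrame, dict]:
    """Score-plot table (component 1 vs 2) plus the Hotelling T2 ellipse.

    The second axis is the second predictive score when available,
    otherwise the first orthogonal score.  The ellipse holds the nominal
    ``alpha`` confidence region assuming bivariate normal scores:
    semi-axes ``sqrt(var(t_i) * T2_crit)`` with
    ``T2_crit = 2 (n-1)/(n-2) F_alpha(2, n-2)``.
    """
    t1 = model.scores[:, 0] if model.n_predictive >= 1 else None
    if t1 is None:
        raise ValueError("model has no predictive component")
    if model.n_predictive >= 2:
        t2, axis2 = model.scores[:, 1], "predictive 2"
    elif model.n_orthogonal >= 1:
        t2, axis2 = model.ortho_scores[:, 0], "orthogonal 1"
    else:
        raise ValueError("need at least 2 total components for a score plot")
    n = t1.size
    table = pd.DataFrame(
        {
            "sample_id": (
                model.sample_ids
                if model.sample_ids is not None
                else [f"sample_{i}" for i in range(n)]
            ),
            "t1": t1,
            "t2": t2,
            "label": model.labels,
        }
    )
    t2_crit = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(alpha, 2, n - 2)
    ellipse = {
        "axis2": axis2,
        "t2_crit": float(t2_crit),
        "semi_axis_1": float(np.sqrt(t1.var(ddof=1) * t2_crit)),
        "semi_axis_2": float(np.sqrt(t2.var(ddof=1) * t2_crit)),
    }
    return table, ellipse
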