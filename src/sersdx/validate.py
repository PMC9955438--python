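"""Model validation and diagnostic performance metrics.

Covers four tools used to judge the spectral classifiers:

* confusion matrices with per-class sensitivity/specificity and overall
  accuracy — including the multiclass "specificity" convention used in
  some clinical-spectroscopy reports (fraction of the *out-of-class*
  samples that are assigned to their own correct class), alongside the
  textbook one-vs-rest TN/(TN+FP);
* stratified k-fold cross-validation with pooled out-of-fold predictions;
* a label-permutation test: the model is refitted many times with the
  dummy response row-permuted, R2Y/Q2 are regressed against the mean
  absolute correlation between the permuted and original responses, and
  the regression intercepts at correlation 0 diagnose overfitting
  (well-constructed when the R2 intercept < 0.4 and the Q2
  intercept < 0.05);
* one-vs-rest ROC curves and rank-statistic AUC per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import opls as _opls
from . import pcalda as _pcalda

logger = logging.getLogger(__name__)

R2_INTERCEPT_LIMIT = 0.4
Q2_INTERCEPT_LIMIT = 0.05


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.65 -> 2.7), as printed in report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true class, columns = predicted) + metrics.

    ``sensitivity_pct``/``specificity_pct``/``accuracy_pct`` are percent
    values rounded half-up to one decimal; ``specificity_pct`` uses the
    cross-class convention described in the module docstring and
    ``specificity_ovr_pct`` the standard one-vs-rest TN/(TN+FP).
    """

    class_order: list[str]
    matrix: np.ndarray
    auc: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        c = len(self.class_order)
        if self.matrix.shape != (c, c):
            raise ValueError("matrix must be square in the class order")
        if np.any(self.matrix < 0):
            raise ValueError("matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def class_sizes(self) -> dict[str, int]:
        return dict(zip(self.class_order, self.matrix.sum(axis=1).tolist()))

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix)) / self.total

    def sensitivity(self, cls: str) -> float:
        i = self.class_order.index(cls)
        return self.matrix[i, i] / self.matrix[i].sum()

    def specificity(self, cls: str) -> float:
        """Out-of-class samples assigned to their own correct class."""
        i = self.class_order.index(cls)
        others = [k for k in range(len(self.class_order)) if k != i]
        correct = sum(self.matrix[k, k] for k in others)
        return correct / self.matrix[others].sum()

    def specificity_ovr(self, cls: str) -> float:
        """Standard one-vs-rest specificity TN / (TN + FP)."""
        i = self.class_order.index(cls)
        others = [k for k in range(len(self.class_order)) if k != i]
        negatives = self.matrix[others].sum()
        false_pos = self.matrix[others, i].sum()
        return (negatives - false_pos) / negatives

    @property
    def accuracy_pct(self) -> float:
        return round_half_up(100.0 * self.accuracy)

    @property
    def sensitivity_pct(self) -> dict[str, float]:
        return {c: round_half_up(100.0 * self.sensitivity(c)) for c in self.class_order}

    @property
    def specificity_pct(self) -> dict[str, float]:
        return {c: round_half_up(100.0 * self.specificity(c)) for c in self.class_order}

    @property
    def specificity_ovr_pct(self) -> dict[str, float]:
        return {
            c: round_half_up(100.0 * self.specificity_ovr(c)) for c in self.class_order
        }

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, index=self.class_order, columns=self.class_order)
        frame.index.name = "true"
        return frame

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.class_order:
            rows.append(
                {
                    "class": c,
                    "n": self.class_sizes[c],
                    "sensitivity_pct": self.sensitivity_pct[c],
                    "specificity_pct": self.specificity_pct[c],
                    "specificity_ovr_pct": self.specificity_ovr_pct[c],
                    "auc": None if self.auc is None else self.auc.get(c),
                }
            )
        return pd.DataFrame(rows)


def confusion_metrics(
    y_true: Sequence, y_pred: Sequence, class_order: Sequence[str]
) -> ClassificationReport:
    """Build a :class:`ClassificationReport` from label sequences."""
    y_true = np.asarray(y_true, dtype=object).astype(str)
    y_pred = np.asarray(y_pred, dtype=object).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    order = [str(c) for c in class_order]
    unknown = (set(y_true) | set(y_pred)) - set(order)
    if unknown:
        raise ValueError(f"labels not in class order: {sorted(unknown)}")
    index = {c: i for i, c in enumerate(order)}
    matrix = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        matrix[index[t], index[p]] += 1
    return ClassificationReport(class_order=order, matrix=matrix)


def reconstruct_binary_counts(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> tuple[int, int, float]:
    """Invert printed binary sensitivity/specificity to integer counts.

    Returns ``(true_positives, true_negatives, accuracy_pct)`` where the
    counts are the nearest integers consistent with the printed percent
    values and the accuracy is recomputed from them (half-up, 1 decimal).
    """
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    acc = round_half_up(100.0 * (tp + tn) / (n_pos + n_neg))
    return tp, tn, acc


# ---------------------------------------------------------------------------
# model specs and cross-validation
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative classifier choice for CV and permutation testing.

    ``kind`` is ``"opls"`` or ``"pcalda"``; ``params`` are forwarded to
    the corresponding fit function.
    """

    kind: str = "opls"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("opls", "pcalda"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    def fit_predict(
        self,
        X_train: np.ndarray,
        labels_train: np.ndarray,
        X_test: np.ndarray,
        class_order: Sequence[str],
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fit on the training block, return (scores, labels) on the test block."""
        if self.kind == "opls":
            model = _opls.fit_opls(
                X_train,
                labels_train,
                class_order=class_order,
                compute_q2=False,
                **{**{"n_orthogonal": 1}, **self.params},
            )
            return _opls.predict_opls(model, X_test)
        model = _pcalda.fit_pcalda(
            X_train, labels_train, class_order=class_order, **self.params
        )
        return _pcalda.predict_pcalda(model, X_test)


@dataclass
class CVResult:
    predictions: np.ndarray  # pooled out-of-fold labels, sample order
    scores: np.ndarray  # pooled out-of-fold continuous class scores
    report: ClassificationReport
    folds: int
    seed: int


def kfold_cv(
    X: np.ndarray,
    labels: Sequence,
    model_spec: ModelSpec,
    folds: int = 10,
    seed: int = 0,
    class_order: Sequence[str] | None = None,
) -> CVResult:
    """Stratified k-fold CV; every sample is predicted exactly once.

    The report (confusion matrix, metrics, per-class one-vs-rest AUC) is
    computed on the pooled out-of-fold predictions.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    order = [str(c) for c in class_order] if class_order is not None else sorted(set(labels))
    counts = {c: int(np.sum(labels == c)) for c in order}
    if folds > min(counts.values()):
        raise ValueError(
            f"folds ({folds}) exceeds the smallest class size ({min(counts.values())})"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(labels.size, dtype=object)
    scores = np.full((labels.size, len(order)), np.nan)
    for train, test in splitter.split(X, labels):
        s, p = model_spec.fit_predict(X[train], labels[train], X[test], order)
        pred[test] = p
        scores[test] = s
    report = confusion_metrics(labels, pred, order)
    report.auc = one_vs_rest_auc(scores, labels, order)
    return CVResult(predictions=pred, scores=scores, report=report, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Outcome of a label-permutation validation of an OPLS-DA model."""

    correlations: np.ndarray  # abscissa per permutation
    r2y_values: np.ndarray
    q2_values: np.ndarray
    original_r2y: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float

    @property
    def n_permutations(self) -> int:
        return self.correlations.size

    @property
    def well_constructed(self) -> bool:
        return permutation_verdict(self.r2_intercept, self.q2_intercept)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "correlation": np.append(self.correlations, 1.0),
                "r2y": np.append(self.r2y_values, self.original_r2y),
                "q2": np.append(self.q2_values, self.original_q2),
                "permuted": [True] * self.n_permutations + [False],
            }
        )
        return frame


def permutation_verdict(r2_intercept: float, q2_intercept: float) -> bool:
    """Overfitting verdict: R2 intercept < 0.4 and Q2 intercept < 0.05."""
    return (r2_intercept < R2_INTERCEPT_LIMIT) and (q2_intercept < Q2_INTERCEPT_LIMIT)


def _mean_abs_column_correlation(Y_perm: np.ndarray, Y_orig: np.ndarray) -> float:
    corrs = []
    for j in range(Y_orig.shape[1]):
        a, b = Y_perm[:, j], Y_orig[:, j]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            corrs.append(1.0 if np.array_equal(a, b) else 0.0)
            continue
        corrs.append(abs(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(corrs))


def permutation_test(
    X: np.ndarray,
    labels: Sequence,
    model_spec: ModelSpec | None = None,
    n_perm: int = 100,
    seed: int = 0,
    cv_folds: int = 10,
    class_order: Sequence[str] | None = None,
) -> PermutationResult:
    """Refit under row-permuted responses and regress R2Y/Q2 on correlation.

    For each of ``n_perm`` permutations the class labels are shuffled,
    the OPLS model refitted, and the triple (mean absolute column-wise
    correlation between the permuted and original dummy matrices, R2Y,
    Q2) recorded.  Straight lines through these points and the original
    model (at correlation 1) give the intercepts at correlation 0.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    spec = model_spec or ModelSpec("opls")
    if spec.kind != "opls":
        raise ValueError("permutation test requires an OPLS model spec (R2/Q2)")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    order = [str(c) for c in class_order] if class_order is not None else sorted(set(labels))
    Y = _opls.dummy_response(labels, order)

    params = {**{"n_orthogonal": 1}, **spec.params}

    def fit(lab: np.ndarray) -> _opls.OPLSModel:
        return _opls.fit_opls(
            X, lab, class_order=order, cv_folds=cv_folds, seed=seed, **params
        )

    original = fit(labels)
    rng = np.random.default_rng(seed)
    corrs = np.empty(n_perm)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels.size)
        model = fit(labels[perm])
        corrs[i] = _mean_abs_column_correlation(Y[perm], Y)
        r2s[i] = model.r2y_cum
        q2s[i] = model.q2_cum

    xs = np.append(corrs, 1.0)
    r2_line = np.polyfit(xs, np.append(r2s, original.r2y_cum), 1)
    q2_line = np.polyfit(xs, np.append(q2s, original.q2_cum), 1)
    return PermutationResult(
        correlations=corrs,
        r2y_values=r2s,
        q2_values=q2s,
        original_r2y=original.r2y_cum,
        original_q2=original.q2_cum,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], membership: Sequence[bool]) -> tuple[float, pd.DataFrame]:
    """Rank-statistic AUC (ties count one half) plus the ROC point list.

    ``membership`` flags the positive class; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    member = np.asarray(membership, dtype=bool)
    if member.all() or (~member).all():
        raise ValueError("ROC needs both classes present")
    # Mann-Whitney rank form; ties contribute 1/2
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    n_pos = int(member.sum())
    n_neg = member.size - n_pos
    auc = (ranks[member].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = _sk_roc_curve(member.astype(int), scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc), points


def one_vs_rest_auc(
    scores: np.ndarray, labels: Sequence, class_order: Sequence[str]
) -> dict[str, float]:
    """Per-class AUC using that class's continuous model score column."""
    labels = np.asarray(labels, dtype=object).astype(str)
    out = {}
    for j, c in enumerate(class_order):
        auc, _ = roc_auc(scores[:, j], labels == c)
        out[c] = auc
    return out


def roc_tables(
    scores: np.ndarray, labels: Sequence, class_order: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """One ROC point table per class (one-vs-rest)."""
    labels = np.asarray(labels, dtype=object).astype(str)
    return {
        c: roc_auc(scores[:, j], labels == c)[1] for j, c in enumerate(class_order)
    }
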