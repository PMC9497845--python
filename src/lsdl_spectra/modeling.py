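"""Nine-classifier benchmark under stratified 10-fold cross-validation.

Fixed, documented hyperparameters replace interactive tuning: KNN uses K=1
with Euclidean distance; the SVM family covers linear, quadratic, cubic and
"fine Gaussian" (RBF with kernel scale sqrt(P)/4, i.e. gamma = 8/P) kernels
at C=1; features are z-scored with training-fold statistics inside every
fold. Metrics are computed on the pooled out-of-fold predictions and
reported in percent (rounded half-away-from-zero for display, unrounded
kept alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balancing import BalanceSpec, smote_balance
from .errors import DegenerateInputError, ValidationError
from .features import FeatureMatrix

MODEL_NAMES = ("DT", "LDA", "QDA", "KNN", "LSVM", "QSVM", "CSVM", "FGSVM", "LR")

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "CVConfig",
    "MetricsRow",
    "MetricsTable",
    "build_estimator",
    "evaluate_cv",
    "run_grid",
    "pca_projection",
]


@dataclass(frozen=True)
class ModelSpec:
    """Named classifier with its fixed hyperparameter set."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValidationError(f"unknown model {self.name!r}; expected {MODEL_NAMES}")


@dataclass(frozen=True)
class CVConfig:
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")


@dataclass
class MetricsRow:
    """Acc/Sens/Spec/AUC in percent for one model, or n/a with a reason."""

    model: str
    acc: float | None
    sens: float | None
    spec: float | None
    auc: float | None
    na_reason: str | None = None
    confusion: tuple[int, int, int, int] | None = None  # tp, fn, tn, fp

    @property
    def is_na(self) -> bool:
        return self.acc is None

    def rounded(self) -> dict[str, object]:
        def r(v):
            if v is None:
                return "n/a"
            return int(math.floor(v + 0.5))  # half away from zero; metrics >= 0

        return {"model": self.model, "acc": r(self.acc), "sens": r(self.sens),
                "spec": r(self.spec), "auc": r(self.auc)}


@dataclass
class MetricsTable:
    name: str
    rows: list[MetricsRow]
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self, rounded: bool = True):
        import pandas as pd

        if rounded:
            return pd.DataFrame([r.rounded() for r in self.rows])
        return pd.DataFrame(
            [
                {"model": r.model, "acc": r.acc, "sens": r.sens, "spec": r.spec,
                 "auc": r.auc, "na_reason": r.na_reason}
                for r in self.rows
            ]
        )

    def to_markdown(self) -> str:
        lines = [
            f"### {self.name}",
            "",
            "| Model | Acc (%) | Sens (%) | Spec (%) | AUC (%) |",
            "|-------|---------|----------|----------|---------|",
        ]
        for r in self.rows:
            d = r.rounded()
            lines.append(
                f"| {d['model']} | {d['acc']} | {d['sens']} | {d['spec']} | {d['auc']} |"
            )
        return "\n".join(lines)

    def mean_accuracy(self) -> float:
        vals = [r.acc for r in self.rows if not r.is_na]
        if not vals:
            raise DegenerateInputError(f"{self.name}: all rows n/a")
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _Knn1WithMargin(KNeighborsClassifier):
    """K=1 nearest neighbor with a continuous score for ROC curves.

    The score is the negative distance margin: distance to the nearest
    negative-class training point minus distance to the nearest
    positive-class point (larger = more positive).
    """

    def __init__(self):
        super().__init__(n_neighbors=1, metric="euclidean")

    def fit(self, X, y):
        super().fit(X, y)
        classes = np.unique(y)
        self._nn_by_class = {
            c: NearestNeighbors(n_neighbors=1).fit(X[np.asarray(y) == c])
            for c in classes
        }
        return self

    def decision_function(self, X):
        # oriented toward classes_[1], matching the sklearn convention
        pos, neg = self.classes_[1], self.classes_[0]
        d_pos = self._nn_by_class[pos].kneighbors(X)[0][:, 0]
        d_neg = self._nn_by_class[neg].kneighbors(X)[0][:, 0]
        return d_neg - d_pos


class _StrictQDA(QuadraticDiscriminantAnalysis):
    """QDA that refuses singular class covariance instead of limping on,
    matching the n/a reporting convention for degenerate inputs."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        p = X.shape[1]
        for c in np.unique(y):
            rows = X[y == c]
            if rows.shape[0] <= p:
                raise DegenerateInputError(
                    f"QDA: class {c!r} has {rows.shape[0]} samples for {p} features"
                )
            cov = np.cov(rows, rowvar=False)
            if np.linalg.matrix_rank(cov, tol=1e-10) < p:
                raise DegenerateInputError(
                    f"QDA: singular covariance for class {c!r}"
                )
        return super().fit(X, y)


def build_estimator(spec: ModelSpec, n_features: int, seed: int = 0):
    """Instantiate the named classifier with its fixed hyperparameters."""
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if name == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if name == "QDA":
        return _StrictQDA()
    if name == "KNN":
        return _Knn1WithMargin()
    if name == "LSVM":
        return SVC(kernel="linear", C=hp.pop("C", 1.0), random_state=seed, **hp)
    if name == "QSVM":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale",
                   C=hp.pop("C", 1.0), random_state=seed, **hp)
    if name == "CSVM":
        return SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale",
                   C=hp.pop("C", 1.0), random_state=seed, **hp)
    if name == "FGSVM":
        # "fine" kernel scale sqrt(P)/4 => gamma = 1/scale^2 = 16/P ... with
        # the 1/(2 sigma^2) parameterization this is 8/P
        return SVC(kernel="rbf", gamma=8.0 / n_features, C=hp.pop("C", 1.0),
                   random_state=seed, **hp)
    if name == "LR":
        return LogisticRegression(max_iter=2000, **hp)
    raise ValidationError(f"unknown model {name!r}")


def _positive_label(labels: Sequence[str], pos_label: str | None) -> tuple[str, str]:
    uniq = sorted(set(str(v) for v in labels))
    if len(uniq) != 2:
        raise ValidationError(f"binary labels required, got {uniq}")
    if pos_label is None:
        for cand in ("cancer", "high_grade"):
            if cand in uniq:
                pos_label = cand
                break
        else:
            pos_label = uniq[0]
    if pos_label not in uniq:
        raise ValidationError(f"positive label {pos_label!r} not present in {uniq}")
    neg = next(v for v in uniq if v != pos_label)
    return pos_label, neg


def _scores(est, X, pos_label) -> np.ndarray:
    if hasattr(est, "decision_function"):
        s = est.decision_function(X)
        # sklearn orients decision_function toward classes_[1]
        if hasattr(est, "classes_") and str(est.classes_[1]) != str(pos_label):
            s = -s
        return s
    proba = est.predict_proba(X)
    col = list(est.classes_).index(pos_label)
    return proba[:, col]


def evaluate_cv(
    features: FeatureMatrix,
    model: ModelSpec | str,
    cv: CVConfig | None = None,
    pos_label: str | None = None,
    balance_in_folds: BalanceSpec | None = None,
) -> MetricsRow:
    """Pooled out-of-fold Acc/Sens/Spec/AUC for one model.

    With ``balance_in_folds`` set, SMOTE runs inside each training fold
    (the leakage-safe placement); otherwise the features are used as given.
    Fitting failures on any fold produce an n/a row, not an exception.
    """
    cv = cv or CVConfig()
    spec = ModelSpec(model) if isinstance(model, str) else model
    X = features.X
    y = features.labels.astype(str)
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains missing values")
    pos, neg = _positive_label(y, pos_label)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv.folds:
        raise ValidationError(
            f"every class needs >= {cv.folds} members for {cv.folds}-fold CV"
        )
    splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)

    pred = np.empty(len(y), dtype=object)
    score = np.empty(len(y), dtype=float)
    try:
        for tr, te in splitter.split(X, y):
            X_tr, y_tr = X[tr], y[tr]
            if balance_in_folds is not None:
                fm_tr = FeatureMatrix(
                    X=X_tr, feature_names=features.feature_names, labels=y_tr
                )
                fm_tr = smote_balance(fm_tr, balance_in_folds)
                X_tr, y_tr = fm_tr.X, fm_tr.labels.astype(str)
            scaler = StandardScaler().fit(X_tr)
            est = build_estimator(spec, X.shape[1], seed=cv.seed)
            est.fit(scaler.transform(X_tr), y_tr)
            Xz = scaler.transform(X[te])
            pred[te] = est.predict(Xz)
            score[te] = _scores(est, Xz, pos)
    except DegenerateInputError as exc:
        return MetricsRow(spec.name, None, None, None, None, na_reason=str(exc))
    except (np.linalg.LinAlgError, ValueError) as exc:
        return MetricsRow(spec.name, None, None, None, None,
                          na_reason=f"{type(exc).__name__}: {exc}")

    pred = pred.astype(str)
    tp = int(np.sum((pred == pos) & (y == pos)))
    fn = int(np.sum((pred != pos) & (y == pos)))
    tn = int(np.sum((pred == neg) & (y == neg)))
    fp = int(np.sum((pred != neg) & (y == neg)))
    acc = 100.0 * (tp + tn) / len(y)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spc = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    auc = 100.0 * roc_auc_score((y == pos).astype(int), score)
    return MetricsRow(spec.name, acc, sens, spc, auc, confusion=(tp, fn, tn, fp))


def run_grid(
    datasets: Mapping[str, Mapping[str, FeatureMatrix]],
    models: Sequence[str] = MODEL_NAMES,
    cv: CVConfig | None = None,
    pos_label: str | None = None,
    balance_in_folds: BalanceSpec | None = None,
) -> dict[tuple[str, str], MetricsTable]:
    """One metrics table per (dataset, representation) pair.

    ``datasets`` maps dataset name -> {representation name -> FeatureMatrix},
    e.g. {"dataset1": {"raw": fm_raw, "lsdl": fm_lsdl}}.
    """
    cv = cv or CVConfig()
    tables: dict[tuple[str, str], MetricsTable] = {}
    for ds_name, reps in datasets.items():
        for rep_name, fm in reps.items():
            rows = [
                evaluate_cv(fm, m, cv, pos_label=pos_label,
                            balance_in_folds=balance_in_folds)
                for m in models
            ]
            tables[(ds_name, rep_name)] = MetricsTable(
                name=f"{ds_name}/{rep_name}",
                rows=rows,
                metadata={
                    "folds": cv.folds,
                    "seed": cv.seed,
                    "n_samples": len(fm),
                    "representation": rep_name,
                    "pooled_out_of_fold": True,
                    "svm_C": 1.0,
                    "standardized_per_fold": True,
                    "balance_in_folds": balance_in_folds is not None,
                },
            )
    return tables


def pca_projection(
    features: FeatureMatrix, variance_target: float = 0.98
) -> tuple[np.ndarray, np.ndarray, int]:
    """Scores of the first two principal components of the z-scored features.

    Returns ``(scores_2d, explained_variance_ratio, n_components_kept)``
    where the kept count is the smallest reaching ``variance_target``.
    """
    X = features.X
    if X.shape[0] < 3:
        raise ValidationError("PCA projection needs at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise DegenerateInputError("constant feature matrix")
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA()
    scores = pca.fit_transform(Z)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    k = min(k, len(evr))
    if scores.shape[1] == 1:
        scores = np.hstack([scores, np.zeros_like(scores)])
    return scores[:, :2], evr, k
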