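"""Classification protocols and per-feature diagnostic machinery.

Classifiers: linear SVM (maximum-margin, penalty C), k-nearest neighbours
(Euclidean on standardized features, majority vote) and Gaussian Naive
Bayes. Features are z-scored with training-fold statistics inside every
fit. Validation protocols: leave-one-out cross-validation (optionally with
nested per-fold ANOVA feature selection) and a stratified seeded 50/50
split. The positive class is "case" (macular edema) everywhere.

Per-feature diagnostics mirror a standard biomarker workup: ROC curve from
midpoint thresholds evaluated in both orientations ("positive if <= t" and
"positive if > t"), trapezoidal AUC, and the Youden-index cut-off
J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .image import ParameterError
from .selection import NEGATIVE_LABEL, POSITIVE_LABEL, rank_features, select_top_k

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm_linear", "knn", "naive_bayes")


@dataclass
class ClassifyConfig:
    svm_c: float = 1.0
    knn_k: int = 3
    nb_var_floor: float = 1e-9


@dataclass
class ClassifierReport:
    scheme: str
    classifier: str
    predictions: list[str]
    tp: int
    fp: int
    tn: int
    fn: int
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "classifier": self.classifier,
            "n": self.n,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "seed": self.seed,
            "predictions": self.predictions,
        }


def _make_classifier(kind: str, cfg: ClassifyConfig):
    if kind == "svm_linear":
        return SVC(kernel="linear", C=cfg.svm_c)
    if kind == "knn":
        # sklearn breaks vote ties by class order, i.e. alphabetically:
        # "case" < "control", so ties resolve to the positive class
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    if kind == "naive_bayes":
        return GaussianNB(var_smoothing=0.0, priors=None)
    raise ParameterError(f"unknown classifier {kind!r}; choose from {CLASSIFIERS}")


def fit_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    kind: str = "svm_linear",
    cfg: ClassifyConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and predict held-out rows.

    Returns predicted labels and a decision score oriented so that larger
    values favour the positive class ("case").
    """
    cfg = cfg or ClassifyConfig()
    train_y = np.asarray(train_y)
    if len(set(train_y)) < 2:
        raise ParameterError("training set must contain both classes")
    scaler = StandardScaler()
    # guard constant columns: zero variance would divide by zero
    scaler.fit(train_x)
    scaler.scale_[scaler.scale_ == 0] = 1.0
    xtr = scaler.transform(train_x)
    xte = scaler.transform(test_x)
    model = _make_classifier(kind, cfg)
    if kind == "naive_bayes":
        model.set_params(var_smoothing=0.0)
    model.fit(xtr, train_y)
    if kind == "naive_bayes" and hasattr(model, "var_"):
        model.var_ = np.maximum(model.var_, cfg.nb_var_floor)
    preds = model.predict(xte)
    pos_idx = list(model.classes_).index(POSITIVE_LABEL) if POSITIVE_LABEL in model.classes_ else 1
    if kind == "svm_linear":
        df = model.decision_function(xte)
        scores = df if model.classes_[1] == POSITIVE_LABEL else -df
    else:
        scores = model.predict_proba(xte)[:, pos_idx]
    return preds, np.asarray(scores, dtype=np.float64)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    tp = int(np.sum((y_true == POSITIVE_LABEL) & (y_pred == POSITIVE_LABEL)))
    fn = int(np.sum((y_true == POSITIVE_LABEL) & (y_pred != POSITIVE_LABEL)))
    tn = int(np.sum((y_true == NEGATIVE_LABEL) & (y_pred == NEGATIVE_LABEL)))
    fp = int(np.sum((y_true == NEGATIVE_LABEL) & (y_pred != NEGATIVE_LABEL)))
    return tp, fp, tn, fn


def loocv(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    kind: str = "svm_linear",
    cfg: ClassifyConfig | None = None,
    nested_k: int | None = None,
) -> ClassifierReport:
    """Leave-one-out cross-validation.

    Each sample is predicted by a model trained on the other n-1;
    standardization (and, when ``nested_k`` is given, ANOVA feature
    selection) is refit inside every fold.
    """
    labels = np.asarray(labels)
    n = len(table)
    if n < 3:
        raise ParameterError("leave-one-out needs at least 3 samples")
    if len(set(labels)) < 2:
        raise ParameterError("both classes must be present")
    preds = []
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        train_tab = table.iloc[train_idx]
        train_y = labels[train_idx]
        if len(set(train_y)) < 2:
            # n=3 with a 2/1 split leaves one-class folds; the only
            # defensible prediction is the sole training class
            preds.append(str(train_y[0]))
            continue
        if nested_k is not None:
            ranked = rank_features(train_tab, train_y)
            cols = select_top_k(ranked, min(nested_k, len(ranked.names)))
        else:
            cols = list(table.columns)
        p, _ = fit_predict(
            train_tab[cols].to_numpy(),
            train_y,
            table.iloc[[i]][cols].to_numpy(),
            kind,
            cfg,
        )
        preds.append(str(p[0]))
    tp, fp, tn, fn = _confusion(labels, np.array(preds))
    return ClassifierReport("loocv", kind, preds, tp, fp, tn, fn)


def split_eval(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    kind: str = "svm_linear",
    fraction: float = 0.5,
    seed: int = 0,
    cfg: ClassifyConfig | None = None,
) -> ClassifierReport:
    """Stratified seeded train/test split; train size rounds up per class."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ParameterError(f"class {cls!r} needs >= 2 samples to stratify")
        perm = rng.permutation(idx)
        n_train = int(np.ceil(fraction * len(idx)))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    preds, _ = fit_predict(
        table.iloc[train_idx].to_numpy(),
        labels[train_idx],
        table.iloc[test_idx].to_numpy(),
        kind,
        cfg,
    )
    tp, fp, tn, fn = _confusion(labels[test_idx], preds)
    return ClassifierReport("split50", kind, [str(p) for p in preds], tp, fp, tn, fn, seed=seed)


# ---------------------------------------------------------------------------
# ROC / Youden diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    """ROC points (threshold, sensitivity, specificity) for one orientation.

    ``le_positive`` calls a sample positive when its score is <= threshold;
    ``gt_positive`` when the score is > threshold. The orientation with
    AUC >= 0.5 is reported.
    """

    points: list[tuple[float, float, float]]
    auc: float
    orientation: str
    curves: dict[str, list[tuple[float, float, float]]] = field(
        repr=False, default_factory=dict
    )
    thresholds: np.ndarray = field(repr=False, default=None)


def _curve(scores: np.ndarray, labels: np.ndarray, orientation: str):
    """Threshold sweep: midpoints between consecutive unique scores ± inf."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = labels == POSITIVE_LABEL
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    pts = []
    for t in thresholds:
        called = scores <= t if orientation == "le_positive" else scores > t
        sens = np.sum(called & pos) / n_pos
        spec = np.sum(~called & ~pos) / n_neg
        pts.append((float(t), float(sens), float(spec)))
    # trapezoid over (FPR, TPR) in sweep order; FPR is monotone along the
    # threshold sweep, so the signed area just needs its sign dropped
    fpr = np.array([1 - s for _, _, s in pts])
    tpr = np.array([s for _, s, _ in pts])
    auc = float(abs(np.trapezoid(tpr, fpr)))
    return pts, auc, thresholds


def roc_points(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and trapezoidal AUC for one score column.

    Both orientations are evaluated and the one with AUC >= 0.5 is kept,
    matching the per-feature <= / > cut-off notation of diagnostic tables.
    Identical scores for all samples degrade to AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ParameterError("scores must be finite")
    pos = labels == POSITIVE_LABEL
    if pos.all() or (~pos).all():
        raise ParameterError("both classes must be present")
    if np.unique(scores).size == 1:
        logger.warning("roc_points: all scores identical; degenerate ROC (AUC 0.5)")
    pts_gt, auc_gt, thr = _curve(scores, labels, "gt_positive")
    pts_le, auc_le, _ = _curve(scores, labels, "le_positive")
    curves = {"gt_positive": pts_gt, "le_positive": pts_le}
    if auc_gt >= auc_le:
        return ROCResult(pts_gt, auc_gt, "gt_positive", curves, thr)
    return ROCResult(pts_le, auc_le, "le_positive", curves, thr)


@dataclass
class DiagnosticResult:
    feature: str
    cutoff: float
    orientation: str
    sensitivity: float  # %
    specificity: float  # %
    auc: float
    youden_j: float


def youden_cutoff(roc: ROCResult, feature: str = "") -> DiagnosticResult:
    """Cut-off maximizing J = sensitivity + specificity - 1.

    Both orientations are searched; ties break toward the ROC's reported
    orientation, then toward higher sensitivity, then toward the lower
    threshold (a screening-oriented convention).
    """
    orientations = [roc.orientation] + [
        o for o in roc.curves if o != roc.orientation
    ]
    best = None
    for orientation in orientations:
        for t, sens, spec in roc.curves.get(orientation, roc.points):
            j = sens + spec - 1.0
            key = (j, sens, -t)
            if best is None or key > best[0]:
                best = (key, orientation, t, sens, spec, j)
    _, orientation, t, sens, spec, j = best
    return DiagnosticResult(
        feature=feature,
        cutoff=t,
        orientation=orientation,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        auc=roc.auc,
        youden_j=j,
    )


def feature_diagnostics(table: pd.DataFrame, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-feature ROC/AUC/Youden workup, sorted by descending AUC.

    Feature columns with non-finite values are skipped.
    """
    labels = np.asarray(labels)
    rows = []
    for name in table.columns:
        vals = table[name].to_numpy(dtype=np.float64)
        if not np.isfinite(vals).all():
            continue
        roc = roc_points(vals, labels)
        diag = youden_cutoff(roc, feature=name)
        rows.append(
            {
                "feature": diag.feature,
                "cutoff": diag.cutoff,
                "orientation": diag.orientation,
                "sensitivity": diag.sensitivity,
                "specificity": diag.specificity,
                "auc": diag.auc,
                "youden_j": diag.youden_j,
            }
        )
    if not rows:
        raise ParameterError("no usable feature column")
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["auc", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def group_comparison(table: pd.DataFrame, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Group means with ANOVA F/p per feature (a case-control summary table)."""
    ranked = rank_features(table, labels)
    df = ranked.table[["feature", "mean_control", "mean_case", "F", "p"]].copy()
    return df.sort_values("feature", kind="mergesort").reset_index(drop=True)
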