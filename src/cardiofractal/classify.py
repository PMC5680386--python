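"""Group separation in multifractal index planes.

Records are reduced to points in a two-dimensional index plane —
typically (alpha1, gamma1) or (alpha1, alpha0) — and a soft-margin
support-vector machine with an RBF kernel is trained on the labeled
points. Prediction quality is summarized by the product
Accuracy = t_p * t_n of the true-positive (healthy) and true-negative
(unhealthy) rates: a classifier that assigns everything to one group
scores zero, however unbalanced the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .errors import DegenerateTrainingError, ParameterError

__all__ = ["LabeledIndexSet", "ClassifierEvaluation", "SVCDecision",
           "accuracy", "train_svc", "evaluate_split", "decision_regions"]

POSITIVE_LABEL = "healthy"
NEGATIVE_LABEL = "unhealthy"


@dataclass(frozen=True)
class LabeledIndexSet:
    """Points in a 2-D index plane with binary group labels."""

    features: np.ndarray          # (n, 2)
    labels: np.ndarray            # 'healthy' / 'unhealthy'
    plane: tuple = ("alpha1", "gamma1")
    subject_ids: list | None = None
    channels: list | None = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        if feats.ndim != 2 or feats.shape[1] != 2:
            raise ParameterError("features must be an (n, 2) array")
        if labels.shape[0] != feats.shape[0]:
            raise ParameterError("labels and features length mismatch")
        bad = set(labels) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ParameterError(f"unknown labels {sorted(bad)}")
        if not np.all(np.isfinite(feats)):
            raise ParameterError("index plane contains missing values")

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class ClassifierEvaluation:
    """tp, tn and accuracy over random stratified splits."""

    train_fraction: float
    n_realizations: int
    tp_list: list
    tn_list: list
    accuracy_list: list
    mean_accuracy: float
    seed: int


def accuracy(tp: float, tn: float) -> float:
    """Accuracy = tp * tn; zero if either rate is zero."""
    if not (0.0 <= tp <= 1.0 and 0.0 <= tn <= 1.0):
        raise ParameterError("tp and tn must lie in [0, 1]")
    return tp * tn


class SVCDecision:
    """A fitted RBF-SVM decision function over a standardized 2-D plane."""

    def __init__(self, svc: SVC, mean: np.ndarray, sd: np.ndarray):
        self._svc = svc
        self._mean = mean
        self._sd = sd

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self._mean) / self._sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._transform(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._transform(X))


def train_svc(data: LabeledIndexSet, C: float = 1.0,
              gamma: float | None = None) -> SVCDecision:
    """Fit the RBF-kernel SVM on a labeled index set.

    Features are standardized by the training-set mean and standard
    deviation; the default kernel width is
    gamma = 1 / (2 * median(pairwise distance)^2) of the standardized
    training points — a scale-free heuristic.
    """
    labels = data.labels
    for cls in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if np.sum(labels == cls) < 3:
            raise DegenerateTrainingError(
                f"need at least 3 points of class {cls!r}")
    mean = data.features.mean(axis=0)
    sd = data.features.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    X = (data.features - mean) / sd
    if gamma is None:
        med = float(np.median(pdist(X)))
        gamma = 1.0 / (2.0 * med ** 2) if med > 0 else 1.0
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(X, labels)
    return SVCDecision(svc, mean, sd)


def _rates(decision: SVCDecision, X: np.ndarray, y: np.ndarray):
    pred = decision.predict(X)
    pos = y == POSITIVE_LABEL
    neg = y == NEGATIVE_LABEL
    tp = float(np.mean(pred[pos] == POSITIVE_LABEL)) if pos.any() else 0.0
    tn = float(np.mean(pred[neg] == NEGATIVE_LABEL)) if neg.any() else 0.0
    return tp, tn


def evaluate_split(data: LabeledIndexSet, train_fraction: float,
                   n_realizations: int = 10, seed: int = 0,
                   C: float = 1.0, gamma: float | None = None
                   ) -> ClassifierEvaluation:
    """Blind-prediction accuracy averaged over random stratified splits.

    For each realization the set is split (stratified, so both classes
    appear on both sides), the SVM is fit on the training part, and
    tp, tn and their product are computed on the held-out part.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must lie strictly in (0, 1)")
    if n_realizations < 1:
        raise ParameterError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    tp_list, tn_list, acc_list = [], [], []
    for _ in range(n_realizations):
        rs = int(rng.integers(0, 2 ** 31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            data.features, data.labels, train_size=train_fraction,
            stratify=data.labels, random_state=rs)
        decision = train_svc(
            LabeledIndexSet(features=X_tr, labels=y_tr, plane=data.plane),
            C=C, gamma=gamma)
        tp, tn = _rates(decision, X_te, y_te)
        tp_list.append(tp)
        tn_list.append(tn)
        acc_list.append(accuracy(tp, tn))
    return ClassifierEvaluation(train_fraction=train_fraction,
                                n_realizations=n_realizations,
                                tp_list=tp_list, tn_list=tn_list,
                                accuracy_list=acc_list,
                                mean_accuracy=float(np.mean(acc_list)),
                                seed=seed)


def decision_regions(decision: SVCDecision, bounds, grid_resolution: int = 200):
    """Rasterize the decision function over a rectangle of the plane.

    ``bounds = ((x_lo, x_hi), (y_lo, y_hi))``. Returns a dict with the
    grid axes, the predicted label raster, the signed decision values,
    and the zero-level boundary polylines (marching squares).
    """
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    if not (x_hi > x_lo and y_hi > y_lo) or grid_resolution < 1:
        raise ParameterError("empty bounds or non-positive resolution")
    xs = np.linspace(x_lo, x_hi, grid_resolution)
    ys = np.linspace(y_lo, y_hi, grid_resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    values = decision.decision_function(pts).reshape(gx.shape)
    labels = decision.predict(pts).reshape(gx.shape)
    polylines = []
    if grid_resolution >= 2 and values.min() < 0 < values.max():
        from skimage import measure
        for contour in measure.find_contours(values, 0.0):
            # contour rows are (row, col) = (y index, x index)
            cx = np.interp(contour[:, 1], np.arange(xs.size), xs)
            cy = np.interp(contour[:, 0], np.arange(ys.size), ys)
            polylines.append(np.column_stack([cx, cy]))
    return {"x": xs, "y": ys, "labels": labels, "decision_values": values,
            "boundaries": polylines}
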