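"""Multi-class linear discriminant analysis (canonical variates).

Given PCA scores (LDA on raw dense coordinates would be singular; an
intermediate PCA reduction guarantees a full-rank within-class scatter),
the classifier forms the within-class scatter

    Sigma_w = sum_i sum_{x in class i} (x - xbar_i)(x - xbar_i)'

and the between-class scatter

    Sigma_b = sum_i m_i (xbar_i - xbar)(xbar_i - xbar)',

and solves the generalized eigenproblem Sigma_b phi = lambda Sigma_w phi
for the discriminant directions (at most g - 1 non-trivial ones for g
classes).  A new sample z is assigned to argmin_k d(z Phi, xbar_k Phi)
under either Euclidean or cosine distance in the discriminant space --
a nearest-centroid rule with implicit equal priors.

Performance is reported one-vs-rest per class: sensitivity/recall
TP/(TP+FN), specificity TN/(FP+TN), precision TP/(TP+FP) and accuracy
(TP+TN)/(TP+FP+TN+FN), plus a row-percentage confusion matrix (rows =
true class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "LDAModel",
    "ClassReport",
    "fit_lda",
    "predict",
    "cross_validate",
    "confusion_and_metrics",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass
class LDAModel:
    classes: np.ndarray
    class_means: np.ndarray  # (g, p)
    class_counts: np.ndarray
    grand_mean: np.ndarray
    scatter_within: np.ndarray  # (p, p)
    scatter_between: np.ndarray  # (p, p)
    directions: np.ndarray  # (p, n_discriminants), unit columns
    eigenvalues: np.ndarray  # descending, >= 0

    @property
    def proportions(self) -> np.ndarray:
        """Share of discriminant variance carried by each direction."""
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_nonzero(self) -> int:
        lam = self.eigenvalues
        if len(lam) == 0 or lam[0] <= 0:
            return 0
        return int((lam > _EIG_TOL * lam[0]).sum())

    def project(self, data: np.ndarray) -> np.ndarray:
        """Discriminant-space coordinates, centered at the grand mean so
        that angular (cosine) distances are taken about the data center."""
        return (np.atleast_2d(data) - self.grand_mean) @ self.directions


def fit_lda(features: np.ndarray, labels, ridge: float = 0.0) -> LDAModel:
    """Fit canonical variates to (n, p) features with g class labels.

    Requires p < n and a nonsingular within-class scatter; if the scatter
    is singular, reduce the features by PCA first or pass a small
    ``ridge`` (adds ridge * trace/p * I).  Directions are unit length
    with the same deterministic sign convention as the PCA loadings.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(labels):
        raise ValueError("features must be (n, p) matching labels")
    classes, y = np.unique(labels, return_inverse=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 classes")
    n, p = x.shape

    counts = np.bincount(y, minlength=g)
    means = np.stack([x[y == i].mean(axis=0) for i in range(g)])
    grand = (counts[:, None] * means).sum(axis=0) / n

    sw = np.zeros((p, p))
    for i in range(g):
        d = x[y == i] - means[i]
        sw += d.T @ d
    db = means - grand
    sb = (counts[:, None] * db).T @ db
    if ridge > 0:
        scale = np.trace(sw) / p
        if scale <= 0:  # no within-class variation at all
            scale = max(np.trace(sb) / p, 1.0)
        sw = sw + ridge * scale * np.eye(p)

    try:
        lam, vec = scipy.linalg.eigh(sb, sw)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        raise np.linalg.LinAlgError(
            "singular within-class scatter: reduce features with PCA first "
            "or pass ridge > 0"
        ) from None
    order = np.argsort(lam)[::-1]
    n_keep = min(g - 1, p)
    lam = np.clip(lam[order][:n_keep], 0.0, None)
    vec = vec[:, order][:, :n_keep]
    vec = vec / np.linalg.norm(vec, axis=0)
    flip = np.sign(vec[np.abs(vec).argmax(axis=0), np.arange(vec.shape[1])])
    flip[flip == 0] = 1.0
    vec = vec * flip
    return LDAModel(classes, means, counts, grand, sw, sb, vec, lam)


def predict(model: LDAModel, samples: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Nearest projected centroid classification (Euclidean or cosine)."""
    z = model.project(samples)
    c = model.project(model.class_means)
    if metric == "euclidean":
        d = np.linalg.norm(z[:, None, :] - c[None, :, :], axis=2)
    elif metric == "cosine":
        zn = np.linalg.norm(z, axis=1, keepdims=True)
        cn = np.linalg.norm(c, axis=1, keepdims=True)
        zn[zn == 0] = 1.0
        cn[cn == 0] = 1.0
        d = 1.0 - (z @ c.T) / (zn * cn.T)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ties = (d == d.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.debug("tie in %d prediction(s); broken by lowest class index",
                     int(ties.sum()))
    return model.classes[np.argmin(d, axis=1)]


@dataclass
class ClassReport:
    """Classification performance in the tabular layout of the field:
    row-percentage confusion matrix plus one-vs-rest metrics."""

    classes: np.ndarray
    confusion_counts: np.ndarray
    confusion_percent: np.ndarray  # rows sum to 100
    precision: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    per_class_accuracy: np.ndarray
    accuracy: float  # overall fraction correct
    macro: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "confusion_percent": np.round(self.confusion_percent, 2).tolist(),
            "precision": self.precision.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "accuracy": self.accuracy,
            "macro": self.macro,
        }


def confusion_and_metrics(y_true, y_pred) -> ClassReport:
    """Build the confusion matrix and one-vs-rest metrics.

    Rows of the confusion matrix are the TRUE classes and are expressed
    as percentages (each row sums to 100).  Metrics are fractions in
    [0, 1]; ``accuracy`` is the overall fraction of correct predictions.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    classes = np.unique(y_true)
    unseen = set(np.unique(y_pred)) - set(classes)
    if unseen:
        raise ValueError(f"predicted label(s) {sorted(unseen)!r} not among true classes")
    g = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((g, g), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("class with no true samples")
    percent = 100.0 * counts / row_sums[:, None]

    n = counts.sum()
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = n - tp - fp - fn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        sensitivity = tp / (tp + fn)
        specificity = np.where(fp + tn > 0, tn / (fp + tn), 0.0)
    per_class_acc = (tp + tn) / n
    accuracy = float(tp.sum() / n)
    macro = {
        "precision": float(precision.mean()),
        "sensitivity": float(sensitivity.mean()),
        "specificity": float(specificity.mean()),
        "accuracy": accuracy,
    }
    return ClassReport(
        classes, counts, percent, precision, sensitivity, specificity,
        per_class_acc, accuracy, macro,
    )


def _stratified_split(labels: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = max(1, int(round(train_frac * len(idx))))
        n_train = min(n_train, len(idx) - 1)  # keep at least one test sample
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def cross_validate(
    features: np.ndarray,
    labels,
    scheme: str = "split",
    train_frac: float = 0.70,
    seed: int | None = None,
    metric: str = "euclidean",
    ridge: float = 0.0,
) -> ClassReport:
    """Cross-validated classification report.

    ``scheme='loocv'`` leaves each sample out in turn; ``scheme='split'``
    is a stratified 70/30 train/test split (seed required).  Each fold
    refits the LDA on its training portion only.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)

    def fit_fold(xt, yt):
        # a fold can lose within-class variation (e.g. one sample per
        # class); fall back to a negligible ridge so the fold still fits
        try:
            return fit_lda(xt, yt, ridge=ridge)
        except np.linalg.LinAlgError:
            if ridge > 0:
                raise
            logger.debug("singular fold scatter; refitting with ridge 1e-8")
            return fit_lda(xt, yt, ridge=1e-8)

    if scheme == "loocv":
        preds = []
        for i in range(len(x)):
            mask = np.ones(len(x), dtype=bool)
            mask[i] = False
            model = fit_fold(x[mask], labels[mask])
            preds.append(predict(model, x[i : i + 1], metric)[0])
        return confusion_and_metrics(labels, np.array(preds))
    if scheme == "split":
        if seed is None:
            raise ValueError("split scheme requires a seed")
        rng = np.random.default_rng(seed)
        train_idx, test_idx = _stratified_split(labels, train_frac, rng)
        model = fit_fold(x[train_idx], labels[train_idx])
        preds = predict(model, x[test_idx], metric)
        return confusion_and_metrics(labels[test_idx], preds)
    raise ValueError(f"unknown scheme {scheme!r}")
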