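"""Balanced-resampled linear discriminant analysis with repeated cross-validation.

The classifier projects feature vectors onto at most C-1 discriminant
directions — eigenvectors of the pooled within-class scatter inverse times
the between-class scatter — and assigns each event to the nearest projected
class centroid.  Class imbalance is handled by random under-sampling to the
smallest class; performance is estimated by leave-one-subset-out (k-fold)
cross-validation, repeated many times with fresh resampling so that means
carry a meaningful 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .features import LabeledDataset
from .metrics import (
    ConfusionMatrix,
    EvaluationReport,
    ci95,
    f1_score,
    overall_accuracy,
    precision_recall_f1,
)

__all__ = [
    "CvConfig",
    "LdaModel",
    "undersample",
    "lda_fit",
    "lda_predict",
    "crossval_confusion",
    "repeat_evaluate",
]


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation protocol: k folds, repeated n times with under-sampling."""

    n_subsets: int = 10
    n_repeats: int = 1000
    seed: int = 0
    undersample: bool = True

    def __post_init__(self) -> None:
        if self.n_subsets < 2:
            raise ValueError("n_subsets must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class LdaModel:
    """Fitted discriminant model.

    ``basis`` holds up to C-1 unit-norm discriminant directions (columns) in
    standardized feature space; ``centroids_projected`` the class centroids
    in that space, ordered like ``class_order``.
    """

    class_order: tuple[str, ...]
    class_means: np.ndarray  # (C, d) in standardized space
    pooled_scatter: np.ndarray  # (d, d)
    basis: np.ndarray  # (d, r), r <= C-1
    centroids_projected: np.ndarray  # (C, r)
    eigenvalues: np.ndarray  # (r,)
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray

    @property
    def n_directions(self) -> int:
        return self.basis.shape[1]


def undersample(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Randomly discard events from larger classes until all classes match
    the smallest class count.  Row order of retained events is preserved;
    deterministic given ``seed``."""
    counts = dataset.class_counts()
    if not counts:
        raise ValueError("empty dataset")
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for label in sorted(counts):
        idx = np.flatnonzero(dataset.y == label)
        if len(idx) > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep.append(idx)
    kept = np.sort(np.concatenate(keep))
    return dataset.subset(kept)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def lda_fit(
    train: LabeledDataset,
    ridge: float = 1e-6,
    standardize: bool = True,
) -> LdaModel:
    """Fit the discriminant basis on a training set.

    Features are optionally z-scored (training statistics only).  The pooled
    within-class scatter gets a ridge of ``ridge * trace/dim`` on its
    diagonal so small folds stay invertible.  Directions solve the
    generalized eigenproblem S_b v = lambda S_w v; the top C-1 eigenvectors
    (unit-normalized) form the basis.
    """
    labels = sorted(set(train.y.tolist()))
    if len(labels) < 2:
        raise ValueError("LDA needs at least 2 classes")
    counts = train.class_counts()
    small = [c for c in labels if counts[c] < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 training events: {small}")

    if standardize:
        mean, scale = _standardize_fit(train.X)
    else:
        mean = np.zeros(train.X.shape[1])
        scale = np.ones(train.X.shape[1])
    X = (train.X - mean) / scale
    d = X.shape[1]

    grand = X.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    class_means = np.empty((len(labels), d))
    for i, label in enumerate(labels):
        xc = X[train.y == label]
        mu = xc.mean(axis=0)
        class_means[i] = mu
        centered = xc - mu
        sw += centered.T @ centered
        diff = (mu - grand)[:, None]
        sb += len(xc) * (diff @ diff.T)

    sw_reg = sw + ridge * (np.trace(sw) / d) * np.eye(d)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(sb, sw_reg)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-class scatter is singular even after ridge "
            "regularization; use more data or fewer features"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    r = len(labels) - 1
    basis = eigvecs[:, order[:r]]
    eigvals = np.clip(eigvals[order[:r]], 0.0, None)
    norms = np.linalg.norm(basis, axis=0)
    basis = basis / np.where(norms > 0, norms, 1.0)

    centroids = class_means @ basis
    return LdaModel(
        class_order=tuple(labels),
        class_means=class_means,
        pooled_scatter=sw,
        basis=basis,
        centroids_projected=centroids,
        eigenvalues=eigvals,
        scaler_mean=mean,
        scaler_scale=scale,
    )


def lda_predict(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Assign each row to the class of the nearest projected centroid.

    Euclidean distance in discriminant space; exact ties resolve to the
    first class in ``class_order`` (argmin keeps the first minimum).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.scaler_mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.scaler_mean.shape[0]})"
        )
    Z = ((X - model.scaler_mean) / model.scaler_scale) @ model.basis
    d2 = ((Z[:, None, :] - model.centroids_projected[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray(model.class_order)[idx]


def crossval_confusion(
    dataset: LabeledDataset,
    config: CvConfig,
    repeat_index: int = 0,
    ridge: float = 1e-6,
    standardize: bool = True,
) -> ConfusionMatrix:
    """One leave-one-subset-out pass: k stratified folds, each tested once.

    Events of every class are randomly spread over ``n_subsets`` folds; each
    fold is predicted by a model trained on the others and every event is
    tested exactly once.  Deterministic given (dataset, config, repeat_index).
    """
    labels = sorted(set(dataset.y.tolist()))
    counts = dataset.class_counts()
    k = config.n_subsets
    too_small = [c for c in labels if counts[c] < k]
    if too_small:
        raise ValueError(f"classes smaller than n_subsets={k}: {too_small}")

    rng = np.random.default_rng(config.seed + repeat_index)
    fold_of = np.empty(len(dataset), dtype=int)
    for label in labels:
        idx = np.flatnonzero(dataset.y == label)
        perm = rng.permutation(idx)
        fold_of[perm] = np.arange(len(perm)) % k

    cm = np.zeros((len(labels), len(labels)), dtype=np.int64)
    label_index = {c: i for i, c in enumerate(labels)}
    for fold in range(k):
        test_mask = fold_of == fold
        model = lda_fit(dataset.subset(np.flatnonzero(~test_mask)), ridge=ridge,
                        standardize=standardize)
        pred = lda_predict(model, dataset.X[test_mask])
        for t, p in zip(dataset.y[test_mask], pred):
            cm[label_index[t], label_index[p]] += 1
    return ConfusionMatrix(counts=cm, class_order=tuple(labels))


def repeat_evaluate(
    dataset: LabeledDataset,
    config: CvConfig,
    ridge: float = 1e-6,
    standardize: bool = True,
) -> EvaluationReport:
    """Repeat (undersample, k-fold cross-validate, score) n_repeats times.

    Repeat r seeds both the under-sampling and the fold assignment with
    ``config.seed + r``, so any reported number can be regenerated in
    isolation.  Metrics are summarised as mean and 1.96-standard-error 95%
    CI over repeats, in percent; undefined per-class metrics (empty rows or
    columns in a repeat) are excluded from that repeat's average rather than
    counted as zero.
    """
    labels = sorted(set(dataset.y.tolist()))
    per_repeat: dict[str, dict[str, list[float]]] = {
        c: {"precision": [], "recall": [], "f1": []} for c in labels
    }
    oac: list[float] = []
    cm_sum = np.zeros((len(labels), len(labels)), dtype=float)
    for r in range(config.n_repeats):
        ds_r = undersample(dataset, config.seed + r) if config.undersample else dataset
        cm = crossval_confusion(ds_r, config, repeat_index=r, ridge=ridge,
                                standardize=standardize)
        oac.append(overall_accuracy(cm))
        cm_sum += cm.counts
        for c in labels:
            m = precision_recall_f1(cm, c)
            per_repeat[c]["precision"].append(m.precision)
            per_repeat[c]["recall"].append(m.recall)
            per_repeat[c]["f1"].append(m.f1)

    per_class = {}
    f1_of_means = {}
    for c in labels:
        per_class[c] = {}
        for metric, values in per_repeat[c].items():
            mean, hw = ci95(values)
            per_class[c][metric] = (100.0 * mean, 100.0 * hw)
        p_mean = per_class[c]["precision"][0] / 100.0
        r_mean = per_class[c]["recall"][0] / 100.0
        f1_of_means[c] = 100.0 * f1_score(p_mean, r_mean)
    oac_mean, oac_hw = ci95(oac)
    return EvaluationReport(
        class_order=tuple(labels),
        per_class=per_class,
        overall_accuracy=(100.0 * oac_mean, 100.0 * oac_hw),
        f1_of_means=f1_of_means,
        n_repeats=config.n_repeats,
        config={
            "n_subsets": config.n_subsets,
            "n_repeats": config.n_repeats,
            "seed": config.seed,
            "undersample": config.undersample,
            "ridge": ridge,
            "standardize": standardize,
        },
        degenerate_ci=config.n_repeats == 1,
        mean_confusion=cm_sum / config.n_repeats,
    )
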