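"""The decoding chain: sliding-window crops, CSP, PCA, LDA, balanced accuracy.

Thirty-second stimulation trials are augmented into 3-s crops by a
non-overlapping sliding window (10 crops per trial). Common spatial
patterns (CSP) filters are fitted by simultaneous diagonalization of the
two class-average covariance matrices; the log-variance of each spatially
filtered crop is the feature, reduced to two principal components and
classified with linear discriminant analysis. Evaluation uses an 80/20
stratified split with stratified ten-fold cross-validation on the training
portion, scored by balanced accuracy (mean of sensitivity and specificity).

Crops of one parent trial are highly dependent; by default every split is
*group-aware* (all crops of a trial stay on one side), with naive per-crop
stratification available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg as _linalg
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import (
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)

from .config import ClassificationConfig
from .preprocessing import EpochSet

__all__ = [
    "CropSet", "CSPModel", "ClassifierReport", "crop_augment", "fit_csp",
    "csp_features", "reduce_pca", "train_eval", "bacc", "bacc_multiclass",
    "decode_crops",
]


@dataclass
class CropSet:
    """Fixed-length contiguous slices of parent trials.

    ``parent_ids[i]`` is the index of the epoch the i-th crop was cut from;
    ``offsets[i]`` its starting sample within that epoch.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    parent_ids: np.ndarray
    offsets: np.ndarray
    channel_names: List[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)

    @property
    def n_crops(self) -> int:
        return self.data.shape[0]


@dataclass
class CSPModel:
    """Fitted CSP spatial filters for one class pair.

    ``filters`` has shape (2 * n_pairs, channels); ``eigenvalues[i]`` is the
    fraction of class-A variance captured by filter i (in [0, 1], extremes
    first). ``patterns`` are the corresponding forward-model columns.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    class_pair: Tuple[str, str]
    shrinkage: float
    channel_names: List[str] = field(default_factory=list)

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


@dataclass
class ClassifierReport:
    """Evaluation summary of one binary (or multi-class) task."""

    confusion: np.ndarray
    classes: List[str]
    fold_baccs: List[float]
    test_bacc: float
    seed: int
    class_pair: Optional[Tuple[str, str]] = None
    group_aware: bool = True

    @property
    def validation_bacc(self) -> float:
        return float(np.mean(self.fold_baccs)) if self.fold_baccs else float("nan")


def crop_augment(epochs: EpochSet, window_s: float, stride_s: float) -> CropSet:
    """Slide a window over every trial to create fixed-length crops.

    Offsets run ``0, stride, 2*stride, ...`` while the window still fits;
    with window = stride (default 3 s) the crops tile the trial exactly
    (10 crops per 30-s trial). Window and stride are in seconds.
    """
    n_win = int(round(window_s * epochs.fs))
    n_stride = int(round(stride_s * epochs.fs))
    if n_win > epochs.n_samples:
        raise ValueError(
            f"window {window_s} s ({n_win} samples) exceeds trial length "
            f"({epochs.n_samples} samples)"
        )
    if n_stride < 1:
        raise ValueError("stride must be at least one sample")
    starts = np.arange(0, epochs.n_samples - n_win + 1, n_stride)
    data, labels, parents, offsets = [], [], [], []
    for k in range(epochs.n_epochs):
        for s in starts:
            data.append(epochs.data[k, :, s : s + n_win])
            labels.append(epochs.labels[k])
            parents.append(k)
            offsets.append(s)
    return CropSet(
        data=np.stack(data),
        fs=epochs.fs,
        labels=np.array(labels),
        parent_ids=np.array(parents),
        offsets=np.array(offsets),
        channel_names=list(epochs.channel_names),
    )


def _class_covariance(data: np.ndarray) -> np.ndarray:
    """Average trace-normalized spatial covariance over crops."""
    covs = np.einsum("kct,kdt->kcd", data, data) / data.shape[2]
    traces = np.trace(covs, axis1=1, axis2=2)
    traces = np.where(traces > 0, traces, 1.0)
    return (covs / traces[:, None, None]).mean(axis=0)


def _shrink(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    n = cov.shape[0]
    return (1 - shrinkage) * cov + shrinkage * (np.trace(cov) / n) * np.eye(n)


def fit_csp(
    crops: Union[CropSet, np.ndarray],
    labels: Optional[Sequence] = None,
    n_pairs: int = 2,
    shrinkage: float = 1e-4,
) -> CSPModel:
    """Fit CSP filters discriminating two classes by variance ratio.

    Solves the generalized eigenproblem ``Ca w = lambda (Ca + Cb) w`` on the
    (optionally shrinkage-regularized) class-average covariances and keeps
    the ``n_pairs`` filters with the largest and smallest eigenvalues,
    extremes first. Eigenvalues are the class-A variance fractions.
    """
    if isinstance(crops, CropSet):
        data, labels = crops.data, crops.labels
        channel_names = list(crops.channel_names)
    else:
        data = np.asarray(crops, dtype=float)
        if labels is None:
            raise ValueError("labels required with array input")
        labels = np.asarray(labels)
        channel_names = []
    classes = sorted(set(np.asarray(labels).tolist()))
    if len(classes) != 2:
        raise ValueError(f"CSP is binary; got classes {classes}")
    a, b = classes
    mask = np.asarray(labels) == a
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 crops per class")
    n_chan = data.shape[1]
    if not 1 <= 2 * n_pairs <= n_chan:
        raise ValueError(f"n_pairs={n_pairs} infeasible for {n_chan} channels")
    ca = _shrink(_class_covariance(data[mask]), shrinkage)
    cb = _shrink(_class_covariance(data[~mask]), shrinkage)
    composite = ca + cb
    cond = np.linalg.eigvalsh(composite)
    if cond[0] <= max(1e-12 * cond[-1], 0.0):
        raise np.linalg.LinAlgError(
            "composite covariance is rank deficient; increase the covariance "
            "shrinkage (e.g. shrinkage=1e-4)"
        )
    evals, evecs = _linalg.eigh(ca, composite)      # ascending in [0, 1]
    evals = np.clip(evals, 0.0, 1.0)
    order: List[int] = []
    lo, hi = 0, n_chan - 1
    for _ in range(n_pairs):                        # extremes first
        order.append(hi)
        order.append(lo)
        hi -= 1
        lo += 1
    filters = evecs[:, order].T
    return CSPModel(
        filters=filters,
        eigenvalues=evals[order],
        class_pair=(str(a), str(b)),
        shrinkage=shrinkage,
        channel_names=channel_names,
    )


def csp_features(
    model: CSPModel,
    crops: Union[CropSet, np.ndarray],
    var_floor: float = 1e-20,
) -> np.ndarray:
    """Log-variance of each spatially filtered signal, per crop.

    Zero-variance projections are floored at ``var_floor`` before the log.
    """
    data = crops.data if isinstance(crops, CropSet) else np.asarray(crops, float)
    if data.shape[1] != model.filters.shape[1]:
        raise ValueError(
            f"crop channel count {data.shape[1]} does not match model "
            f"({model.filters.shape[1]})"
        )
    projected = np.einsum("fc,kct->kft", model.filters, data)
    var = projected.var(axis=2)
    return np.log(np.maximum(var, var_floor))


def reduce_pca(features: np.ndarray, k: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Project mean-centered features onto the top-k principal axes.

    Sign convention: the largest-magnitude loading of each axis is positive,
    making the projection deterministic. Returns (scores, explained variance
    ratio).
    """
    features = np.asarray(features, dtype=float)
    if k > features.shape[1]:
        raise ValueError(f"k={k} exceeds feature dimension {features.shape[1]}")
    if features.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(features)
    comps = pca.components_
    flip = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip, pca.explained_variance_ratio_


def bacc(confusion: np.ndarray) -> float:
    """Balanced accuracy of a 2x2 confusion matrix: (Sens + Spec) / 2.

    Rows are true classes, columns predictions; ``confusion[0, 0]`` counts
    true positives of the first class.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (2, 2):
        raise ValueError("binary bACC needs a 2x2 confusion matrix")
    totals = confusion.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("both classes must have at least one instance")
    sens = confusion[0, 0] / totals[0]
    spec = confusion[1, 1] / totals[1]
    return float((sens + spec) / 2)


def bacc_multiclass(confusion: np.ndarray) -> float:
    """Mean per-class recall (reduces to binary bACC for two classes)."""
    confusion = np.asarray(confusion, dtype=float)
    totals = confusion.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every class must have at least one instance")
    return float(np.mean(np.diag(confusion) / totals))


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    out = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        out[index[t], index[p]] += 1
    return out


def _effective_folds(labels, groups, requested: int) -> int:
    """Cap the fold count so every class can appear in every validation fold.

    With group-aware splitting the limit is the number of distinct parent
    trials of the rarest class; without groups, its sample count.
    """
    labels = np.asarray(labels)
    counts = []
    for c in set(labels.tolist()):
        if groups is None:
            counts.append(int((labels == c).sum()))
        else:
            counts.append(len(set(np.asarray(groups)[labels == c].tolist())))
    return max(2, min(requested, min(counts)))


def _grouped_split(labels, groups, test_fraction, seed):
    """Stratified split of label-pure groups; returns boolean test mask."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    group_label = {}
    for g in uniq:
        lab = set(np.asarray(labels)[groups == g].tolist())
        if len(lab) != 1:
            raise ValueError(f"group {g} has mixed labels {lab}")
        group_label[g] = lab.pop()
    train_g, test_g = train_test_split(
        uniq,
        test_size=test_fraction,
        random_state=seed,
        stratify=[group_label[g] for g in uniq],
    )
    return np.isin(groups, test_g)


def train_eval(
    features: np.ndarray,
    labels: Sequence,
    seed: int,
    groups: Optional[Sequence] = None,
    cv_folds: int = 10,
    split_fraction: float = 0.8,
) -> ClassifierReport:
    """80/20 split, stratified k-fold CV with LDA, held-out test bACC.

    With ``groups`` (default decoding mode passes parent-trial ids), all
    samples of one group stay on one side of every split, so crops never
    leak across the train/validation/test boundary.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"binary task expected; got {classes}")
    if groups is not None:
        test_mask = _grouped_split(labels, groups, 1 - split_fraction, seed)
    else:
        idx = np.arange(len(labels))
        _, test_idx = train_test_split(
            idx, test_size=1 - split_fraction, random_state=seed,
            stratify=labels,
        )
        test_mask = np.isin(idx, test_idx)
    x_train, y_train = features[~test_mask], labels[~test_mask]
    x_test, y_test = features[test_mask], labels[test_mask]

    fold_baccs: List[float] = []
    if groups is not None:
        g_train = np.asarray(groups)[~test_mask]
        k = _effective_folds(y_train, g_train, cv_folds)
        splitter = StratifiedGroupKFold(k, shuffle=True, random_state=seed)
        folds = splitter.split(x_train, y_train, g_train)
    else:
        k = _effective_folds(y_train, None, cv_folds)
        splitter = StratifiedKFold(k, shuffle=True, random_state=seed)
        folds = splitter.split(x_train, y_train)
    for tr, va in folds:
        if len(set(y_train[tr])) < 2 or len(set(y_train[va])) < 2:
            raise ValueError(
                "a cross-validation fold is missing a class; use fewer folds"
            )
        lda = LinearDiscriminantAnalysis().fit(x_train[tr], y_train[tr])
        fold_baccs.append(
            bacc(_confusion(y_train[va], lda.predict(x_train[va]), classes))
        )
    lda = LinearDiscriminantAnalysis().fit(x_train, y_train)
    confusion = _confusion(y_test, lda.predict(x_test), classes)
    return ClassifierReport(
        confusion=confusion,
        classes=[str(c) for c in classes],
        fold_baccs=fold_baccs,
        test_bacc=bacc(confusion),
        seed=seed,
        class_pair=(str(classes[0]), str(classes[1])),
        group_aware=groups is not None,
    )


def decode_crops(
    crops: CropSet,
    config: Optional[ClassificationConfig] = None,
    seed: int = 0,
) -> ClassifierReport:
    """Full decoding of a binary CropSet: CSP -> log-variance -> PCA -> LDA.

    The 80/20 split and the ten-fold cross-validation are group-aware by
    default (``config.group_aware``); CSP and PCA are refitted inside every
    fold (``config.csp_per_fold``) so that no spatial filter ever sees its
    own validation or test crops.
    """
    cfg = config or ClassificationConfig()
    labels = crops.labels
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"binary task expected; got {classes}")
    groups = crops.parent_ids if cfg.group_aware else None

    if groups is not None:
        test_mask = _grouped_split(labels, groups, 1 - cfg.split_fraction, seed)
    else:
        idx = np.arange(len(labels))
        _, test_idx = train_test_split(
            idx, test_size=1 - cfg.split_fraction, random_state=seed,
            stratify=labels,
        )
        test_mask = np.isin(idx, test_idx)
    tr_idx = np.flatnonzero(~test_mask)
    te_idx = np.flatnonzero(test_mask)

    def _fit_chain(train_ids):
        model = fit_csp(
            crops.data[train_ids], labels[train_ids],
            n_pairs=cfg.n_csp_pairs, shrinkage=cfg.csp_shrinkage,
        )
        feats = csp_features(model, crops.data[train_ids])
        pca = PCA(n_components=cfg.pca_components, svd_solver="full")
        lda = LinearDiscriminantAnalysis()
        lda.fit(pca.fit_transform(feats), labels[train_ids])
        return model, pca, lda

    def _predict(chain, ids):
        model, pca, lda = chain
        return lda.predict(pca.transform(csp_features(model, crops.data[ids])))

    y_tr = labels[tr_idx]
    if groups is not None:
        g_tr = np.asarray(groups)[tr_idx]
        k = _effective_folds(y_tr, g_tr, cfg.cv_folds)
        splitter = StratifiedGroupKFold(k, shuffle=True, random_state=seed)
        folds = splitter.split(tr_idx, y_tr, g_tr)
    else:
        k = _effective_folds(y_tr, None, cfg.cv_folds)
        splitter = StratifiedKFold(k, shuffle=True, random_state=seed)
        folds = splitter.split(tr_idx, y_tr)

    fold_baccs: List[float] = []
    shared_chain = None if cfg.csp_per_fold else _fit_chain(tr_idx)
    for tr, va in folds:
        if len(set(y_tr[tr])) < 2 or len(set(y_tr[va])) < 2:
            raise ValueError(
                "a cross-validation fold is missing a class; use fewer folds"
            )
        chain = _fit_chain(tr_idx[tr]) if cfg.csp_per_fold else shared_chain
        pred = _predict(chain, tr_idx[va])
        fold_baccs.append(bacc(_confusion(y_tr[va], pred, classes)))

    chain = _fit_chain(tr_idx)
    confusion = _confusion(labels[te_idx], _predict(chain, te_idx), classes)
    return ClassifierReport(
        confusion=confusion,
        classes=[str(c) for c in classes],
        fold_baccs=fold_baccs,
        test_bacc=bacc(confusion),
        seed=seed,
        class_pair=(str(classes[0]), str(classes[1])),
        group_aware=groups is not None,
    )
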