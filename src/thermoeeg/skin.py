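"""Robot-skin temperature-level classification and withdrawal policy.

A robot-skin patch with two temperature cells sampled at 250 Hz touches an
object for 3 s; seven time-domain features per sensor channel (mean absolute
value, root mean square, variance, simple square integral, slope sign
changes, waveform length, Willison amplitude) feed one of five classifiers
(KNN, SVM, NB, LDA, QLDA) that predicts the object's temperature bin:

    very cold [10, 14.99], cold [16, 24.99], warm [25, 33],
    hot [35, 40], very hot [40.99, 44.99]  (degrees Celsius).

The predicted bin's intensity group maps onto a withdrawal speed:
NOX -> fast, MOD -> slow, INNO -> delayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .classification import ClassifierReport, _confusion, bacc_multiclass
from .conditions import CONDITIONS, ORDER_COLD_TO_HOT, ConditionLabel, Group

SKIN_FS = 250.0

FEATURE_NAMES = ["MAV", "RMS", "VAR", "SSI", "SSC", "WL", "WA"]

#: Temperature bins in cold -> hot order: (condition name, low, high) in C.
TEMP_BINS: List[Tuple[str, float, float]] = [
    (name, *CONDITIONS[name].temp_range_c) for name in ORDER_COLD_TO_HOT
]


@dataclass
class SkinProfile:
    """Two-sensor skin temperature time series at 250 Hz.

    ``data`` is (2, n_samples) in degrees Celsius; ``label`` is the true
    temperature bin of the touched object when known.
    """

    data: np.ndarray
    fs: float = SKIN_FS
    label: Optional[str] = None
    object_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise ValueError("skin profile must be (2 sensors) x samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        return pd.DataFrame(
            {"time_s": t, "sensor1_c": self.data[0], "sensor2_c": self.data[1],
             "label": self.label or ""}
        )


def _channel_features(x: np.ndarray, ssc_threshold: float, wa_threshold: float):
    x = np.asarray(x, dtype=float)
    n = len(x)
    diff = np.diff(x)
    mav = np.abs(x).mean()
    rms = np.sqrt((x**2).mean())
    var = ((x - x.mean()) ** 2).mean()
    ssi = (x**2).sum()
    # slope sign change: consecutive differences of opposite sign, both
    # exceeding the noise threshold in magnitude
    ssc = int(
        np.sum(
            (diff[:-1] * diff[1:] < 0)
            & (np.abs(diff[:-1]) > ssc_threshold)
            & (np.abs(diff[1:]) > ssc_threshold)
        )
    )
    wl = np.abs(diff).sum()
    wa = int(np.sum(np.abs(diff) > wa_threshold))
    return {
        "MAV": float(mav), "RMS": float(rms), "VAR": float(var),
        "SSI": float(ssi), "SSC": float(ssc), "WL": float(wl), "WA": float(wa),
    }


def extract_features(
    window: np.ndarray,
    ssc_threshold: float = 0.01,
    wa_threshold: float = 0.01,
) -> Dict[str, float]:
    """Seven time-domain features per sensor channel of a 3-s contact window.

    MAV = mean(|x_i|); VAR = mean((x_i - mean(x))^2); RMS, SSI (sum of
    squares), SSC and WA (counts above the 0.01 C noise threshold), and WL
    (summed absolute first differences) follow the standard time-domain
    definitions. For multichannel input, keys are suffixed ``_1``, ``_2``.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    if window.ndim == 1:
        return _channel_features(window, ssc_threshold, wa_threshold)
    out: Dict[str, float] = {}
    for c in range(window.shape[0]):
        feats = _channel_features(window[c], ssc_threshold, wa_threshold)
        out.update({f"{k}_{c + 1}": v for k, v in feats.items()})
    return out


def feature_table(
    profiles: Sequence[SkinProfile],
    window_s: float = 3.0,
    ssc_threshold: float = 0.01,
    wa_threshold: float = 0.01,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix over the first ``window_s`` seconds of each profile."""
    rows, labels = [], []
    for p in profiles:
        n = int(round(window_s * p.fs))
        if n > p.n_samples:
            raise ValueError(
                f"profile shorter ({p.duration_s} s) than window {window_s} s"
            )
        rows.append(extract_features(p.data[:, :n], ssc_threshold, wa_threshold))
        labels.append(p.label)
    return pd.DataFrame(rows), np.asarray(labels)


_CLASSIFIERS = {
    "KNN": lambda seed: KNeighborsClassifier(n_neighbors=5),
    "SVM": lambda seed: SVC(kernel="rbf", random_state=seed),
    "NB": lambda seed: GaussianNB(),
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
    "QLDA": lambda seed: QuadraticDiscriminantAnalysis(reg_param=0.5),
}


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def select_features(
    features: pd.DataFrame,
    labels: Sequence[str],
    k: int,
    seed: int = 0,
    cv_folds: int = 5,
) -> List[str]:
    """Sequential forward selection maximizing cross-validated mean recall.

    Greedily adds the feature column that most improves the ``cv_folds``-fold
    cross-validated balanced (mean per-class recall) accuracy of an LDA
    classifier; returns the ``k`` selected column names in selection order.
    Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 classes")
    cols = list(features.columns)
    if not 1 <= k <= len(cols):
        raise ValueError(f"k={k} outside [1, {len(cols)}]")
    x_all = features.to_numpy(dtype=float)
    classes = sorted(set(labels.tolist()))

    def cv_score(col_idx: List[int]) -> float:
        x = x_all[:, col_idx]
        skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
        scores = []
        for tr, va in skf.split(x, labels):
            xtr, xva = _standardize(x[tr], x[va])
            lda = LinearDiscriminantAnalysis().fit(xtr, labels[tr])
            conf = _confusion(labels[va], lda.predict(xva), classes)
            totals = conf.sum(axis=1)
            recalls = [conf[i, i] / t for i, t in enumerate(totals) if t > 0]
            scores.append(float(np.mean(recalls)))
        return float(np.mean(scores))

    selected: List[int] = []
    remaining = list(range(len(cols)))
    for _ in range(k):
        best_idx, best_score = None, -np.inf
        for j in remaining:   # ties resolved by column order: deterministic
            s = cv_score(selected + [j])
            if s > best_score + 1e-12:
                best_idx, best_score = j, s
        selected.append(best_idx)
        remaining.remove(best_idx)
    return [cols[j] for j in selected]


def train_temp_classifier(
    profiles: Sequence[SkinProfile],
    classifier: str = "QLDA",
    seed: int = 0,
    window_s: float = 3.0,
    features: Optional[Sequence[str]] = None,
    split_fraction: float = 0.8,
):
    """Train a five-bin temperature classifier on labelled skin profiles.

    80/20 stratified split; features are standardized on the training
    portion. Returns ``(fitted model, ClassifierReport)`` where the report
    carries the multi-class confusion matrix and the mean per-class recall
    as its balanced-accuracy score.
    """
    if classifier not in _CLASSIFIERS:
        raise ValueError(
            f"unknown classifier {classifier!r}; options: {sorted(_CLASSIFIERS)}"
        )
    table, labels = feature_table(profiles, window_s=window_s)
    if features is not None:
        table = table[list(features)]
    classes = sorted(set(labels.tolist()))
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 5:
        raise ValueError(f"need >= 5 profiles per class; got {counts}")
    x = table.to_numpy(dtype=float)
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx, test_size=1 - split_fraction, random_state=seed, stratify=labels
    )
    xtr, xte = _standardize(x[tr], x[te])
    model = _CLASSIFIERS[classifier](seed)
    model.fit(xtr, labels[tr])
    conf = _confusion(labels[te], model.predict(xte), classes)
    return model, ClassifierReport(
        confusion=conf,
        classes=[str(c) for c in classes],
        fold_baccs=[],
        test_bacc=bacc_multiclass(conf),
        seed=seed,
    )


def temp_to_class(
    temp_c: float, gap_policy: str = "nearest"
) -> Optional[ConditionLabel]:
    """Map a temperature to its five-bin condition label.

    Temperatures falling in the gaps between printed bins (and beyond the
    outermost bins) are assigned to the nearest bin boundary under the
    default ``gap_policy="nearest"``; ``gap_policy="unresolved"`` returns
    ``None`` for them instead.
    """
    if not np.isfinite(temp_c):
        raise ValueError(f"temperature must be finite, got {temp_c}")
    for name, low, high in TEMP_BINS:
        if low <= temp_c <= high:
            return CONDITIONS[name]
    if gap_policy == "unresolved":
        return None
    if gap_policy != "nearest":
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    dists = [
        (min(abs(temp_c - low), abs(temp_c - high)), i)
        for i, (_, low, high) in enumerate(TEMP_BINS)
    ]
    _, i = min(dists)
    return CONDITIONS[TEMP_BINS[i][0]]


def in_gap(temp_c: float) -> bool:
    """True when ``temp_c`` falls outside every printed temperature bin."""
    return temp_to_class(temp_c, gap_policy="unresolved") is None


WITHDRAWAL_SPEEDS = {Group.NOX: "fast", Group.MOD: "slow", Group.INNO: "delayed"}


def withdrawal_policy(group: Group) -> str:
    """Withdrawal speed for an intensity group: NOX fast, MOD slow, INNO delayed."""
    try:
        group = Group(group)
    except ValueError:
        raise ValueError(
            f"unknown group {group!r}; options: {[g.value for g in Group]}"
        ) from None
    return WITHDRAWAL_SPEEDS[group]
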