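"""Heartbeat feature extraction and SVM/MLP classification.

Each usable heartbeat becomes one row of a feature matrix.  Candidate
features per beat: the first ``p`` autoregressive coefficients of the beat
segment (AR(p) model ``x(n) = sum_i a(i) x(n-i) + e(n)``, Burg estimate,
p = 4 by default), the PR and RT intervals derived from the detected P/R/T
peaks, patient age and sex, and optionally 32 level-4 db4 approximation
coefficients of the beat segment.  Named feature sets mirror the classifier
comparisons the detector supports:

    AR                  4 cols   a1..a4
    PR+RT+Age+Sex       4 cols   pr, rt, age, sex
    AR+PR+RT            6 cols
    AR+PR+RT+Age+Sex    8 cols
    AR+DWT+PR+RT+Age+Sex 40 cols (adds f1..f32)

Classification uses an RBF-kernel SVM (C = 65536, gamma = 2.44e-4) or an
MLP (one hidden layer of 32 units), a stratified 70/30 train/test split,
and z-score standardization fitted on the training split only.  Metrics:
overall accuracy, per-class precision/recall/F1 and the confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import pywt
from scipy.signal import resample_poly
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.regression.linear_model import burg

from .io import ECGRecord, PeakAnnotations

logger = logging.getLogger("ecgfusion")

__all__ = [
    "ARModel", "ClassifierSpec", "ClassificationReport", "FEATURE_SETS",
    "fit_ar", "beat_intervals", "beat_segment", "build_feature_matrix",
    "train_test_split_70_30", "train_classifier", "evaluate_classifier",
    "resample_record",
]

#: named feature sets -> ordered column groups
FEATURE_SETS = {
    "AR": ("ar",),
    "PR+RT+Age+Sex": ("intervals", "demographics"),
    "AR+PR+RT": ("ar", "intervals"),
    "AR+PR+RT+Age+Sex": ("ar", "intervals", "demographics"),
    "AR+DWT+PR+RT+Age+Sex": ("ar", "dwt", "intervals", "demographics"),
}

#: beat segment bounds relative to the R peak, seconds (covers one beat at
#: any studied sampling rate)
SEGMENT_BEFORE = 0.25
SEGMENT_AFTER = 0.45

N_DWT_COEFFS = 32


@dataclass(frozen=True)
class ARModel:
    """Fitted AR(p) model: coefficients a(1..p) and innovation variance."""
    order: int
    coefficients: np.ndarray
    noise_variance: float

    def __post_init__(self):
        if len(self.coefficients) != self.order:
            raise ValueError("order must equal the number of coefficients")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")


@dataclass(frozen=True)
class ClassifierSpec:
    """SVM or MLP hyperparameters.

    SVM defaults follow the RBF-kernel working point C = 65536 and
    gamma = 1/(2 sigma^2) = 2.44e-4; the MLP default is a single hidden
    layer of 32 units trained for at most 500 iterations.
    """
    kind: str = "svm"  # "svm" | "mlp"
    C: float = 65536.0
    kernel_gamma: float = 2.44e-4
    hidden_layer_sizes: tuple = (32,)
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("svm", "mlp"):
            raise ValueError("kind must be 'svm' or 'mlp'")
        if self.C <= 0 or self.kernel_gamma <= 0:
            raise ValueError("C and kernel_gamma must be positive")


@dataclass
class ClassificationReport:
    """Overall accuracy (%) plus per-class precision/recall/F1 and the
    confusion matrix (rows = true class, columns = predicted)."""
    accuracy: float
    classes: list
    precision: dict
    recall: dict
    f1: dict
    confusion: np.ndarray

    def __str__(self) -> str:
        lines = [f"overall accuracy: {self.accuracy:.2f}%"]
        for c in self.classes:
            lines.append(f"  {c}: precision {self.precision[c]:.3f} "
                         f"recall {self.recall[c]:.3f} f1 {self.f1[c]:.3f}")
        return "\n".join(lines)


def fit_ar(beat_segment: np.ndarray, order: int = 4) -> ARModel:
    """Burg estimate of an AR(p) model for one beat segment.

    The series is demeaned before fitting.  Requires more than ``3 * order``
    samples and a non-constant segment.
    """
    x = np.asarray(beat_segment, dtype=float)
    if len(x) <= 3 * order:
        raise ValueError(f"segment of {len(x)} samples too short for AR({order})")
    if np.ptp(x) == 0:
        raise ValueError("constant segment has no AR structure")
    coeffs, sigma2 = burg(x, order=order, demean=True)
    return ARModel(order=order, coefficients=np.asarray(coeffs, dtype=float),
                   noise_variance=float(sigma2))


def beat_intervals(annotations: PeakAnnotations, fs: float) -> pd.DataFrame:
    """Per-beat PR and RT intervals in seconds.

    A beat is usable when its R peak has a P in the PR range before it and a
    T after it (nearest preceding P / following T).  Beats missing either
    are dropped and counted in the log.

    Returns a DataFrame with columns ``r_index``, ``pr_interval``,
    ``rt_interval``.
    """
    p, r, t = annotations.p_indices, annotations.r_indices, annotations.t_indices
    rows, dropped = [], 0
    for ri in r:
        pj = p[p < ri]
        tj = t[t > ri]
        if pj.size == 0 or tj.size == 0:
            dropped += 1
            continue
        pr = (ri - pj[-1]) / fs
        rt = (tj[0] - ri) / fs
        rows.append((int(ri), pr, rt))
    if dropped:
        logger.info("beat_intervals: dropped %d beat(s) without P or T", dropped)
    return pd.DataFrame(rows, columns=["r_index", "pr_interval", "rt_interval"])


def beat_segment(record: ECGRecord, r_index: int) -> np.ndarray:
    """Samples from 0.25 s before to 0.45 s after the R peak (clipped)."""
    lo = max(0, r_index - int(round(SEGMENT_BEFORE * record.fs)))
    hi = min(len(record), r_index + int(round(SEGMENT_AFTER * record.fs)) + 1)
    return record.samples[lo:hi]


def _dwt_features(segment: np.ndarray, wavelet: str = "db4",
                  level: int = 4, n: int = N_DWT_COEFFS) -> np.ndarray:
    coeffs = pywt.wavedec(segment, wavelet, mode="periodization", level=level)
    a = coeffs[0]
    out = np.zeros(n)
    out[: min(n, len(a))] = a[:n]
    return out


def build_feature_matrix(records, feature_set: str = "PR+RT+Age+Sex",
                         ar_order: int = 4):
    """Assemble the per-beat feature table for a list of annotated records.

    ``records`` is an iterable of ``(ECGRecord, PeakAnnotations, label)``
    triples; the label is the class assigned to every usable beat of that
    record.  Records lacking age/sex are skipped (with a log entry) when the
    feature set needs demographics.  Returns ``(DataFrame, labels)``; the
    column order is a1..ap | f1..f32 | pr, rt | age, sex, following the
    feature-set definition.  Sex is encoded M -> 0, F -> 1.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"choose from {sorted(FEATURE_SETS)}")
    groups = FEATURE_SETS[feature_set]
    rows, labels, skipped = [], [], 0
    for record, ann, label in records:
        if "demographics" in groups and (record.age is None or record.sex is None):
            skipped += 1
            continue
        intervals = beat_intervals(ann, record.fs)
        for _, beat in intervals.iterrows():
            row = {}
            ri = int(beat.r_index)
            if "ar" in groups or "dwt" in groups:
                seg = beat_segment(record, ri)
                if len(seg) <= 3 * ar_order or np.ptp(seg) == 0:
                    continue
                if "ar" in groups:
                    model = fit_ar(seg, ar_order)
                    row.update({f"a{i+1}": c
                                for i, c in enumerate(model.coefficients)})
                if "dwt" in groups:
                    row.update({f"f{i+1}": c
                                for i, c in enumerate(_dwt_features(seg))})
            if "intervals" in groups:
                row["pr"] = beat.pr_interval
                row["rt"] = beat.rt_interval
            if "demographics" in groups:
                row["age"] = float(record.age)
                row["sex"] = {"M": 0.0, "F": 1.0}[record.sex]
            rows.append(row)
            labels.append(label)
    if skipped:
        logger.warning("build_feature_matrix: skipped %d record(s) missing "
                       "age/sex", skipped)
    if not rows:
        logger.warning("build_feature_matrix: no usable beats")
        return pd.DataFrame(), np.asarray([], dtype=object)
    table = pd.DataFrame(rows)
    return table, np.asarray(labels, dtype=object)


def train_test_split_70_30(table: pd.DataFrame, labels, seed: int = 0):
    """Stratified 70/30 split, deterministic for a fixed seed.

    Returns ``(X_train, X_test, y_train, y_test)``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to split")
    return train_test_split(table, labels, test_size=0.30, random_state=seed,
                            stratify=labels)


def train_classifier(X_train, y_train, spec: ClassifierSpec | None = None):
    """Fit the classifier behind a train-fitted z-score standardizer."""
    spec = spec or ClassifierSpec()
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set has a single class")
    if spec.kind == "svm":
        model = SVC(C=spec.C, kernel="rbf", gamma=spec.kernel_gamma)
    else:
        model = MLPClassifier(hidden_layer_sizes=spec.hidden_layer_sizes,
                              max_iter=spec.max_iter, random_state=spec.seed)
    pipe = Pipeline([("scale", StandardScaler()), ("clf", model)])
    pipe.fit(np.asarray(X_train, dtype=float), y_train)
    return pipe


def evaluate_classifier(model, X_test, y_test) -> ClassificationReport:
    """Confusion matrix and the derived accuracy/precision/recall/F1."""
    y_test = np.asarray(y_test)
    y_pred = model.predict(np.asarray(X_test, dtype=float))
    classes = sorted(np.unique(np.concatenate([y_test, y_pred])).tolist())
    cm = confusion_matrix(y_test, y_pred, labels=classes)
    tp = np.diag(cm).astype(float)
    support_true = cm.sum(axis=1).astype(float)
    support_pred = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(support_pred > 0, tp / support_pred, 0.0)
        rec = np.where(support_true > 0, tp / support_true, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return ClassificationReport(
        accuracy=100.0 * tp.sum() / cm.sum(),
        classes=classes,
        precision=dict(zip(classes, prec)),
        recall=dict(zip(classes, rec)),
        f1=dict(zip(classes, f1)),
        confusion=cm,
    )


def resample_record(record: ECGRecord,
                    target_fs: float,
                    annotations: PeakAnnotations | None = None):
    """Band-limited resampling to ``target_fs`` (e.g. 128 Hz for
    cross-database work), rescaling any annotations with rounding.

    Returns the resampled record, or ``(record, annotations)`` when
    annotations are given.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    ratio = Fraction(target_fs / record.fs).limit_denominator(10000)
    if ratio == 1:
        out = record.with_samples(record.samples.copy())
    else:
        samples = resample_poly(record.samples, ratio.numerator,
                                ratio.denominator)
        out = ECGRecord(samples, target_fs, record_id=record.record_id,
                        lead=record.lead, age=record.age, sex=record.sex,
                        rhythm_label=record.rhythm_label)
    if annotations is None:
        return out
    scale = target_fs / record.fs
    rescaled = PeakAnnotations(
        p_indices=np.round(annotations.p_indices * scale).astype(int),
        r_indices=np.round(annotations.r_indices * scale).astype(int),
        t_indices=np.round(annotations.t_indices * scale).astype(int),
    )
    return out, rescaled
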