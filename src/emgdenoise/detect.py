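"""Corrupted-epoch gating: three time-domain features and a linear
maximum-margin classifier separating contaminated ("C-EEG") from clean
("NC-EEG") epochs.

Features are standardized to zero mean / unit variance before fitting, and
the standardization is stored with the model.  Decision scores exactly on
the boundary map to "C-EEG": attempting a correction on a clean epoch is the
cheaper mistake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import histogram_entropy
from .signal import as_samples
from .wavelet import subband_entropy

LABEL_CORRUPTED = "C-EEG"
LABEL_CLEAN = "NC-EEG"


class NotFittedError(RuntimeError):
    """Prediction requested from an unfitted classifier."""


@dataclass(frozen=True)
class FeatureVector:
    """variance (uV^2), non-normalized Shannon entropy, peak-to-peak (uV)."""

    variance: float
    shannon_entropy: float
    peak_to_peak: float

    def as_array(self) -> np.ndarray:
        return np.array([self.variance, self.shannon_entropy, self.peak_to_peak])


def extract_features(epoch, entropy: str = "energy") -> FeatureVector:
    """Population variance, Shannon entropy and max-min range.

    ``entropy="energy"`` uses the non-normalized energy entropy
    sum(x^2 * ln(x^2)) -- the same convention the wavelet-level selection
    uses, and the one under which corrupted epochs dominate clean ones.
    ``entropy="histogram"`` switches to a 64-bin amplitude-histogram
    estimator.
    """
    data = as_samples(epoch)
    if data.size == 0:
        raise ValueError("empty epoch")
    if entropy == "energy":
        ent = subband_entropy(data)
    elif entropy == "histogram":
        ent = histogram_entropy(data, bins=64)
    else:
        raise ValueError(f"unknown entropy estimator {entropy!r}")
    return FeatureVector(
        variance=float(np.var(data)),
        shannon_entropy=float(ent),
        peak_to_peak=float(np.max(data) - np.min(data)),
    )


def feature_matrix(epochs, entropy: str = "energy") -> np.ndarray:
    return np.vstack([extract_features(e, entropy).as_array() for e in epochs])


@dataclass
class ClassifierModel:
    """Standardizer + linear SVM with the boundary tie broken toward C-EEG."""

    entropy: str = "energy"
    _scaler: StandardScaler | None = field(default=None, repr=False)
    _svc: SVC | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self._svc is not None

    def fit(self, epochs, labels) -> "ClassifierModel":
        labels = np.asarray(labels)
        classes = set(labels)
        if classes != {LABEL_CORRUPTED, LABEL_CLEAN}:
            raise ValueError(
                f"training set must contain both {LABEL_CORRUPTED} and "
                f"{LABEL_CLEAN}, got {sorted(classes)}"
            )
        X = feature_matrix(epochs, self.entropy)
        self._scaler = StandardScaler().fit(X)
        self._svc = SVC(kernel="linear", C=1.0).fit(
            self._scaler.transform(X), labels
        )
        return self

    def decision_scores(self, epochs) -> np.ndarray:
        """Signed distances; positive means clean (NC-EEG)."""
        if not self.is_fitted:
            raise NotFittedError("classifier has not been fitted")
        X = self._scaler.transform(feature_matrix(epochs, self.entropy))
        scores = self._svc.decision_function(X)
        # sklearn orients the score toward classes_[1]; force NC-EEG positive
        if self._svc.classes_[1] != LABEL_CLEAN:
            scores = -scores
        return scores

    def predict(self, epochs) -> np.ndarray:
        scores = self.decision_scores(epochs)
        return np.where(scores > 0, LABEL_CLEAN, LABEL_CORRUPTED)


def classify_epoch(model: ClassifierModel, epoch) -> str:
    """Label a single epoch as C-EEG or NC-EEG."""
    return str(model.predict([epoch])[0])


def _rates(y_true, y_pred) -> dict:
    """Sensitivity/specificity/accuracy with C-EEG as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == LABEL_CORRUPTED) & (y_pred == LABEL_CORRUPTED)))
    tn = int(np.sum((y_true == LABEL_CLEAN) & (y_pred == LABEL_CLEAN)))
    fp = int(np.sum((y_true == LABEL_CLEAN) & (y_pred == LABEL_CORRUPTED)))
    fn = int(np.sum((y_true == LABEL_CORRUPTED) & (y_pred == LABEL_CLEAN)))
    n = tp + tn + fp + fn
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / n if n else float("nan"),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


@dataclass
class CVReport:
    folds: list[dict]
    held_out: dict
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "held_out": self.held_out,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def train_classifier(
    epochs,
    labels,
    split: float = 0.8,
    folds: int = 10,
    seed: int = 0,
    entropy: str = "energy",
) -> tuple[ClassifierModel, CVReport]:
    """Fit on a stratified ``split`` of the data, report k-fold
    cross-validation on the training part and rates on the held-out part."""
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("training requires examples of both classes")
    if not (0 < split < 1):
        raise ValueError("split must be in (0, 1)")
    epochs = list(epochs)
    idx = np.arange(len(epochs))
    idx_train, idx_test = train_test_split(
        idx, train_size=split, stratify=labels, random_state=seed
    )
    train_epochs = [epochs[i] for i in idx_train]
    train_labels = labels[idx_train]

    fold_reports = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fit_idx, val_idx in skf.split(np.zeros(len(train_epochs)), train_labels):
        fold_model = ClassifierModel(entropy).fit(
            [train_epochs[i] for i in fit_idx], train_labels[fit_idx]
        )
        pred = fold_model.predict([train_epochs[i] for i in val_idx])
        fold_reports.append(_rates(train_labels[val_idx], pred))

    model = ClassifierModel(entropy).fit(train_epochs, train_labels)
    held_out = _rates(labels[idx_test], model.predict([epochs[i] for i in idx_test]))
    report = CVReport(
        folds=fold_reports,
        held_out=held_out,
        n_train=len(idx_train),
        n_test=len(idx_test),
    )
    return model, report
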