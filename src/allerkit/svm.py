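"""SVM classification on amino-acid composition features.

A protein is represented by its 20-dimensional amino-acid composition — the
fraction of each residue, count(i) / length, in the fixed alphabetical order
``ACDEFGHIKLMNPQRSTVWY`` — and an SVM with probability calibration separates
allergens from non-allergens in that space. Composition is permutation
invariant: shuffled or reversed variants of a sequence map to the same
feature vector, a documented blind spot of this feature set against
reversed-sequence negatives.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .alphabet import AA_ORDER, encode
from .records import Label, ProteinRecord, SequenceDataset, Verdict

#: Fingerprint of the feature ordering baked into every trained model.
FEATURE_FINGERPRINT = hashlib.sha256(AA_ORDER.encode()).hexdigest()[:16]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SvmParams:
    """SVM hyperparameters; defaults are standard LIBSVM-style settings."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    probability_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if not 0 <= self.probability_threshold <= 1:
            raise ValueError("probability_threshold must be in [0, 1]")


def composition(rec: ProteinRecord) -> np.ndarray:
    """Amino-acid composition vector: fraction of each residue (sums to 1)."""
    if not rec.sequence:
        raise ValueError(f"record {rec.id!r}: empty sequence has no composition")
    counts = np.bincount(encode(rec.sequence), minlength=20)
    return counts / counts.sum()


def dataset_features(ds: SequenceDataset) -> tuple[np.ndarray, np.ndarray]:
    """Composition matrix (n, 20) and 0/1 label vector (1 = allergen)."""
    X = np.stack([composition(rec) for rec in ds])
    y = np.array([1 if rec.label is Label.ALLERGEN else 0 for rec in ds])
    return X, y


@dataclass
class SvmModel:
    """A trained composition SVM with its parameter snapshot."""

    classifier: SVC
    params: SvmParams
    class_counts: dict[str, int]
    fingerprint: str = FEATURE_FINGERPRINT

    def probabilities(self, ds: SequenceDataset) -> np.ndarray:
        """P(allergen) per record."""
        if self.fingerprint != FEATURE_FINGERPRINT:
            raise ValueError("feature-order fingerprint mismatch; model is incompatible")
        X = np.stack([composition(rec) for rec in ds])
        proba = self.classifier.predict_proba(X)
        allergen_col = int(np.where(self.classifier.classes_ == 1)[0][0])
        return proba[:, allergen_col]

    def decision_values(self, ds: SequenceDataset) -> np.ndarray:
        """Uncalibrated margin distances (positive = allergen side)."""
        X = np.stack([composition(rec) for rec in ds])
        return self.classifier.decision_function(X)


def svm_train(ds: SequenceDataset, params: SvmParams | None = None) -> SvmModel:
    """Train a probability-calibrated SVM on composition features.

    Requires both classes among the labeled records; deterministic for a
    fixed seed (the seed drives the internal Platt-calibration CV).
    """
    params = params or SvmParams()
    labeled = SequenceDataset(
        [r for r in ds if r.label in (Label.ALLERGEN, Label.NON_ALLERGEN)], provenance=ds.provenance
    )
    X, y = dataset_features(labeled)
    classes = set(y.tolist())
    if classes != {0, 1}:
        raise ValueError(f"training needs both classes, got labels {sorted(classes)}")
    clf = SVC(
        kernel=params.kernel,
        C=params.C,
        gamma=params.gamma,
        probability=True,
        random_state=params.seed,
    )
    with warnings.catch_warnings():
        # the pinned sklearn still supports Platt calibration via
        # probability=True; silence its forward-deprecation notice
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        clf.fit(X, y)
    counts = {"allergen": int(y.sum()), "non_allergen": int(len(y) - y.sum())}
    return SvmModel(classifier=clf, params=params, class_counts=counts)


def svm_predict(model: SvmModel, queries: SequenceDataset) -> list[Verdict]:
    """Per query: allergen probability and verdict at the probability threshold."""
    probs = model.probabilities(queries)
    threshold = model.params.probability_threshold
    return [
        Verdict(rec.id, "svm", bool(p >= threshold), [], score=float(p))
        for rec, p in zip(queries, probs)
    ]


def save_model(model: SvmModel, path) -> None:
    """Serialize a model (format-versioned pickle with params and fingerprint)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "fingerprint": model.fingerprint,
        "params": model.params,
        "class_counts": model.class_counts,
        "classifier": model.classifier,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> SvmModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')}")
    if payload["fingerprint"] != FEATURE_FINGERPRINT:
        raise ValueError("feature-order fingerprint mismatch; refusing to load")
    return SvmModel(
        classifier=payload["classifier"],
        params=payload["params"],
        class_counts=payload["class_counts"],
        fingerprint=payload["fingerprint"],
    )
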