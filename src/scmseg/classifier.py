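"""Object-level false-positive removal with a small feed-forward classifier.

Each segmented object is summarised by an 8-dimensional feature vector —
area, eccentricity, extent, solidity, and mean/standard deviation of
intensity over the object (foreground) and over a tight peripheral
background ring. A one-hidden-layer neural network trained on labeled
objects (true nucleus vs. artifact) then prunes objects that are likely
false positives from the segmentation mask.

Labeled objects are split 70/15/15 into training, validation and test
sets; training stops early when the validation score stops improving, and
the held-out test accuracy is recorded as the generalisation estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .config import ClassifierConfig
from .errors import DataError, NotTrainedError, ShapeMismatchError
from .pipeline import _relabel_sequential

__all__ = [
    "FEATURE_NAMES",
    "TrainedClassifier",
    "extract_features",
    "train_classifier",
    "filter_objects",
    "save_model",
    "load_model",
]

#: Fixed order of the 8 per-object features.
FEATURE_NAMES = (
    "area",
    "eccentricity",
    "extent",
    "solidity",
    "fg_mean",
    "fg_std",
    "bg_mean",
    "bg_std",
)

#: Dilation distance (in 8-connected steps) defining the background ring.
_RING_STEPS = 3


@dataclass
class TrainedClassifier:
    """A trained object classifier with its training metadata."""

    scaler: StandardScaler
    network: MLPClassifier
    seed: int
    n_train: int
    n_val: int
    n_test: int
    validation_accuracy: float
    test_accuracy: float
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Posterior probability of being a true nucleus, per object."""
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != len(FEATURE_NAMES):
            raise DataError(
                f"expected {len(FEATURE_NAMES)} features, "
                f"got {features.shape[1]}"
            )
        scaled = self.scaler.transform(features)
        proba = self.network.predict_proba(scaled)
        positive = list(self.network.classes_).index(True)
        return proba[:, positive]

    def predict(self, features: np.ndarray,
                threshold: float | None = None) -> np.ndarray:
        """Boolean keep/discard decision per object.

        ``threshold`` defaults to the config's ``decision_threshold``.
        """
        if threshold is None:
            threshold = self.config.decision_threshold
        return self.predict_proba(features) >= threshold


def extract_features(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Per-object feature matrix, one row per label in ascending order.

    The background ring of an object consists of pixels within
    ``_RING_STEPS`` 8-connected dilation steps of its footprint, excluding
    the pixels of *all* objects (so a neighbouring nucleus never leaks into
    another object's background statistics). An object completely walled in
    by other objects gets zero background statistics.

    Degenerate shapes follow region-properties conventions: a single pixel
    has eccentricity 0, extent 1, solidity 1; collinear pixels have
    eccentricity 1.
    """
    mask = np.asarray(mask)
    image = np.asarray(image, dtype=np.float64)
    if mask.shape != image.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} != image shape {image.shape}"
        )
    regions = regionprops(mask, intensity_image=image)
    if not regions:
        return np.empty((0, len(FEATURE_NAMES)), dtype=np.float64)

    any_object = mask > 0
    struct = np.ones((3, 3), dtype=bool)
    rows = np.empty((len(regions), len(FEATURE_NAMES)), dtype=np.float64)
    pad = _RING_STEPS
    for i, reg in enumerate(regions):
        r0, c0, r1, c1 = reg.bbox
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p = min(r1 + pad, mask.shape[0])
        c1p = min(c1 + pad, mask.shape[1])
        crop_obj = mask[r0p:r1p, c0p:c1p] == reg.label
        ring = ndi.binary_dilation(crop_obj, structure=struct,
                                   iterations=_RING_STEPS)
        ring &= ~any_object[r0p:r1p, c0p:c1p]
        ring_vals = image[r0p:r1p, c0p:c1p][ring]
        bg_mean = float(ring_vals.mean()) if ring_vals.size else 0.0
        bg_std = float(ring_vals.std()) if ring_vals.size else 0.0
        fg_vals = image[r0p:r1p, c0p:c1p][crop_obj]
        solidity = float(reg.solidity)
        if not np.isfinite(solidity):
            solidity = 1.0
        rows[i] = (
            float(reg.area),
            float(reg.eccentricity),
            float(reg.extent),
            float(solidity),
            float(fg_vals.mean()),
            float(fg_vals.std()),
            bg_mean,
            bg_std,
        )
    return rows


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Train the object classifier on labeled feature vectors.

    Splits the objects 70/15/15 (stratified by class, seeded) into
    training, validation and test sets. The network — one hidden layer of
    ``config.hidden_units`` logistic-output units — is fit on the training
    set with early stopping monitored on the validation set; the untouched
    test set yields the reported generalisation accuracy. Features are
    standardized with statistics of the training portion only.
    """
    config = config or ClassifierConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise DataError(
            f"features must be (n, {len(FEATURE_NAMES)}), got {X.shape}"
        )
    if X.shape[0] != y.shape[0]:
        raise ShapeMismatchError("features and labels lengths differ")
    if X.shape[0] < 20:
        raise DataError(
            f"need at least 20 labeled objects, got {X.shape[0]}"
        )
    if np.unique(y).size < 2:
        raise DataError("labels contain a single class; need both classes")

    X_fit, X_test, y_fit, y_test = train_test_split(
        X, y, test_size=config.test_fraction, stratify=y, random_state=seed
    )
    # Early-stopping validation is carved out of the fit portion so the
    # overall split matches train/val/test fractions.
    val_of_fit = config.val_fraction / (1.0 - config.test_fraction)
    network = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        solver="adam",
        early_stopping=True,
        validation_fraction=val_of_fit,
        n_iter_no_change=config.patience,
        max_iter=config.max_epochs,
        random_state=seed,
    )
    scaler = StandardScaler().fit(X_fit)
    import warnings

    with warnings.catch_warnings():
        # Convergence at max_epochs is acceptable; early stopping governs.
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        network.fit(scaler.transform(X_fit), y_fit)

    n_test = X_test.shape[0]
    n_val = int(np.ceil(X_fit.shape[0] * val_of_fit))
    n_train = X_fit.shape[0] - n_val
    test_acc = float(network.score(scaler.transform(X_test), y_test))
    val_acc = float(network.best_validation_score_)
    return TrainedClassifier(
        scaler=scaler,
        network=network,
        seed=seed,
        n_train=n_train,
        n_val=n_val,
        n_test=n_test,
        validation_accuracy=val_acc,
        test_accuracy=test_acc,
        config=config,
    )


def filter_objects(clf: TrainedClassifier, mask: np.ndarray,
                   image: np.ndarray) -> np.ndarray:
    """Remove objects the classifier rejects; relabel survivors 1..n.

    Never creates pixels: the surviving object pixel set is a subset of the
    input mask's. An empty mask passes through unchanged.
    """
    if not isinstance(clf, TrainedClassifier):
        raise NotTrainedError("filter_objects requires a TrainedClassifier")
    mask = np.asarray(mask)
    feats = extract_features(mask, image)
    if feats.shape[0] == 0:
        return np.zeros_like(mask, dtype=np.int32)
    keep = clf.predict(feats)
    present = np.unique(mask)
    present = present[present > 0]
    drop = present[~keep]
    out = mask.astype(np.int32, copy=True)
    if drop.size:
        out[np.isin(out, drop)] = 0
    return _relabel_sequential(out)


def save_model(clf: TrainedClassifier, path: str | Path) -> None:
    """Serialize a trained classifier to one portable JSON file.

    The file holds a metadata header plus the scaler statistics and
    network weights as nested lists; :func:`load_model` restores an
    equivalent classifier without refitting.
    """
    payload = {
        "format": "scmseg-object-classifier",
        "version": 1,
        "feature_names": list(FEATURE_NAMES),
        "seed": clf.seed,
        "splits": {"train": clf.n_train, "val": clf.n_val,
                   "test": clf.n_test},
        "validation_accuracy": clf.validation_accuracy,
        "test_accuracy": clf.test_accuracy,
        "config": {
            "hidden_units": clf.config.hidden_units,
            "train_fraction": clf.config.train_fraction,
            "val_fraction": clf.config.val_fraction,
            "test_fraction": clf.config.test_fraction,
            "patience": clf.config.patience,
            "max_epochs": clf.config.max_epochs,
            "decision_threshold": clf.config.decision_threshold,
        },
        "scaler": {
            "mean": clf.scaler.mean_.tolist(),
            "scale": clf.scaler.scale_.tolist(),
        },
        "network": {
            "coefs": [w.tolist() for w in clf.network.coefs_],
            "intercepts": [b.tolist() for b in clf.network.intercepts_],
            "classes": [int(c) for c in clf.network.classes_],
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedClassifier:
    """Restore a classifier saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "scmseg-object-classifier":
        raise DataError(f"{path} is not a scmseg classifier file")
    cfg = ClassifierConfig(**payload["config"])
    scaler = StandardScaler()
    scaler.mean_ = np.asarray(payload["scaler"]["mean"], dtype=np.float64)
    scaler.scale_ = np.asarray(payload["scaler"]["scale"], dtype=np.float64)
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = scaler.mean_.size

    network = MLPClassifier(hidden_layer_sizes=(cfg.hidden_units,),
                            activation="logistic")
    network.coefs_ = [np.asarray(w, dtype=np.float64)
                      for w in payload["network"]["coefs"]]
    network.intercepts_ = [np.asarray(b, dtype=np.float64)
                           for b in payload["network"]["intercepts"]]
    network.n_layers_ = len(network.coefs_) + 1
    network.n_outputs_ = network.coefs_[-1].shape[1]
    network.out_activation_ = "logistic"
    network.classes_ = np.asarray(payload["network"]["classes"])
    network.n_features_in_ = network.coefs_[0].shape[0]
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(network.classes_)
    network._label_binarizer = lb

    splits = payload["splits"]
    return TrainedClassifier(
        scaler=scaler,
        network=network,
        seed=int(payload["seed"]),
        n_train=int(splits["train"]),
        n_val=int(splits["val"]),
        n_test=int(splits["test"]),
        validation_accuracy=float(payload["validation_accuracy"]),
        test_accuracy=float(payload["test_accuracy"]),
        config=cfg,
    )
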