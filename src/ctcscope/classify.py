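"""Binary CTC/WBC classifier on normalized single-cell crops.

The reference recipe is transfer learning: an ImageNet-pretrained ResNet-50
backbone used as a frozen feature extractor, followed by a trainable head
(fully connected + ReLU, dropout 0.6, 2-way softmax), cross-entropy loss,
Adam at 1e-4, minibatches of 16, on 34x34 inputs resized from the 30x30
crops.  Because pretrained weights require a deep-learning framework and a
weight download, the package also provides a small scratch CNN backbone
(3 conv blocks + pooling) with the identical head and training loop that
trains in CPU-minutes; it is the default and the one exercised by the test
suite.  Requesting ``pretrained-resnet50`` without torch/torchvision and
cached weights raises :class:`BackboneUnavailableError`.

Class order is fixed as ``[WBC, CTC]`` everywhere; probability ties resolve
to WBC (the non-rare class) to minimize false CTC calls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, ScratchCNN, cross_entropy
from .dataset import CellCrop
from .errors import (BackboneUnavailableError, ClassCoverageError,
                     LeakageError, ParameterError)
from .synthgen import CTC, WBC

CLASS_ORDER = (WBC, CTC)

SCRATCH_BACKBONE = "small-scratch-cnn"
RESNET_BACKBONE = "pretrained-resnet50"


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference recipe where
    it states them; head width, epoch budget and early stopping are package
    choices)."""

    input_side: int = 34
    backbone: str = SCRATCH_BACKBONE
    freeze_backbone: bool = False
    head_hidden_units: int = 256
    dropout_rate: float = 0.6
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.backbone not in (SCRATCH_BACKBONE, RESNET_BACKBONE):
            raise ParameterError(f"unknown backbone {self.backbone!r}")


@dataclass
class TrainedModel:
    """A trained network plus its config echo and learning history."""

    network: ScratchCNN
    config: TrainConfig
    history: dict = field(default_factory=dict)
    class_order: tuple = CLASS_ORDER


def prepare_input(pixels: np.ndarray, side: int) -> np.ndarray:
    """Bilinear-resize a crop to the model's input side (no-op if equal)."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape == (side, side):
        return pixels
    return resize(pixels, (side, side), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def build_model(config: TrainConfig) -> ScratchCNN:
    """Construct the untrained network for the configured backbone."""
    if config.backbone == RESNET_BACKBONE:
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise BackboneUnavailableError(
                "pretrained-resnet50 requires torch/torchvision and a cached "
                "ImageNet weight file, neither of which is available here; "
                f"use backbone='{SCRATCH_BACKBONE}' instead") from exc
        raise BackboneUnavailableError(
            "pretrained-resnet50 weights are not bundled; "
            f"use backbone='{SCRATCH_BACKBONE}'")
    return ScratchCNN(input_side=config.input_side,
                      hidden=config.head_hidden_units,
                      dropout_rate=config.dropout_rate,
                      seed=config.seed,
                      freeze_backbone=config.freeze_backbone)


def _crops_to_arrays(crops: list[CellCrop], side: int):
    X = np.stack([prepare_input(c.pixels, side) for c in crops])
    labels = [c.label for c in crops]
    if any(lab not in CLASS_ORDER for lab in labels):
        raise ClassCoverageError("all crops must be labeled WBC or CTC")
    y = np.array([CLASS_ORDER.index(lab) for lab in labels])
    return X, y


def _fit_arrays(network: ScratchCNN, X_tr, y_tr, X_val, y_val,
                config: TrainConfig) -> dict:
    """Shared training loop: Adam + minibatches + best-val-loss early stop."""
    if len(np.unique(y_tr)) < 2:
        raise ClassCoverageError("training set must contain both classes")
    if len(X_val) == 0:
        raise ParameterError("validation set must be nonempty")
    opt = Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best = (np.inf, network.get_state(), 0)
    n = len(X_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, acc = network.train_step(X_tr[idx], y_tr[idx], opt, rng)
            losses.append(loss)
            accs.append(acc)
        vp = network.predict_proba(X_val)
        v_loss = cross_entropy(vp, y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float(np.mean(accs)))
        history["val_loss"].append(v_loss)
        history["val_acc"].append(float((vp.argmax(axis=1) == y_val).mean()))
        if v_loss < best[0] - 1e-9:
            best = (v_loss, network.get_state(), epoch)
        elif epoch - best[2] >= config.patience:
            break
    network.set_state(best[1])
    history["best_epoch"] = best[2]
    return history


def train(model: ScratchCNN, train_crops: list[CellCrop],
          val_crops: list[CellCrop], config: TrainConfig) -> TrainedModel:
    """Train on labeled crops with a leakage guard.

    Train and validation sets must be disjoint by ``origin_id`` — an
    augmented copy of a validation cell appearing in training would leak a
    near-duplicate across the boundary.
    """
    tr_origins = {c.origin_id for c in train_crops}
    val_origins = {c.origin_id for c in val_crops}
    shared = tr_origins & val_origins
    if shared:
        raise LeakageError(
            f"{len(shared)} origin(s) shared between train and validation, "
            f"e.g. {sorted(shared)[:3]}")
    if not val_crops:
        raise ParameterError("validation set must be nonempty")
    X_tr, y_tr = _crops_to_arrays(train_crops, config.input_side)
    X_val, y_val = _crops_to_arrays(val_crops, config.input_side)
    history = _fit_arrays(model, X_tr, y_tr, X_val, y_val, config)
    return TrainedModel(network=model, config=config, history=history)


def predict(model: TrainedModel, crops: list[CellCrop]):
    """Class probabilities and argmax labels for crops (dropout disabled).

    Returns ``(probs, labels)`` with probs columns in ``CLASS_ORDER`` and a
    tie resolving to WBC.
    """
    if not crops:
        return np.zeros((0, 2)), []
    X = np.stack([prepare_input(c.pixels, model.config.input_side)
                  for c in crops])
    probs = model.network.predict_proba(X)
    labels = [CLASS_ORDER[i] for i in probs.argmax(axis=1)]
    return probs, labels


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Checkpoint = npz of parameters + JSON sidecar (config, history)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             *[p for p in model.network.get_state()])
    sidecar = {"config": asdict(model.config), "history": model.history,
               "class_order": list(model.class_order)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = TrainConfig(**sidecar["config"])
    network = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        network.set_state([data[k] for k in data.files])
    return TrainedModel(network=network, config=config,
                        history=sidecar["history"],
                        class_order=tuple(sidecar["class_order"]))


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn estimator facade over the scratch CNN.

    ``X`` may be ``(n, side, side)`` images or flattened ``(n, side*side)``
    rows (pipeline-friendly); ``y`` is any pair of labels.  A stratified
    ``validation_fraction`` split drives early stopping.
    """

    def __init__(self, input_side: int = 34, backbone: str = SCRATCH_BACKBONE,
                 freeze_backbone: bool = False, head_hidden_units: int = 256,
                 dropout_rate: float = 0.6, learning_rate: float = 1e-4,
                 batch_size: int = 16, max_epochs: int = 50, patience: int = 10,
                 validation_fraction: float = 0.2, seed: int = 0):
        self.input_side = input_side
        self.backbone = backbone
        self.freeze_backbone = freeze_backbone
        self.head_hidden_units = head_hidden_units
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            input_side=self.input_side, backbone=self.backbone,
            freeze_backbone=self.freeze_backbone,
            head_hidden_units=self.head_hidden_units,
            dropout_rate=self.dropout_rate, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, seed=self.seed)

    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:                      # flattened rows of square images
            side = int(round(np.sqrt(X.shape[1])))
            if side * side != X.shape[1]:
                raise ParameterError("flattened X rows must be square images")
            X = X.reshape(len(X), side, side)
        elif X.ndim != 3:
            raise ParameterError("X must be (n, side, side) or (n, side*side)")
        return np.stack([prepare_input(img, self.input_side) for img in X])

    def fit(self, X, y):
        config = self._config()
        Xs = self._coerce_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ClassCoverageError("CNNClassifier is a binary classifier")
        yi = (y == self.classes_[1]).astype(int)
        rng = np.random.default_rng(self.seed)
        val_idx = []
        for cls in (0, 1):
            idx = np.flatnonzero(yi == cls)
            idx = rng.permutation(idx)
            n_val = max(int(round(self.validation_fraction * len(idx))), 1)
            val_idx.extend(idx[:n_val])
        val_mask = np.zeros(len(yi), dtype=bool)
        val_mask[val_idx] = True
        self.network_ = build_model(config)
        self.history_ = _fit_arrays(self.network_, Xs[~val_mask], yi[~val_mask],
                                    Xs[val_mask], yi[val_mask], config)
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.network_.predict_proba(self._coerce_X(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
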