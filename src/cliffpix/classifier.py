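"""The two-convolutional-layer pair-image classifier.

Architecture: conv(32 filters, 3x3) -> conv(32 filters, 5x5) ->
2x2 max-pool -> dropout -> flatten -> dense(128) -> softmax over the
two classes (cliff vs non-cliff), trained with Adam on categorical
cross-entropy.  Class index 1 is the cliff (AC) class throughout.

The full-size profile takes 300x900x3 tensors; a reduced profile at
150x450x3 with a short epoch budget exists for desk-scale runs and is
what the packaged benchmark uses.  Given a seed, initialization, batch
order and dropout are all reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, UsageError
from .nn import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    InputCenter,
    MaxPool2,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)

AC_CLASS = 1  # softmax column of the cliff class
NON_AC_CLASS = 0


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The architecture fields mirror the fixed design (two conv layers of
    32 filters with 3x3 and 5x5 receptive fields, max-pooling, dropout,
    one dense layer, softmax over two classes); the training fields are
    free choices exposed with sensible defaults.
    """

    input_shape: tuple[int, int, int] = (300, 900, 3)
    n_filters_per_conv: int = 32
    filter_sizes: tuple[int, int] = (3, 5)
    pool_size: int = 2
    dropout_rate: float = 0.25
    dense_units: int = 128
    n_classes: int = 2
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    class_weighting: bool = False  # keep the natural class imbalance by default
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise UsageError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.n_classes != 2:
            raise UsageError("this classifier is binary (n_classes must be 2)")
        if len(self.filter_sizes) != 2:
            raise UsageError("exactly two convolutional layers are supported")
        if self.optimizer != "adam":
            raise UsageError(f"unknown optimizer {self.optimizer!r}")
        if min(self.input_shape[:2]) < max(self.filter_sizes):
            raise UsageError("input smaller than the largest filter")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise UsageError("invalid training hyperparameters")


def reduced_config(**overrides) -> ModelConfig:
    """Desk-scale profile: 150x450 inputs, short schedule."""
    cfg = ModelConfig(
        input_shape=(150, 450, 3), epochs=2, batch_size=16, learning_rate=1e-3
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise UsageError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    return cfg


@dataclass(frozen=True)
class PredictionRecord:
    mmp_id: str
    p_ac: float
    p_non_ac: float
    predicted_label: str  # "AC" or "NON_AC"


class CNNClassifier:
    """Model handle: a :class:`Sequential` network plus its config."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_seed, self._train_seed = ss.spawn(2)
        rng = np.random.default_rng(init_seed)
        h, w, c = config.input_shape
        k1, k2 = config.filter_sizes
        nf = config.n_filters_per_conv
        flat = (h // config.pool_size) * (w // config.pool_size) * nf
        self.net = Sequential(
            [
                InputCenter(offset=1.0, name="center"),  # white background -> 0
                Conv2D(k1, c, nf, "conv1", rng, compute_input_grad=False),
                ReLU("relu1"),
                Conv2D(k2, nf, nf, "conv2", rng),
                ReLU("relu2"),
                MaxPool2("pool"),
                Dropout(config.dropout_rate, "dropout"),
                Flatten("flatten"),
                Dense(flat, config.dense_units, "dense1", rng),
                ReLU("relu3"),
                Dense(config.dense_units, config.n_classes, "dense2", rng),
            ]
        )

    # -- training ---------------------------------------------------------
    def fit(self, images: np.ndarray, labels: np.ndarray) -> list[float]:
        """Train in place; returns the per-epoch mean loss history.

        ``labels`` are integers with 1 = cliff (AC), 0 = non-AC.
        """
        cfg = self.config
        images = np.ascontiguousarray(images, dtype=np.float32)
        labels = np.asarray(labels, dtype=np.int64)
        if images.ndim != 4 or images.shape[1:] != cfg.input_shape:
            raise UsageError(
                f"fit: images of shape {images.shape[1:]} != config {cfg.input_shape}"
            )
        classes = np.unique(labels)
        if len(classes) < 2:
            raise DataError("fit: training data contain a single class")
        onehot = np.zeros((len(labels), cfg.n_classes), dtype=np.float32)
        onehot[np.arange(len(labels)), labels] = 1.0
        weights = None
        if cfg.class_weighting:
            freq = np.bincount(labels, minlength=cfg.n_classes).astype(np.float64)
            w_per_class = len(labels) / (cfg.n_classes * freq)
            weights = w_per_class[labels].astype(np.float32)

        rng = np.random.default_rng(self._train_seed)
        opt = Adam(lr=cfg.learning_rate)
        history: list[float] = []
        n = len(images)
        batch_buf = np.empty((min(cfg.batch_size, n),) + cfg.input_shape, dtype=np.float32)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses, counts = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = batch_buf[: len(idx)]
                np.take(images, idx, axis=0, out=xb)
                yb = onehot[idx]
                wb = weights[idx] if weights is not None else None
                logits = self.net.forward(xb, train=True, rng=rng)
                loss, dlogits = softmax_cross_entropy(logits, yb, wb)
                self.net.backward(dlogits)
                opt.step(self.net.params())
                losses.append(loss)
                counts.append(len(idx))
            history.append(float(np.average(losses, weights=counts)))
        self.net.release_buffers()  # drop batch-sized work arrays
        return history

    # -- inference --------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        images = np.ascontiguousarray(images, dtype=np.float32)
        if images.ndim != 4 or images.shape[1:] != self.config.input_shape:
            raise UsageError(
                f"predict: images of shape {images.shape[1:]} != config {self.config.input_shape}"
            )
        chunks = []
        for start in range(0, len(images), batch_size):
            logits = self.net.forward(images[start : start + batch_size], train=False)
            chunks.append(softmax(logits))
        self.net.release_buffers()
        if not chunks:
            return np.empty((0, self.config.n_classes), dtype=np.float32)
        return np.concatenate(chunks, axis=0)

    def predict(self, images: np.ndarray, mmp_ids=None) -> list[PredictionRecord]:
        probs = self.predict_proba(images)
        if mmp_ids is None:
            mmp_ids = [str(i) for i in range(len(probs))]
        records = []
        for mid, p in zip(mmp_ids, probs):
            p_ac, p_non = float(p[AC_CLASS]), float(p[NON_AC_CLASS])
            records.append(
                PredictionRecord(
                    mmp_id=mid,
                    p_ac=p_ac,
                    p_non_ac=p_non,
                    predicted_label="AC" if p_ac >= p_non else "NON_AC",
                )
            )
        return records

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.net.get_weights())
        cfg = asdict(self.config)
        with open(directory / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "CNNClassifier":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            cfg_dict = json.load(fh)
        for key in ("input_shape", "filter_sizes"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(ModelConfig(**cfg_dict))
        with np.load(directory / "weights.npz") as data:
            model.net.set_weights({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig | None = None) -> CNNClassifier:
    """Construct a seeded, untrained classifier."""
    return CNNClassifier(config or ModelConfig())


def train(model: CNNClassifier, images, labels, config: ModelConfig | None = None):
    """Train ``model`` (optionally overriding its training config);
    returns the loss history."""
    if config is not None:
        config.validate()
        model.config = config
    return model.fit(images, labels)


def predict(model: CNNClassifier, images, mmp_ids=None) -> list[PredictionRecord]:
    return model.predict(images, mmp_ids=mmp_ids)
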