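"""One-vs-one decomposition and the pairwise training protocol.

A K-class problem is decomposed into K(K-1)/2 binary tasks, one per unordered
class pair.  Each task trains a backbone ending in a 2-node softmax head with
an imbalance-weighted cross-entropy loss, a polynomial learning-rate decay
applied on validation-loss plateaus, an overfit-gap early stop, and best
balanced-accuracy checkpoint selection.  The backbone is a pluggable
contract; the default is a small softmax-head linear model over downsampled
pixels, which keeps the framework fully exercisable on a laptop-scale CPU.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.transform import resize as _sk_resize

from .data import class_weights
from .evaluation import bacc, confusion
from .synthetic import LabeledImageSet

__all__ = [
    "BinaryTask",
    "TrainingConfig",
    "TrainingTrace",
    "BackboneContract",
    "LinearSoftmaxBackbone",
    "enumerate_tasks",
    "weighted_cross_entropy",
    "poly_decay",
    "plateau_trigger",
    "early_stop",
    "train_pairwise",
]

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class BinaryTask:
    """Unordered class pair {i, j} with i < j; class i is the positive class
    (first confidence column) by convention."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("require i < j")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)

    @property
    def positive_class(self) -> int:
        return self.i


def enumerate_tasks(K: int) -> list[BinaryTask]:
    """All K(K-1)/2 unordered class pairs, lexicographically sorted."""
    if K < 2:
        raise ValueError("K must be >= 2")
    return [BinaryTask(i, j) for i in range(K) for j in range(i + 1, K)]


def weighted_cross_entropy(
    true_onehot: np.ndarray, pred: np.ndarray, weights: np.ndarray
) -> float:
    """Mean class-weighted cross-entropy, -w_c log q_c at the true class c.

    With one-hot targets the full cross-entropy sum collapses to the true
    class term.  Predictions are clipped to [eps, 1-eps] before the log.
    """
    true_onehot = np.atleast_2d(np.asarray(true_onehot, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if true_onehot.shape != pred.shape:
        raise ValueError("shape mismatch between targets and predictions")
    weights = np.asarray(weights, dtype=float)
    if weights.shape[-1] != pred.shape[-1]:
        raise ValueError("weights length must equal the class count")
    q = np.clip(pred, _LOG_EPS, 1.0 - _LOG_EPS)
    per_sample = -(true_onehot * weights * np.log(q)).sum(axis=1)
    return float(per_sample.mean())


def poly_decay(lr0: float, current_epoch: int, total_epochs: int) -> float:
    """Linear polynomial decay lr0 * (1 - current_epoch / total_epochs)."""
    if not 0 <= current_epoch <= total_epochs:
        raise ValueError("require 0 <= current_epoch <= total_epochs")
    return lr0 * (1.0 - current_epoch / total_epochs)


def plateau_trigger(val_losses: list[float], patience: int) -> bool:
    """True iff the running minimum of ``val_losses`` has not strictly
    improved within the last ``patience`` recorded epochs."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if len(val_losses) == 0:
        raise ValueError("val_losses must be non-empty")
    if len(val_losses) <= patience:
        return False
    return min(val_losses[-patience:]) >= min(val_losses[:-patience])


def early_stop(train_acc: float, val_acc: float, gap: float) -> bool:
    """True iff training accuracy exceeds validation accuracy by strictly
    more than ``gap`` (overfitting guard)."""
    return train_acc - val_acc > gap


@dataclass(frozen=True)
class TrainingConfig:
    """Training schedule: initial LR, epoch budget, batch size, plateau
    patience (epochs without val-loss improvement before an LR decay event),
    overfit gap for early stopping, frozen-layer fraction, seed."""

    lr0: float = 0.05
    total_epochs: int = 40
    batch_size: int = 32
    plateau_patience: int = 8
    overfit_gap: float = 0.10
    frozen_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if not 0.0 < self.overfit_gap < 1.0:
            raise ValueError("overfit_gap must lie in (0, 1)")
        if not 0.0 <= self.frozen_fraction <= 1.0:
            raise ValueError("frozen_fraction must lie in [0, 1]")


@dataclass
class TrainingTrace:
    """Per-epoch record of the training loop plus the selected checkpoint."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_bacc: list[float] = field(default_factory=list)
    lr_used: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = "completed"


class BackboneContract(ABC):
    """Contract a pairwise classifier backbone must satisfy.

    The framework is backbone-agnostic: any model exposing a softmax head of
    ``n_classes`` nodes, per-epoch minibatch training at an externally
    scheduled learning rate, and exact snapshot/restore of its state can be
    plugged in.  ``trainable_fraction`` mirrors partial fine-tuning (1 -
    frozen fraction of layers); the default backbone has a single layer and
    treats any nonzero value as fully trainable.
    """

    trainable_fraction: float = 1.0

    @abstractmethod
    def initialize(self, images: list[np.ndarray], n_classes: int, seed: int) -> None:
        """Bind feature extraction to the training images and init weights."""

    @abstractmethod
    def train_epoch(
        self,
        images: list[np.ndarray],
        labels: np.ndarray,
        sample_weights: np.ndarray,
        lr: float,
        batch_size: int,
        rng: np.random.Generator,
    ) -> float:
        """One pass over the data; returns the mean weighted loss."""

    @abstractmethod
    def predict_confidences(self, images: list[np.ndarray]) -> np.ndarray:
        """(n, n_classes) confidence rows summing to 1."""

    @abstractmethod
    def snapshot(self) -> Any:
        """Opaque copy of the full trainable state."""

    @abstractmethod
    def restore(self, state: Any) -> None:
        """Restore a snapshot; predictions round-trip exactly."""


class LinearSoftmaxBackbone(BackboneContract):
    """Default lightweight backbone: a softmax-head linear model (optionally
    one hidden layer) over 16 x 16 downsampled RGB pixels, trained with Adam.

    Feature extraction resizes each image to ``feature_size`` and flattens;
    features are standardized with statistics frozen at ``initialize``.
    """

    def __init__(self, feature_size: tuple[int, int] = (16, 16), hidden: int = 0):
        self.feature_size = feature_size
        self.hidden = hidden
        self._params: dict[str, np.ndarray] = {}
        self._adam: dict[str, Any] = {}
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self._cache: dict[int, np.ndarray] = {}

    # -- features -----------------------------------------------------------
    def _extract(self, images: list[np.ndarray]) -> np.ndarray:
        key = id(images)
        if key in self._cache and len(self._cache[key]) == len(images):
            return self._cache[key]
        feats = np.stack(
            [
                _sk_resize(
                    np.asarray(im, dtype=float),
                    (*self.feature_size, 3),
                    order=1,
                    mode="reflect",
                    anti_aliasing=True,
                    preserve_range=True,
                ).ravel()
                for im in images
            ]
        )
        if self._mu is not None:
            feats = (feats - self._mu) / self._sd
        self._cache[key] = feats
        return feats

    # -- contract -----------------------------------------------------------
    def initialize(self, images: list[np.ndarray], n_classes: int, seed: int) -> None:
        self._mu = None
        self._sd = None
        self._cache = {}
        raw = self._extract(images)
        self._cache = {}
        self._mu = raw.mean(axis=0)
        self._sd = np.maximum(raw.std(axis=0), 1e-6)
        d = raw.shape[1]
        rng = np.random.default_rng(seed)
        if self.hidden > 0:
            self._params = {
                "W1": rng.standard_normal((d, self.hidden)) * np.sqrt(2.0 / d),
                "b1": np.zeros(self.hidden),
                "W2": np.zeros((self.hidden, n_classes)),
                "b2": np.zeros(n_classes),
            }
        else:
            self._params = {"W2": np.zeros((d, n_classes)), "b2": np.zeros(n_classes)}
        self._adam = {
            "t": 0,
            "m": {k: np.zeros_like(v) for k, v in self._params.items()},
            "v": {k: np.zeros_like(v) for k, v in self._params.items()},
        }

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if self.hidden > 0:
            H = np.maximum(X @ self._params["W1"] + self._params["b1"], 0.0)
        else:
            H = None
        Z = (H if H is not None else X) @ self._params["W2"] + self._params["b2"]
        Z = Z - Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
        return P, H

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam["t"] += 1
        t = self._adam["t"]
        for k, g in grads.items():
            m = self._adam["m"][k] = beta1 * self._adam["m"][k] + (1 - beta1) * g
            v = self._adam["v"][k] = beta2 * self._adam["v"][k] + (1 - beta2) * g**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self._params[k] = self._params[k] - lr * m_hat / (np.sqrt(v_hat) + eps)

    def train_epoch(self, images, labels, sample_weights, lr, batch_size, rng) -> float:
        X = self._extract(images)
        y = np.asarray(labels, dtype=int)
        w = np.asarray(sample_weights, dtype=float)
        n, n_classes = len(y), self._params["b2"].shape[0]
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb, yb, wb = X[idx], y[idx], w[idx]
            P, H = self._forward(Xb)
            q = np.clip(P[np.arange(len(yb)), yb], _LOG_EPS, 1 - _LOG_EPS)
            losses.append(float(np.mean(-wb * np.log(q))))
            if lr <= 0.0:
                continue
            G = P.copy()
            G[np.arange(len(yb)), yb] -= 1.0
            G *= wb[:, None] / len(yb)
            grads: dict[str, np.ndarray] = {}
            if self.hidden > 0:
                grads["W2"] = H.T @ G
                grads["b2"] = G.sum(axis=0)
                GH = (G @ self._params["W2"].T) * (H > 0)
                grads["W1"] = Xb.T @ GH
                grads["b1"] = GH.sum(axis=0)
            else:
                grads["W2"] = Xb.T @ G
                grads["b2"] = G.sum(axis=0)
            self._adam_step(grads, lr)
        return float(np.mean(losses))

    def predict_confidences(self, images) -> np.ndarray:
        P, _ = self._forward(self._extract(images))
        return P

    def snapshot(self) -> Any:
        return (
            {k: v.copy() for k, v in self._params.items()},
            {
                "t": self._adam["t"],
                "m": {k: v.copy() for k, v in self._adam["m"].items()},
                "v": {k: v.copy() for k, v in self._adam["v"].items()},
            },
        )

    def restore(self, state: Any) -> None:
        params, adam = state
        self._params = {k: v.copy() for k, v in params.items()}
        self._adam = {
            "t": adam["t"],
            "m": {k: v.copy() for k, v in adam["m"].items()},
            "v": {k: v.copy() for k, v in adam["v"].items()},
        }


def _binary_subset(
    data: LabeledImageSet, task: BinaryTask, indices: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    mask = np.isin(data.labels[indices], list(task.pair))
    sel = np.asarray(indices)[mask]
    images = [data.images[i] for i in sel]
    binary = (data.labels[sel] == task.j).astype(int)  # 0 = class i (positive)
    return images, binary


def train_pairwise(
    data: LabeledImageSet,
    task: BinaryTask,
    backbone: BackboneContract,
    config: TrainingConfig,
    val_split: tuple[np.ndarray, np.ndarray],
) -> tuple[BackboneContract, TrainingTrace]:
    """Train one pairwise classifier with the full schedule.

    Per epoch: one minibatch pass with the class-imbalance-weighted
    cross-entropy; the LR starts at lr0 and, whenever the validation loss has
    plateaued for ``plateau_patience`` epochs, is reset from the polynomial
    decay at the current epoch (held constant otherwise).  Training stops
    early when train accuracy exceeds validation accuracy by more than
    ``overfit_gap``, or when the decayed LR reaches zero.  The returned
    backbone is restored to the epoch with the best validation balanced
    accuracy.
    """
    train_idx, val_idx = val_split
    train_images, y_train = _binary_subset(data, task, train_idx)
    val_images, y_val = _binary_subset(data, task, val_idx)
    for name, y in (("train", y_train), ("val", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"both classes of pair {task.pair} must appear in the {name} split")

    counts = {0: int((y_train == 0).sum()), 1: int((y_train == 1).sum())}
    w = class_weights(counts, mode="total").as_array(2)
    sample_w = w[y_train]
    onehot_val = np.eye(2)[y_val]
    unit_w = np.ones(2)

    backbone.initialize(train_images, n_classes=2, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))

    trace = TrainingTrace()
    best_bacc = -np.inf
    best_state = backbone.snapshot()
    lr = config.lr0
    for epoch in range(config.total_epochs):
        train_loss = backbone.train_epoch(
            train_images, y_train, sample_w, lr, config.batch_size, rng
        )
        p_train = backbone.predict_confidences(train_images)
        p_val = backbone.predict_confidences(val_images)
        train_acc = float((p_train.argmax(axis=1) == y_train).mean())
        val_loss = weighted_cross_entropy(onehot_val, p_val, unit_w)
        val_pred = p_val.argmax(axis=1)
        val_bacc = bacc(confusion(y_val, val_pred, 2))
        val_acc = float((val_pred == y_val).mean())

        trace.train_loss.append(train_loss)
        trace.val_loss.append(val_loss)
        trace.train_acc.append(train_acc)
        trace.val_bacc.append(val_bacc)
        trace.lr_used.append(lr)

        if val_bacc > best_bacc:
            best_bacc = val_bacc
            trace.best_epoch = epoch
            best_state = backbone.snapshot()

        if early_stop(train_acc, val_acc, config.overfit_gap):
            trace.stop_reason = "overfit_gap"
            break
        if plateau_trigger(trace.val_loss, config.plateau_patience):
            lr = poly_decay(config.lr0, epoch + 1, config.total_epochs)
            if lr <= 0.0:
                trace.stop_reason = "plateau_exhausted"
                break

    backbone.restore(best_state)
    return backbone, trace
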