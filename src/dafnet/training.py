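"""Training and evaluation protocol for the sweep classifiers.

Mini-batch Adam optimization of the softmax cross-entropy over two
classes, a fixed epoch budget with validation accuracy measured after
every epoch, and best-validation checkpointing: the parameter state
reported (and later evaluated on the test split exactly once) is the
one from the epoch with the highest validation accuracy, ties broken
toward the earlier epoch so a model is kept from before it overfits.
Raw-image (2-D) pipelines optionally re-shuffle each window's sample
rows every epoch as augmentation; the 1-D DAF pipeline is invariant to
row order by construction, so it needs none.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .models import model_from_meta
from .representation import SNPMatrix, compute_distances
from .simulate import LabeledWindows


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (defaults follow the evaluation setup)."""

    batch_size: int = 8
    epochs: int = 100
    learning_rate: float = 0.5e-3
    seed: int = 0
    augment_row_shuffle: bool = False
    adam_betas: Tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs >= 1 and learning_rate > 0 required")


@dataclass
class RunReport:
    """Per-epoch curves plus the checkpointed result of one training run."""

    train_loss: List[float]
    train_accuracy: List[float]
    val_loss: List[float]
    val_accuracy: List[float]
    best_epoch: int
    best_val_accuracy: float
    seed: int
    model_meta: Dict
    config: Dict
    test_accuracy: Optional[float] = None

    def to_jsonl(self) -> str:
        lines = [
            json.dumps(
                {
                    "epoch": e,
                    "train_loss": self.train_loss[e],
                    "train_accuracy": self.train_accuracy[e],
                    "val_loss": self.val_loss[e],
                    "val_accuracy": self.val_accuracy[e],
                }
            )
            for e in range(len(self.train_loss))
        ]
        lines.append(
            json.dumps(
                {
                    "summary": True,
                    "best_epoch": self.best_epoch,
                    "best_val_accuracy": self.best_val_accuracy,
                    "test_accuracy": self.test_accuracy,
                    "seed": self.seed,
                    "model": self.model_meta,
                    "config": self.config,
                }
            )
        )
        return "\n".join(lines)


#: a checkpoint is the best-epoch parameter state plus model/feature metadata
Checkpoint = Dict


def augment_row_shuffle(matrix: SNPMatrix, rng: np.random.Generator) -> SNPMatrix:
    """Uniformly permute sample rows; positions and label untouched."""
    return matrix.with_rows(rng.permutation(matrix.n_samples))


class ArraySet:
    """A static (inputs, labels) pair for the 1-D feature pipeline."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.asarray(x)
        self.y = np.asarray(y, dtype=np.int64)
        if len(self.x) != len(self.y):
            raise ValueError("inputs and labels differ in length")

    def __len__(self) -> int:
        return len(self.y)

    def epoch_inputs(self, rng: Optional[np.random.Generator] = None):
        return self.x

    def batch(self, inputs, idx: np.ndarray):
        return inputs[idx], self.y[idx]

    @classmethod
    def from_windows(
        cls, windows: LabeledWindows, scale: Optional[float] = None
    ) -> "ArraySet":
        x, y = windows.features(scale=scale)
        return cls(x, y)


class RawImageSet:
    """Raw N x W allele images for the 2-D pipeline, with optional fusion.

    Alleles map to pixel values 0 (ancestral) / 1 (derived) / 0.5
    (missing).  ``fusion="early_conv"`` broadcasts each window's
    distance vector across rows as a second channel; ``"late_fc"``
    carries it as an auxiliary vector; ``"none"`` drops it.  With
    ``shuffle_rows`` the row order of every window is redrawn each
    epoch (augmentation for raw-data models).
    """

    def __init__(
        self,
        windows: LabeledWindows,
        fusion: str = "none",
        shuffle_rows: bool = False,
        scale: Optional[float] = None,
    ):
        self.matrices = windows.matrices
        self.y = np.asarray(windows.labels, dtype=np.int64)
        self.fusion = fusion
        self.shuffle_rows = shuffle_rows
        dists = []
        for m in self.matrices:
            d = compute_distances(m.positions)
            dists.append(d / scale if scale else d)
        self.dist = np.asarray(dists, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.y)

    def _images(self, order_rng: Optional[np.random.Generator]):
        imgs = []
        for m in self.matrices:
            a = m.alleles
            if order_rng is not None:
                a = a[order_rng.permutation(a.shape[0])]
            img = np.where(a < 0, 0.5, a).astype(np.float64)
            imgs.append(img)
        return np.asarray(imgs)[:, None]  # (n, 1, N, W)

    def epoch_inputs(self, rng: Optional[np.random.Generator] = None):
        imgs = self._images(rng if (self.shuffle_rows and rng is not None) else None)
        if self.fusion == "early_conv":
            chan = np.broadcast_to(
                self.dist[:, None, None, :], (len(self.y), 1, imgs.shape[2], imgs.shape[3])
            )
            return np.concatenate([imgs, chan], axis=1)
        return imgs

    def batch(self, inputs, idx: np.ndarray):
        if self.fusion == "late_fc":
            return (inputs[idx], self.dist[idx]), self.y[idx]
        return inputs[idx], self.y[idx]


DataSet = Union[ArraySet, RawImageSet]


def _accuracy_and_loss(model, dataset: DataSet, batch_size: int = 64):
    inputs = dataset.epoch_inputs(None)
    n = len(dataset)
    correct = 0
    loss_sum = 0.0
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        xb, yb = dataset.batch(inputs, idx)
        logits = model.forward(xb)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        loss_sum += loss * len(idx)
        correct += int((logits.argmax(axis=1) == yb).sum())
    return correct / n, loss_sum / n


def train(
    model,
    train_set: DataSet,
    val_set: DataSet,
    config: TrainConfig,
    feature_scale: Optional[float] = None,
) -> Tuple[Checkpoint, RunReport]:
    """Run the full epoch budget and return the best-validation state.

    The returned checkpoint holds the parameter state from the epoch
    with maximal validation accuracy (earliest epoch on ties), the
    model metadata and the distance-scaling metadata, so a scan can
    verify compatibility before applying it.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise TrainingError("empty training or validation set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(
        model.parameters(),
        lr=config.learning_rate,
        betas=config.adam_betas,
        eps=config.adam_eps,
    )
    report = RunReport(
        train_loss=[],
        train_accuracy=[],
        val_loss=[],
        val_accuracy=[],
        best_epoch=-1,
        best_val_accuracy=-1.0,
        seed=config.seed,
        model_meta=model.meta(),
        config=asdict(config),
    )
    best_state = None
    n = len(train_set)
    for epoch in range(config.epochs):
        aug_rng = (
            np.random.default_rng((config.seed, 7, epoch))
            if config.augment_row_shuffle
            else None
        )
        inputs = train_set.epoch_inputs(aug_rng)
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = train_set.batch(inputs, idx)
            logits = model.forward(xb)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        val_acc, val_loss = _accuracy_and_loss(model, val_set)
        report.train_loss.append(epoch_loss / n)
        report.train_accuracy.append(epoch_correct / n)
        report.val_loss.append(val_loss)
        report.val_accuracy.append(val_acc)
        if val_acc > report.best_val_accuracy:
            report.best_val_accuracy = val_acc
            report.best_epoch = epoch
            best_state = model.get_state()
    checkpoint: Checkpoint = {
        "state": best_state,
        "model_meta": model.meta(),
        "feature_scale": feature_scale,
        "val_accuracy": report.best_val_accuracy,
        "epoch": report.best_epoch,
    }
    return checkpoint, report


def restore(checkpoint: Checkpoint):
    """Rebuild the model a checkpoint was trained from and load its state."""
    model = model_from_meta(checkpoint["model_meta"], seed=0)
    model.set_state(checkpoint["state"])
    return model


def evaluate(
    checkpoint_or_model, test_set: DataSet
) -> Tuple[float, np.ndarray]:
    """Accuracy under argmax plus the 2 x 2 confusion matrix.

    ``confusion[i, j]`` counts windows of true class i predicted as j
    (class 0 = neutral, 1 = sweep).
    """
    if len(test_set) == 0:
        raise ValueError("empty evaluation set")
    model = (
        restore(checkpoint_or_model)
        if isinstance(checkpoint_or_model, dict)
        else checkpoint_or_model
    )
    inputs = test_set.epoch_inputs(None)
    n = len(test_set)
    confusion = np.zeros((2, 2), dtype=np.int64)
    for start in range(0, n, 64):
        idx = np.arange(start, min(start + 64, n))
        xb, yb = test_set.batch(inputs, idx)
        pred = model.forward(xb).argmax(axis=1)
        for t, p in zip(yb, pred):
            confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / n)
    return accuracy, confusion


@dataclass
class RepeatSummary:
    """Aggregate of repeated training runs (mean/min/max test accuracy)."""

    accuracies: List[float]
    reports: List[RunReport]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.accuracies))

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))


def repeat_runs(
    model_builder: Callable[[int], object],
    train_set: DataSet,
    val_set: DataSet,
    test_set: DataSet,
    config: TrainConfig,
    n_runs: int = 10,
) -> RepeatSummary:
    """Train ``n_runs`` models with derived seeds and aggregate test accuracy."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    accs: List[float] = []
    reports: List[RunReport] = []
    for run in range(n_runs):
        seed = config.seed + run
        model = model_builder(seed)
        ckpt, report = train(
            model, train_set, val_set, TrainConfig(**{**asdict(config), "seed": seed})
        )
        acc, _ = evaluate(ckpt, test_set)
        report.test_accuracy = acc
        accs.append(acc)
        reports.append(report)
    return RepeatSummary(accs, reports)


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------

def save_checkpoint(checkpoint: Checkpoint, path: str) -> None:
    arrays = {f"param_{i}": a for i, a in enumerate(checkpoint["state"])}
    meta = {
        "model_meta": checkpoint["model_meta"],
        "feature_scale": checkpoint["feature_scale"],
        "val_accuracy": checkpoint["val_accuracy"],
        "epoch": checkpoint["epoch"],
        "n_params": len(checkpoint["state"]),
    }
    with open(path, "wb") as fh:  # handle keeps the exact path (no .npz suffixing)
        np.savez(
            fh,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )


def load_checkpoint(path: str) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = [data[f"param_{i}"] for i in range(meta["n_params"])]
    return {
        "state": state,
        "model_meta": meta["model_meta"],
        "feature_scale": meta["feature_scale"],
        "val_accuracy": meta["val_accuracy"],
        "epoch": meta["epoch"],
    }
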