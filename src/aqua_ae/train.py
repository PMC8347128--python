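"""Self-supervised autoencoder training: split, fit, evaluate.

Training follows the usual reconstruction recipe: the input image is its
own target, minibatches are drawn in a seeded order, the optimizer is Adam
(step size 0.001, moment decays 0.9/0.999), and the loss is binary cross
entropy for MLP models and mean squared error for CNN models (both as
per-pixel means). Convergence is operationalized as early stopping: when
the validation loss has not improved for ``patience`` consecutive epochs,
training stops and the best-epoch weights are restored.

``fit`` is reproducible bit-for-bit under a fixed seed in single-threaded
use: weight initialization, the 80/20 partition, and every epoch's batch
order all derive from the one configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from aqua_ae._layers import Adam, bce_loss, mse_loss
from aqua_ae.metrics import benchmark
from aqua_ae.models import Autoencoder

__all__ = [
    "TrainConfig",
    "TrainingResults",
    "EvalReport",
    "TrainingError",
    "split_dataset",
    "fit",
    "evaluate",
]


class TrainingError(RuntimeError):
    """Raised on empty data or a non-finite loss, with a diagnostic message."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; defaults follow the full-scale study settings."""

    epochs: int = 512
    batch_size: int = 8
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    loss: str | None = None  # None -> bce for MLP, mse for CNN
    split_fraction: float = 0.8
    seed: int = 0
    patience: int = 32

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss not in (None, "bce", "mse"):
            raise ValueError(f"loss must be 'bce', 'mse' or None, got {self.loss!r}")


def split_dataset(
    items: Sequence, fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Seeded random partition into (train, test); |train| = round(fraction·N).

    Disjoint and exhaustive: the union of both halves is the input multiset.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # keep both halves non-empty
    return [items[i] for i in order[:n_train]], [items[i] for i in order[n_train:]]


@dataclass
class TrainingResults:
    """What a fit produced: loss curves, the best epoch, and the fitted model.

    ``best_epoch`` is the 0-based index of the epoch with the lowest
    validation loss; those weights are the ones left on the model.
    """

    model: Autoencoder
    config: TrainConfig
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]

    def evaluate(self, test_imgs: np.ndarray) -> "EvalReport":
        return evaluate(self.model, test_imgs)

    def summary(self) -> str:
        loss_name = self.config.loss or ("bce" if self.model.spec.family == "mlp" else "mse")
        lines = [
            f"{self.model.spec.family.upper()} '{self.model.spec.text}' — "
            f"{len(self.train_loss)} epochs, loss={loss_name}, "
            f"batch={self.config.batch_size}, seed={self.config.seed}",
            f"{'epoch':>6}{'train loss':>16}{'val loss':>16}",
        ]
        for i, (tr, va) in enumerate(zip(self.train_loss, self.val_loss)):
            marker = "  <- best" if i == self.best_epoch else ""
            lines.append(f"{i + 1:>6}{tr:>16.6g}{va:>16.6g}{marker}")
        lines.append(
            f"converged at epoch {self.best_epoch + 1} "
            f"(val loss {self.best_val_loss:.6g}); "
            + ("stopped early" if self.stopped_early else "ran all epochs")
        )
        return "\n".join(lines)


def _resolve_loss(model: Autoencoder, cfg: TrainConfig):
    name = cfg.loss or ("bce" if model.spec.family == "mlp" else "mse")
    return (bce_loss if name == "bce" else mse_loss), name


def _dataset_loss(model: Autoencoder, data: np.ndarray, loss_fn, batch: int) -> float:
    total = 0.0
    for i in range(0, len(data), batch):
        chunk = data[i : i + batch]
        pred = model.reconstruct(chunk)
        loss, _ = loss_fn(pred, chunk)
        total += loss * len(chunk)
    return total / len(data)


def fit(
    model: Autoencoder,
    data: np.ndarray,
    config: TrainConfig | None = None,
    val_data: np.ndarray | None = None,
) -> TrainingResults:
    """Train an autoencoder on its own inputs and return the results object.

    ``data`` is an (N, side, side, 3) array in [0, 1]. When ``val_data`` is
    not given, ``data`` is partitioned with ``config.split_fraction`` and
    ``config.seed`` first. Uninitialized models are initialized from
    ``config.seed``. Stops early when the validation loss has not improved
    for ``config.patience`` epochs and restores the best-epoch weights.
    """
    cfg = config or TrainConfig()
    data = np.asarray(data, dtype=np.float64)
    if data.size == 0:
        raise TrainingError("empty training data")
    if data.ndim != 4 or data.shape[1:] != model.input_shape:
        raise TrainingError(
            f"data shape {data.shape} does not match model input {model.input_shape}"
        )
    if val_data is None:
        train_idx, val_idx = split_dataset(list(range(len(data))), cfg.split_fraction, cfg.seed)
        train, val = data[train_idx], data[val_idx]
    else:
        train, val = data, np.asarray(val_data, dtype=np.float64)
        if val.size == 0:
            raise TrainingError("empty validation data")

    if not model.initialized:
        model.initialize(cfg.seed)
    loss_fn, _ = _resolve_loss(model, cfg)
    optimizer = Adam(lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))

    results = TrainingResults(model=model, config=cfg)
    best_val = np.inf
    best_weights = None
    since_improve = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for i in range(0, len(train), cfg.batch_size):
            batch = train[order[i : i + cfg.batch_size]]
            x = batch
            for layer in model.layers:
                x = layer.forward(x)
            loss, grad = loss_fn(x, batch)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss {loss} at epoch {epoch + 1}")
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            optimizer.step(model.layers)
            epoch_loss += loss * len(batch)
        results.train_loss.append(epoch_loss / len(train))
        vloss = _dataset_loss(model, val, loss_fn, cfg.batch_size)
        if not np.isfinite(vloss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch + 1}")
        results.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            results.best_epoch = epoch
            best_weights = model.get_weights()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                results.stopped_early = True
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    return results


@dataclass
class EvalReport:
    """Per-image reconstruction benchmarks over a test set."""

    benchmarks: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.benchmarks))

    @property
    def std(self) -> float:
        return float(np.std(self.benchmarks))  # population

    def summary(self) -> str:
        return f"{self.mean:.8f}±{self.std:.9f} over {len(self.benchmarks)} images"


def evaluate(model: Autoencoder, test_imgs: np.ndarray) -> EvalReport:
    """Benchmark each test image against its reconstruction.

    Returns one record per image: the visual-contrast benchmark between the
    source and the model's reconstruction (0 = perfect reconstruction).
    """
    test_imgs = np.asarray(test_imgs, dtype=np.float64)
    if test_imgs.size == 0:
        raise ValueError("empty test set")
    if test_imgs.ndim == 3:
        test_imgs = test_imgs[None]
    values = []
    for img in test_imgs:
        values.append(benchmark(img, model.reconstruct(img)))
    return EvalReport(benchmarks=values)
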