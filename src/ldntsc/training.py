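"""Surrogate-gradient training through time, grid search, accuracy accounting.

Protocol: Adam on the trainable matrices, mini-batches as contiguous slices
of a permutation that is redrawn every ``shuffle_every`` epochs (default
20), and the test accuracy evaluated on the *entire* test set after every
epoch.  The run's headline number is its best per-epoch test accuracy; a
grid search reports

* ``Max_acc``  — the maximum over all hyper-parameter combinations and
  seeds, and
* ``Mean_acc`` — mean +/- sample standard deviation of the per-seed maxima
  (each seed's maximum taken over all combinations).

Selecting the best epoch on test accuracy is deliberately reproduced from
the evaluation protocol this package follows; it is an optimistic estimate
and is documented as such in docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from . import models
from .data import Dataset
from .exceptions import ConfigurationError, DataError

__all__ = ["TrainConfig", "TrainResult", "GridResult", "train",
           "grid_search", "aggregate_maxima", "accuracy"]


@dataclass
class TrainConfig:
    eta: float = 0.005
    epochs: int = 50
    batch_size: int = 50
    shuffle_every: int = 20
    seeds: tuple = (6, 9, 100)
    grid: dict | None = None
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.shuffle_every < 1:
            raise ConfigurationError(
                "epochs, batch_size and shuffle_every must all be >= 1")


@dataclass
class TrainResult:
    per_epoch_acc: list          # test accuracy (%) after each epoch
    per_epoch_loss: list
    max_acc: float               # best per-epoch test accuracy (%)
    best_epoch: int
    best_weights: dict = field(repr=False)


@dataclass
class GridResult:
    rows: list                   # (combo index, combo dict, seed, max acc %)
    max_acc: float
    mean_acc: float
    std_acc: float
    n_runs: int

    def to_csv(self, path, dataset_name=""):
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["dataset", "combo", "seed", "max_accuracy_pct"])
            for ci, combo, seed, acc in self.rows:
                w.writerow([dataset_name, ci, seed, f"{acc:.4f}"])


class _Adam:
    def __init__(self, weights, eta, b1, b2, eps):
        self.eta, self.b1, self.b2, self.eps = eta, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            weights[k] -= self.eta * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def accuracy(model, Z, y):
    """Fraction correct on the full encoded set, in percent."""
    preds = models.predict(model, Z)
    return 100.0 * float(np.mean(preds == np.asarray(y)))


def _check_labels(labels, n_classes):
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise DataError(
            f"labels must be contiguous integers in [0, {n_classes}); "
            "apply binarize_ecg5000 or canonicalize_labels first")
    return labels


def train(model, train_set: Dataset, test_set: Dataset, cfg: TrainConfig,
          log_path=None) -> TrainResult:
    """Train one model; returns the per-epoch trace and best weights.

    The training sample count must be divisible by the batch size
    (use :func:`ldntsc.data.trim_to_batch` on UCR splits first).  The
    shuffle RNG is seeded from the model's seed, so identical
    (seed, config, data) reruns are bit-reproducible.
    """
    n = len(train_set)
    if n % cfg.batch_size != 0:
        raise ConfigurationError(
            f"{n} training samples not divisible by batch_size="
            f"{cfg.batch_size}; trim the dataset with data.trim_to_batch")
    y_train = _check_labels(train_set.labels, model.config.n_classes)
    y_test = _check_labels(test_set.labels, model.config.n_classes)
    Z_train = models.encode_dataset(model, train_set.signals)
    Z_test = models.encode_dataset(model, test_set.signals)
    rng = np.random.default_rng(model.config.seed)
    opt = _Adam(model.weights, cfg.eta, cfg.adam_beta1, cfg.adam_beta2,
                cfg.adam_eps)
    perm = np.arange(n)
    accs, losses = [], []
    best_acc, best_epoch, best_w = -1.0, -1, model.copy_weights()
    log = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            if epoch % cfg.shuffle_every == 0:
                perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                loss, grads = models.loss_and_grad(
                    model, Z_train[idx], y_train[idx])
                opt.step(model.weights, grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            acc = accuracy(model, Z_test, y_test)
            accs.append(acc)
            losses.append(epoch_loss)
            if acc > best_acc:
                best_acc, best_epoch = acc, epoch
                best_w = model.copy_weights()
            if log:
                log.write(f"{epoch}\t{epoch_loss:.6f}\t{acc:.4f}\n")
    finally:
        if log:
            log.close()
    return TrainResult(per_epoch_acc=accs, per_epoch_loss=losses,
                       max_acc=best_acc, best_epoch=best_epoch,
                       best_weights=best_w)


def aggregate_maxima(per_seed_maxima):
    """Max_acc / Mean_acc accounting from per-seed maximum accuracies.

    Returns (max, mean, sample std); the std uses the n-1 denominator and
    is 0 for a single seed.
    """
    vals = np.asarray(list(per_seed_maxima), dtype=float)
    std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.max()), float(vals.mean()), std


def grid_search(model_builder, train_set: Dataset, test_set: Dataset,
                cfg: TrainConfig) -> GridResult:
    """Exhaustive product over the grid values and the seeds.

    ``model_builder(params, seed)`` must return a *fresh* model for the
    given hyper-parameter overrides (weights never persist between
    combinations).  A grid entry named ``eta`` overrides the learning rate
    instead of a model parameter.
    """
    if not cfg.grid:
        raise ConfigurationError("grid_search requires a non-empty grid")
    if not cfg.seeds:
        raise ConfigurationError("grid_search requires at least one seed")
    keys = sorted(cfg.grid)
    combos = list(itertools.product(*(cfg.grid[k] for k in keys)))
    rows = []
    per_seed_max = {}
    for seed in cfg.seeds:
        for ci, combo in enumerate(combos):
            params = dict(zip(keys, combo))
            eta = params.pop("eta", cfg.eta)
            model = model_builder(params, seed)
            res = train(model, train_set, test_set, replace(cfg, eta=eta))
            rows.append((ci, dict(zip(keys, combo)), seed, res.max_acc))
            per_seed_max[seed] = max(per_seed_max.get(seed, -1.0),
                                     res.max_acc)
    mx, mean, std = aggregate_maxima(per_seed_max.values())
    return GridResult(rows=rows, max_acc=mx, mean_acc=mean, std_acc=std,
                      n_runs=len(rows))
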