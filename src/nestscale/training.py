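"""Offline training protocol for the MLP weight estimator.

Patterns that contain both stable and unstable readings supply supervised
examples: the target is the arithmetic mean of the stable readings (the
scale is unbiased while the animal stands still) and the features are the
nine summary variables of the remaining, unstable readings.  The example
set is split 50/50 at random, candidate networks with 1-9 hidden neurons
are fitted by back-propagation on the mean-squared error of the scaled
output, and the smallest network whose held-out accuracy is within a
parsimony tolerance of the best is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .acquisition import Pattern
from .errors import DegenerateInputError
from .estimator import InputScaling, MLPParameters, accuracy_percent, mlp_forward
from .features import FeatureVector, extract_features

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingExample",
    "TrainConfig",
    "build_training_set",
    "split_dataset",
    "train_mlp",
    "select_model",
    "evaluate_model",
    "train_and_select",
]


@dataclass(frozen=True)
class TrainingExample:
    """One supervised pair: unstable-part features, stable-mean target (g)."""

    features: FeatureVector
    target: float


@dataclass
class TrainConfig:
    """Back-propagation and protocol controls.

    Full-batch gradient descent with classic momentum on the MSE of the
    sigmoid output; targets are divided by ``resample_factor`` so the
    (0, 1) output range can represent them.  Training stops early when the
    training MSE has not improved by ``min_improvement`` for ``patience``
    epochs.
    """

    hidden_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    split_fraction: float = 0.5
    seed: int = 0
    learning_rate: float = 0.2
    momentum: float = 0.9
    epochs: int = 40000
    patience: int = 500
    min_improvement: float = 0.0
    step: float = 1.0
    resample_factor: float = 300.0
    count_divisor: float = 2048.0
    parsimony_tol: float = 0.1  # percentage points of held-out accuracy

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")

    @property
    def input_scaling(self) -> InputScaling:
        return InputScaling(weight_divisor=self.resample_factor,
                            count_divisor=self.count_divisor)


def build_training_set(
    patterns: Sequence[Pattern], step: float = 1.0
) -> list[TrainingExample]:
    """One example per mixed pattern (>= 1 stable and >= 1 unstable sample);
    all-stable and all-unstable patterns are skipped and counted."""
    examples: list[TrainingExample] = []
    n_no_stable = n_no_unstable = 0
    for p in patterns:
        stable = p.stable_weights()
        unstable = p.unstable_weights()
        if len(stable) == 0:
            n_no_stable += 1
            continue
        if len(unstable) == 0:
            n_no_unstable += 1
            continue
        examples.append(TrainingExample(
            features=extract_features(p, step=step, exclude_stable=True),
            target=float(stable.mean()),
        ))
    logger.info(
        "build_training_set: %d examples (%d skipped without stable, "
        "%d without unstable samples)",
        len(examples), n_no_stable, n_no_unstable,
    )
    if not examples:
        raise DegenerateInputError("no mixed patterns to train on")
    return examples


def split_dataset(
    examples: Sequence[TrainingExample], fraction: float, seed: int
) -> tuple[list[TrainingExample], list[TrainingExample]]:
    """Disjoint, exhaustive random split; the training half has
    ``ceil(n * fraction)`` examples; reproducible for a fixed seed."""
    n = len(examples)
    if n < 2:
        raise DegenerateInputError("need at least 2 examples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = ceil(n * fraction)
    train = [examples[i] for i in order[:n_train]]
    test = [examples[i] for i in order[n_train:]]
    return train, test


def _design(
    examples: Sequence[TrainingExample], scaling: InputScaling, r: float
) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([scaling.scale(e.features) for e in examples])
    y = np.array([e.target for e in examples]) / r
    return x, y


def train_mlp(
    train: Sequence[TrainingExample], cfg: TrainConfig, hidden_size: int
) -> MLPParameters:
    """Fit one 9-H-1 network by momentum back-propagation.

    Deterministic for a fixed ``cfg.seed``: weights start U(-0.5, 0.5)
    from that seed and the optimizer is full-batch.
    """
    if not train:
        raise DegenerateInputError("empty training set")
    scaling = cfg.input_scaling
    r = cfg.resample_factor
    x, y = _design(train, scaling, r)
    n, n_in = x.shape
    rng = np.random.default_rng(cfg.seed)
    w1 = rng.uniform(-0.5, 0.5, (n_in, hidden_size))
    b1 = rng.uniform(-0.5, 0.5, hidden_size)
    w2 = rng.uniform(-0.5, 0.5, (hidden_size, 1))
    b2 = rng.uniform(-0.5, 0.5, 1)
    v1 = np.zeros_like(w1); vb1 = np.zeros_like(b1)
    v2 = np.zeros_like(w2); vb2 = np.zeros_like(b2)
    yy = y[:, None]
    lr, mom = cfg.learning_rate, cfg.momentum
    best = np.inf
    since_best = 0
    for epoch in range(cfg.epochs):
        h = 1.0 / (1.0 + np.exp(-(x @ w1 + b1)))
        o = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))
        err = o - yy
        mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} (H={hidden_size})"
            )
        if best - mse > cfg.min_improvement:
            best = mse
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        d_o = err * o * (1.0 - o) * (2.0 / n)
        d_h = (d_o @ w2.T) * h * (1.0 - h)
        v2 = mom * v2 - lr * (h.T @ d_o)
        vb2 = mom * vb2 - lr * d_o.sum(axis=0)
        v1 = mom * v1 - lr * (x.T @ d_h)
        vb1 = mom * vb1 - lr * d_h.sum(axis=0)
        w2 += v2; b2 += vb2; w1 += v1; b1 += vb1
    logger.info("train_mlp: H=%d stopped at epoch %d, train MSE %.3e (scaled)",
                hidden_size, epoch + 1, mse)
    return MLPParameters(
        hidden_weights=w1,
        hidden_biases=b1,
        output_weights=w2[:, 0],
        output_bias=float(b2[0]),
        resample_factor=r,
        input_scaling=scaling,
    )


def training_loss_curve(
    train: Sequence[TrainingExample], cfg: TrainConfig, hidden_size: int
) -> np.ndarray:
    """Training MSE per epoch (diagnostics; same updates as train_mlp)."""
    scaling = cfg.input_scaling
    x, y = _design(train, scaling, cfg.resample_factor)
    n, n_in = x.shape
    rng = np.random.default_rng(cfg.seed)
    w1 = rng.uniform(-0.5, 0.5, (n_in, hidden_size))
    b1 = rng.uniform(-0.5, 0.5, hidden_size)
    w2 = rng.uniform(-0.5, 0.5, (hidden_size, 1))
    b2 = rng.uniform(-0.5, 0.5, 1)
    v1 = np.zeros_like(w1); vb1 = np.zeros_like(b1)
    v2 = np.zeros_like(w2); vb2 = np.zeros_like(b2)
    yy = y[:, None]
    lr, mom = cfg.learning_rate, cfg.momentum
    losses = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        h = 1.0 / (1.0 + np.exp(-(x @ w1 + b1)))
        o = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))
        err = o - yy
        losses[epoch] = np.mean(err**2)
        d_o = err * o * (1.0 - o) * (2.0 / n)
        d_h = (d_o @ w2.T) * h * (1.0 - h)
        v2 = mom * v2 - lr * (h.T @ d_o)
        vb2 = mom * vb2 - lr * d_o.sum(axis=0)
        v1 = mom * v1 - lr * (x.T @ d_h)
        vb1 = mom * vb1 - lr * d_h.sum(axis=0)
        w2 += v2; b2 += vb2; w1 += v1; b1 += vb1
    return losses


def evaluate_model(
    model: MLPParameters, test: Sequence[TrainingExample]
) -> float:
    """Mean percent accuracy of the model's predictions on held-out
    examples (order-invariant)."""
    if not test:
        raise DegenerateInputError("empty test set")
    accs = [accuracy_percent(e.target, mlp_forward(e.features, model))
            for e in test]
    return float(np.mean(accs))


def select_model(
    candidates: dict[int, MLPParameters],
    test: Sequence[TrainingExample],
    tol: float = 0.1,
) -> MLPParameters:
    """Accuracy-vs-complexity trade-off: rank candidates by held-out mean
    accuracy and keep the smallest hidden layer within ``tol`` percentage
    points of the best."""
    if not candidates:
        raise DegenerateInputError("no candidate models")
    scores = {h: evaluate_model(m, test) for h, m in candidates.items()}
    best = max(scores.values())
    chosen = min(h for h, s in scores.items() if s >= best - tol)
    logger.info("select_model: scores %s -> H=%d",
                {h: round(s, 3) for h, s in sorted(scores.items())}, chosen)
    return candidates[chosen]


def train_and_select(
    examples: Sequence[TrainingExample], cfg: TrainConfig
) -> tuple[MLPParameters, dict[int, float], int]:
    """Full sweep: split, train every hidden size, select.

    Returns the selected model, the per-H held-out accuracy table and the
    selected hidden size.
    """
    train, test = split_dataset(examples, cfg.split_fraction, cfg.seed)
    candidates = {h: train_mlp(train, cfg, h) for h in cfg.hidden_sizes}
    scores = {h: evaluate_model(m, test) for h, m in candidates.items()}
    best = max(scores.values())
    chosen = min(h for h, s in scores.items() if s >= best - cfg.parsimony_tol)
    return candidates[chosen], scores, chosen
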