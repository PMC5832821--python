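"""The three-layer perceptron at the core of both pipeline stages.

Architecture
------------
A feed-forward network with one input layer, a hidden layer of ``H``
logistic-sigmoid units (default ``H = 2``, deliberately small to limit
overfitting on wide expression data), and a single logistic-sigmoid output
unit.  Biases are realised as a fixed +1 input appended to each layer and
are initialised like every other weight: independent draws from
``Normal(0, init_sd**2)`` with ``init_sd = 0.1``.

Training minimises the squared error ``E = 1/2 (output - target)^2`` by
online (per-sample) backpropagation with momentum,

    dw = -lr * dE/dw + momentum * dw_prev,

with defaults ``lr = 0.1`` and ``momentum = 0.5``.  Because the output
unit is bounded in (0, 1), targets must lie in [0, 1]: binary phenotype
classes for screening, min-max-scaled expression for marker prediction —
the two uses are otherwise identical.

Training samples are visited in a fresh random order each epoch; after
each epoch the mean squared error is recorded on the training subset and
on a held-out test subset, and the weight snapshot with the best test MSE
is returned (early stopping with a patience window, default 20 epochs of
no improvement, capped at 300 epochs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels

__all__ = [
    "Hyperparameters",
    "MLPModel",
    "TrainingTrace",
    "TrainingDivergedError",
    "init_model",
    "forward",
    "gradient",
    "backprop_step",
    "train",
]


class TrainingDivergedError(ArithmeticError):
    """A weight or gradient became non-finite during training."""


@dataclass(frozen=True)
class Hyperparameters:
    """Training hyperparameters with the pipeline's standard defaults."""

    learning_rate: float = 0.1
    momentum: float = 0.5
    init_sd: float = 0.1
    n_hidden: int = 2
    max_epochs: int = 300
    patience: int = 20

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not self.init_sd > 0:
            raise ValueError("init_sd must be > 0")
        if self.n_hidden < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("n_hidden, max_epochs and patience must be >= 1")


@dataclass
class MLPModel:
    """Weights and momentum state of a three-layer perceptron.

    ``W1`` has shape ``(n_inputs + 1, H)`` (last row = hidden biases);
    ``W2`` has shape ``(H + 1,)`` (last entry = output bias).  ``vW1`` and
    ``vW2`` hold the previous applied updates for the momentum term.
    """

    W1: np.ndarray
    W2: np.ndarray
    hyper: Hyperparameters
    vW1: np.ndarray = field(default=None)  # type: ignore[assignment]
    vW2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float).ravel()
        if self.W1.ndim != 2 or self.W2.shape[0] != self.hyper.n_hidden + 1:
            raise ValueError("weight shapes inconsistent with architecture")
        if self.W1.shape[1] != self.hyper.n_hidden:
            raise ValueError("W1 columns must equal n_hidden")
        if self.vW1 is None:
            self.vW1 = np.zeros_like(self.W1)
        if self.vW2 is None:
            self.vW2 = np.zeros_like(self.W2)

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0] - 1

    def to_json(self, path: str | Path | None = None, seed: int | None = None) -> str:
        doc = {
            "n_inputs": self.n_inputs,
            "W1": self.W1.tolist(),
            "W2": self.W2.tolist(),
            "hyper": asdict(self.hyper),
            "seed": seed,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(np.array(doc["W1"]), np.array(doc["W2"]),
                   Hyperparameters(**doc["hyper"]))


@dataclass
class TrainingTrace:
    """Per-epoch train/test error curves and the selected snapshot epoch."""

    train_mse: np.ndarray
    test_mse: np.ndarray
    epoch_selected: int

    def __post_init__(self) -> None:
        self.train_mse = np.asarray(self.train_mse, dtype=float)
        self.test_mse = np.asarray(self.test_mse, dtype=float)
        if self.train_mse.shape != self.test_mse.shape:
            raise ValueError("train and test traces must have equal length")
        if not 0 <= self.epoch_selected < len(self.train_mse):
            raise ValueError("epoch_selected out of range")

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


def init_model(n_inputs: int, hyper: Hyperparameters | None = None,
               seed: int | np.random.SeedSequence = 0) -> MLPModel:
    """Create a model with Normal(0, init_sd^2) weights and zero velocity."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    hyper = hyper or Hyperparameters()
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, hyper.init_sd, size=(n_inputs + 1, hyper.n_hidden))
    W2 = rng.normal(0.0, hyper.init_sd, size=hyper.n_hidden + 1)
    return MLPModel(W1, W2, hyper)


def forward(model: MLPModel, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Forward pass; returns (hidden activations, output in (0, 1))."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_inputs:
        raise ValueError(f"input length {x.shape[0]} != n_inputs {model.n_inputs}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    hidden = np.empty(model.hyper.n_hidden)
    out = _kernels.forward_one(model.W1, model.W2, x, hidden)
    return hidden, float(out)


def gradient(model: MLPModel, x: np.ndarray, y_target: float
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic gradient of E = 1/2 (output - y)^2 w.r.t. every weight.

    Returns (gW1, gW2, output).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_inputs:
        raise ValueError(f"input length {x.shape[0]} != n_inputs {model.n_inputs}")
    gW1 = np.empty_like(model.W1)
    gW2 = np.empty_like(model.W2)
    hidden = np.empty(model.hyper.n_hidden)
    out = _kernels.gradient_one(model.W1, model.W2, x, float(y_target),
                                gW1, gW2, hidden)
    return gW1, gW2, float(out)


def backprop_step(model: MLPModel, x: np.ndarray, y_target: float) -> MLPModel:
    """Apply one online backprop-with-momentum update in place.

    The applied update is stored in the model's velocity arrays so the
    next call's momentum term sees it.
    """
    if not 0.0 <= y_target <= 1.0:
        raise ValueError("y_target must lie in [0, 1]")
    gW1, gW2, _ = gradient(model, x, y_target)
    if not (np.all(np.isfinite(gW1)) and np.all(np.isfinite(gW2))):
        raise TrainingDivergedError("non-finite gradient")
    h = model.hyper
    model.vW1 = -h.learning_rate * gW1 + h.momentum * model.vW1
    model.vW2 = -h.learning_rate * gW2 + h.momentum * model.vW2
    model.W1 += model.vW1
    model.W2 += model.vW2
    if not (np.all(np.isfinite(model.W1)) and np.all(np.isfinite(model.W2))):
        raise TrainingDivergedError("non-finite weight after update")
    return model


def train(X: np.ndarray, targets: np.ndarray, train_idx: np.ndarray,
          test_idx: np.ndarray, hyper: Hyperparameters | None = None,
          seed: int | np.random.SeedSequence = 0
          ) -> tuple[MLPModel, TrainingTrace]:
    """Train a perceptron on rows of ``X`` (samples x inputs).

    The seed controls both the weight initialisation and every epoch's
    shuffle order, so a run is fully reproducible.  The returned model is
    the snapshot with the best test-subset MSE.

    Raises
    ------
    ValueError
        Empty or overlapping index sets, or targets outside [0, 1].
    TrainingDivergedError
        Weights became non-finite (and no earlier snapshot exists).
    """
    X = np.ascontiguousarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float).ravel()
    train_idx = np.asarray(train_idx, dtype=np.int64)
    test_idx = np.asarray(test_idx, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != targets.shape[0]:
        raise ValueError("X must be 2-D with one target per row")
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("train and test index sets must be non-empty")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets must be disjoint")
    if targets.min() < 0 or targets.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    hyper = hyper or Hyperparameters()
    rng = np.random.default_rng(seed)
    model = init_model(X.shape[1], hyper, rng)
    shuffles = np.empty((hyper.max_epochs, train_idx.size), dtype=np.int64)
    for e in range(hyper.max_epochs):
        shuffles[e] = rng.permutation(train_idx)
    bestW1, bestW2, tr, te, best_epoch, diverged = _kernels.train_loop(
        model.W1, model.W2, X, targets, shuffles, test_idx,
        hyper.learning_rate, hyper.momentum, hyper.patience)
    if diverged:
        raise TrainingDivergedError("weights became non-finite during training")
    best = MLPModel(bestW1, bestW2, hyper)
    return best, TrainingTrace(tr, te, best_epoch)
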