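"""Structured covariances as initialization for fully-trained networks.

A single-hidden-layer ReLU network (no hidden threshold) is trained end to
end — hidden weights and readout both move — by full-batch gradient descent
on the softmax cross-entropy loss. Initialization either follows the
Kaiming-He normal scheme, rows w ~ N(0, (2/d) I) so that E||w||^2 = 2, or
samples from a structured covariance rescaled to Tr(C) = 2, which puts the
two schemes on equal footing. Learning speed is summarized by the area
under the training-loss curve, and the learning rate is selected by a grid
search over (1e-4, 1e0) minimizing that area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CovarianceModel, normalize_trace
from .sampling import ReceptiveFieldSet, sample_weights

__all__ = [
    "TrainConfig",
    "TrainTrace",
    "init_hidden_weights",
    "train_full",
    "lr_grid_search",
]


@dataclass
class TrainConfig:
    """Configuration of a full-training run."""

    m: int
    epochs: int
    learning_rate: float
    init_kind: str = "kaiming"  # "kaiming" | "structured"
    cov: CovarianceModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.init_kind == "structured" and self.cov is None:
            raise ValueError("structured init requires a covariance model")


@dataclass
class TrainTrace:
    """Per-epoch training loss and test error of one run."""

    train_loss: np.ndarray
    test_error: np.ndarray
    diverged: bool = False

    @property
    def area(self) -> float:
        """Area under the training-loss curve (trapezoidal), the learning-speed metric."""
        return float(np.trapezoid(self.train_loss))


def init_hidden_weights(
    kind: str,
    m: int,
    seed: int,
    d: int | None = None,
    cov: CovarianceModel | None = None,
) -> ReceptiveFieldSet:
    """Hidden-weight initialization with Tr(covariance) = 2.

    kind = "kaiming": rows i.i.d. N(0, (2/d) I) — Tr((2/d) I) = 2.
    kind = "structured": samples from ``cov`` rescaled to Tr(C) = 2, so any
        structured model (compatible or incompatible with the task) starts
        with the same expected weight energy E||w||^2 = 2.
    """
    if kind == "kaiming":
        if d is None:
            raise ValueError("kaiming init requires the input dimension d")
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((m, d)) * np.sqrt(2.0 / d)
        grid = cov.grid if cov is not None else None
        if grid is None:
            from .grids import Grid1D

            grid = Grid1D(n_samples=d, dt_ms=1.0)
        return ReceptiveFieldSet(
            W=W, grid=grid, provenance={"kind": "kaiming", "seed": seed}
        )
    if kind == "structured":
        if cov is None:
            raise ValueError("structured init requires a covariance model")
        scaled = normalize_trace(cov, 2.0)
        rfs = sample_weights(scaled, m, seed)
        rfs.provenance["init"] = "structured_trace2"
        return rfs
    raise ValueError(f"unknown init kind: {kind!r}")


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    out = np.zeros((y.size, classes.size))
    out[np.arange(y.size), idx] = 1.0
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_full(
    config: TrainConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> TrainTrace:
    """Full-batch gradient descent on softmax cross-entropy, all weights free.

    The readout is initialized Kaiming-style, N(0, 2/m), for every init
    kind; only the hidden-layer initialization differs between conditions.
    Training loss and test error are recorded every epoch. A NaN loss
    aborts and returns the trace accumulated so far with ``diverged=True``.
    """
    X_train = np.asarray(X_train, dtype=float)
    classes = np.unique(y_train)
    Y = _one_hot(np.asarray(y_train), classes)
    n, d = X_train.shape
    rfs = init_hidden_weights(
        config.init_kind, config.m, config.seed, d=d, cov=config.cov
    )
    W = rfs.W.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    B = rng.standard_normal((config.m, classes.size)) * np.sqrt(2.0 / config.m)
    b0 = np.zeros(classes.size)
    lr = config.learning_rate

    losses, errors = [], []
    with np.errstate(over="ignore", invalid="ignore"):
        return _gd_loop(
            config, X_train, Y, classes, X_test, y_test, W, B, b0, lr, losses,
            errors,
        )


def _gd_loop(config, X_train, Y, classes, X_test, y_test, W, B, b0, lr,
             losses, errors) -> TrainTrace:
    n = X_train.shape[0]
    for _ in range(config.epochs):
        A = X_train @ W.T
        H = np.maximum(A, 0.0)
        logits = H @ B + b0
        P = _softmax(logits)
        # cross-entropy, mean over examples
        loss = float(-np.mean(np.sum(Y * np.log(np.clip(P, 1e-300, None)), axis=1)))
        if not np.isfinite(loss):
            return TrainTrace(
                train_loss=np.asarray(losses),
                test_error=np.asarray(errors),
                diverged=True,
            )
        losses.append(loss)
        pred = classes[
            np.argmax(np.maximum(X_test @ W.T, 0.0) @ B + b0, axis=1)
        ]
        errors.append(float(np.mean(pred != np.asarray(y_test))))

        G = (P - Y) / n  # (n, K)
        grad_B = H.T @ G
        grad_b0 = G.sum(axis=0)
        grad_H = G @ B.T
        grad_A = grad_H * (A > 0)
        grad_W = grad_A.T @ X_train
        W -= lr * grad_W
        B -= lr * grad_B
        b0 -= lr * grad_b0
    return TrainTrace(train_loss=np.asarray(losses), test_error=np.asarray(errors))


def lr_grid_search(
    config: TrainConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    rate_grid: np.ndarray | None = None,
) -> tuple[float, dict[float, float]]:
    """Select the learning rate minimizing area under the training-loss curve.

    ``rate_grid`` defaults to 9 log-spaced rates spanning (1e-4, 1e0).
    Returns the best rate and the full rate -> area table; diverged runs are
    excluded, and all-diverged grids raise.
    """
    if rate_grid is None:
        rate_grid = np.logspace(-4, 0, 9)
    rate_grid = np.asarray(rate_grid, dtype=float)
    if rate_grid.size == 0:
        raise ValueError("rate grid must be nonempty")
    table: dict[float, float] = {}
    best_rate, best_area = None, np.inf
    for lr in rate_grid:
        cfg = TrainConfig(
            m=config.m,
            epochs=config.epochs,
            learning_rate=float(lr),
            init_kind=config.init_kind,
            cov=config.cov,
            seed=config.seed,
        )
        trace = train_full(cfg, X_train, y_train, X_test, y_test)
        if trace.diverged:
            continue
        area = trace.area
        table[float(lr)] = area
        if area < best_area:
            best_area, best_rate = area, float(lr)
    if best_rate is None:
        raise RuntimeError("every learning rate in the grid diverged")
    return best_rate, table
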