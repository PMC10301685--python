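"""Shared feedforward building blocks and the training loop.

All architectures in this package are regression networks trained with
mini-batch Adam on mean squared error, early-stopped on validation RMSE.
They differ only in how the first stages are wired (dense, membership-masked
sparse, or per-pathway attention), so a single ``fit`` routine serves them
all. Networks consume a single float64 design matrix per batch; any
architecture-specific slicing (drug block vs expression block) happens
inside the network's ``forward``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Adam, Parameter, Tensor, relu

__all__ = ["Linear", "TrainConfig", "Network", "fit", "gather_cols"]


class TrainingError(RuntimeError):
    """Raised when training cannot proceed (divergence, empty sets)."""


class Linear:
    """Affine layer, optionally constrained by a binary connection mask.

    The mask (shape in x out) zeroes both the initial weights and all
    gradients, so masked connections stay exactly zero through training.
    Weights use He-uniform initialization scaled by each unit's effective
    fan-in — the number of unmasked incoming connections — so sparse units
    start at a useful scale; with an all-ones mask the draw is numerically
    identical to the dense layer's.
    """

    def __init__(
        self,
        fan_in: int,
        fan_out: int,
        rng: np.random.Generator,
        mask: np.ndarray | None = None,
    ):
        raw = rng.uniform(-1.0, 1.0, size=(fan_in, fan_out))
        if mask is None:
            limit = np.sqrt(6.0 / fan_in)
        else:
            eff = np.maximum(np.asarray(mask).sum(axis=0), 1.0)
            limit = np.sqrt(6.0 / eff)  # per-output-unit scale
        self.W = Parameter(raw * limit, mask=mask)
        self.b = Parameter(np.zeros(fan_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


def gather_cols(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select fixed columns of a (batch, features) tensor."""
    idx = np.asarray(idx, dtype=np.intp)
    out_holder: list[Tensor] = []

    def backward():
        g = np.zeros_like(x.data)
        np.add.at(g, (slice(None), idx), out_holder[0].grad)
        x._accum(g)

    out = Tensor._node(x.data[:, idx], (x,), backward)
    out_holder.append(out)
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate is 0."""
    if rate <= 0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by every trained network.

    Defaults are the package's documented baseline settings; all are
    overridable per experiment.
    """

    hidden: tuple[int, ...] = (128, 64)
    dropout: float = 0.1
    lr: float = 2e-3
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0

    def with_seed(self, seed: int) -> "TrainConfig":
        return replace(self, seed=seed)


class Network:
    """Base class: a stack of layers ending in a scalar regression output."""

    def __init__(self, config: TrainConfig):
        self.config = config
        self._layers: list[Linear] = []

    def parameters(self) -> list[Parameter]:
        return [p for layer in self._layers for p in layer.parameters()]

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).data.ravel()


class DenseHead:
    """Hidden dense stack + scalar output, used as the tail of every model."""

    def __init__(
        self, fan_in: int, hidden: tuple[int, ...], rng: np.random.Generator
    ):
        widths = [fan_in, *hidden]
        self.hidden_layers = [
            Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])
        ]
        self.out = Linear(widths[-1], 1, rng)

    def __call__(
        self, h: Tensor, drop: float = 0.0, rng: np.random.Generator | None = None
    ) -> Tensor:
        for layer in self.hidden_layers:
            h = relu(layer(h))
            if drop > 0 and rng is not None:
                h = dropout(h, drop, rng)
        return self.out(h)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.hidden_layers for p in l.parameters()] + self.out.parameters()


def mse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    diff = pred - Tensor(y.reshape(-1, 1))
    return (diff * diff).mean()


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def fit(
    net: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> FitHistory:
    """Mini-batch Adam training with early stopping on validation RMSE.

    The best-validation weights are restored at the end. Raises
    :class:`TrainingError` on an empty validation set or a non-finite loss.
    """
    cfg = net.config
    if len(X_val) == 0:
        raise TrainingError("validation set is empty")
    rng = np.random.default_rng([cfg.seed, 1])
    opt = Adam(net.parameters(), lr=cfg.lr)
    history = FitHistory()
    best = np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0
    n = len(X_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = net.forward(X_train[idx], training=True, rng=rng)
            loss = mse_loss(pred, y_train[idx])
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_loss.append(epoch_loss / n)
        val_pred = net.predict(X_val)
        val_rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        if not np.isfinite(val_rmse):
            raise TrainingError(f"non-finite validation RMSE at epoch {epoch}")
        history.val_rmse.append(val_rmse)
        if val_rmse < best - 1e-12:
            best = val_rmse
            best_state = [p.data.copy() for p in net.parameters()]
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    history.stopped_epoch = epoch
    if best_state is not None:
        for p, w in zip(net.parameters(), best_state):
            p.data = w
    return history
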