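"""Compact feed-forward network engine on numpy.

The synergy models are plain multilayer perceptrons built from dense stacks:
``affine -> activation -> inverted dropout`` per layer. Several encoder
stacks each consume a designated column slice of the input matrix, their
outputs are concatenated and fed to a predictor stack whose last layer is
linear (regression heads). Training minimizes the mean squared error over
all task outputs with equal weights, using Adamax (default) or Adam, with
early stopping on a validation carve-out.

Everything is seeded through a single :class:`numpy.random.Generator`:
weight initialization, batch shuffling and dropout masks, so two runs with
the same seed and data produce identical histories.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TrainingDiverged",
    "DenseStack",
    "MultiEncoderNet",
    "fit_network",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training or validation loss becomes non-finite."""


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(z.dtype)


def _identity(z: np.ndarray) -> np.ndarray:
    return z


def _ones(z: np.ndarray) -> np.ndarray:
    return np.ones_like(z)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "linear": (_identity, _ones),
    "relu": (_relu, _relu_grad),
}


class DenseStack:
    """A fully connected stack of layers with per-layer activation and dropout.

    Weights are initialized from the uniform fan-in scheme
    ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` (weights and biases alike).
    Dropout uses inverted scaling, so prediction-time forward passes need no
    rescaling and are deterministic.
    """

    def __init__(
        self,
        in_dim: int,
        widths: Sequence[int],
        activations: Sequence[str],
        dropouts: Sequence[float],
        rng: np.random.Generator,
    ) -> None:
        if not (len(widths) == len(activations) == len(dropouts)):
            raise ValueError("widths, activations and dropouts must have equal lengths")
        if not widths:
            raise ValueError("a dense stack needs at least one layer")
        for a in activations:
            if a not in ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}; options: {sorted(ACTIVATIONS)}")
        for p in dropouts:
            if not (0.0 <= p < 1.0):
                raise ValueError("dropout probabilities must lie in [0, 1)")
        self.in_dim = int(in_dim)
        self.activations = tuple(activations)
        self.dropouts = tuple(float(p) for p in dropouts)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        dims = [self.in_dim, *map(int, widths)]
        for din, dout in zip(dims[:-1], dims[1:]):
            bound = 1.0 / math.sqrt(din)
            W = rng.random(size=(din, dout))
            W *= 2.0 * bound
            W -= bound
            b = rng.random(size=dout)
            b *= 2.0 * bound
            b -= bound
            self.W.append(W)
            self.b.append(b)

    @property
    def out_dim(self) -> int:
        return self.W[-1].shape[1]

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        a = x
        caches = []
        for W, b, act, p in zip(self.W, self.b, self.activations, self.dropouts):
            z = a @ W + b
            h = ACTIVATIONS[act][0](z)
            mask = None
            if train and p > 0.0:
                mask = (rng.random(h.shape) >= p).astype(h.dtype) / (1.0 - p)
                h = h * mask
            caches.append((a, z, mask))
            a = h
        return a, caches

    def backward(self, grad_out: np.ndarray, caches: list) -> tuple[np.ndarray, list]:
        """Backpropagate; returns (gradient w.r.t. input, per-layer (dW, db))."""
        grads: list = [None] * len(self.W)
        g = grad_out
        for i in reversed(range(len(self.W))):
            a, z, mask = caches[i]
            if mask is not None:
                g = g * mask
            gz = g * ACTIVATIONS[self.activations[i]][1](z)
            grads[i] = (a.T @ gz, gz.sum(axis=0))
            g = gz @ self.W[i].T
        return g, grads

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.W, self.b):
            out.append(W)
            out.append(b)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class MultiEncoderNet:
    """Several encoder stacks over input slices, concatenated into a predictor."""

    def __init__(
        self,
        encoders: Sequence[tuple[str, slice, DenseStack]],
        predictor: DenseStack,
    ) -> None:
        if not encoders:
            raise ValueError("at least one encoder is required")
        total = sum(stack.out_dim for _, _, stack in encoders)
        if predictor.in_dim != total:
            raise ValueError(
                f"predictor input width {predictor.in_dim} != sum of encoder outputs {total}"
            )
        self.encoders = list(encoders)
        self.predictor = predictor

    @property
    def encoder_names(self) -> list[str]:
        return [name for name, _, _ in self.encoders]

    @property
    def n_tasks(self) -> int:
        return self.predictor.out_dim

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        outs, caches = [], []
        for _, sl, stack in self.encoders:
            h, c = stack.forward(X[:, sl], train=train, rng=rng)
            outs.append(h)
            caches.append(c)
        H = np.concatenate(outs, axis=1)
        out, pc = self.predictor.forward(H, train=train, rng=rng)
        return out, {"encoder_caches": caches, "predictor_cache": pc, "widths": [o.shape[1] for o in outs]}

    def backward(self, grad_out: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients flattened in the order of :meth:`parameters`."""
        gH, pred_grads = self.predictor.backward(grad_out, cache["predictor_cache"])
        splits = np.cumsum(cache["widths"])[:-1]
        parts = np.split(gH, splits, axis=1)
        flat: list[np.ndarray] = []
        for (name, sl, stack), g, c in zip(self.encoders, parts, cache["encoder_caches"]):
            _, grads = stack.backward(g, c)
            for dW, db in grads:
                flat.extend((dW, db))
        for dW, db in pred_grads:
            flat.extend((dW, db))
        return flat

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for _, _, stack in self.encoders:
            out.extend(stack.parameters())
        out.extend(self.predictor.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            if p.shape != s.shape:
                raise ValueError("state shape mismatch")
            p[...] = s

    def predict(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Deterministic evaluation-mode forward pass (dropout inactive)."""
        X = np.asarray(X, dtype=float)
        chunks = []
        for start in range(0, X.shape[0], batch_size):
            out, _ = self.forward(X[start : start + batch_size], train=False)
            chunks.append(out)
        return np.concatenate(chunks, axis=0)

    def encoder_outputs(self, X: np.ndarray, batch_size: int = 2048) -> dict[str, np.ndarray]:
        """Final-layer activations of every encoder (evaluation mode)."""
        X = np.asarray(X, dtype=float)
        collected: dict[str, list[np.ndarray]] = {name: [] for name, _, _ in self.encoders}
        for start in range(0, X.shape[0], batch_size):
            chunk = X[start : start + batch_size]
            for name, sl, stack in self.encoders:
                h, _ = stack.forward(chunk[:, sl], train=False)
                collected[name].append(h)
        return {name: np.concatenate(parts, axis=0) for name, parts in collected.items()}


class _AdamFamily:
    """Adam / Adamax with bias correction, matching the standard formulations."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        learning_rate: float,
        variant: str = "adamax",
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if variant not in ("adam", "adamax"):
            raise ValueError(f"unknown optimizer {variant!r}; use 'adam' or 'adamax'")
        if learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        self.lr = float(learning_rate)
        self.variant = variant
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m[...] = b1 * m + (1.0 - b1) * g
            if self.variant == "adamax":
                np.maximum(b2 * u, np.abs(g), out=u)
                p -= (self.lr / (1.0 - b1**self.t)) * m / (u + self.eps)
            else:
                u[...] = b2 * u + (1.0 - b2) * g * g
                m_hat = m / (1.0 - b1**self.t)
                u_hat = u / (1.0 - b2**self.t)
                p -= self.lr * m_hat / (np.sqrt(u_hat) + self.eps)


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def fit_network(
    net: MultiEncoderNet,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    optimizer: str = "adamax",
    learning_rate: float = 1e-3,
    batch_size: int = 128,
    max_epochs: int = 200,
    patience: int = 10,
    validation_fraction: float = 0.1,
    rng: np.random.Generator,
) -> dict:
    """Train with MSE loss and early stopping; restores the best-validation weights.

    Returns a history dict with per-epoch ``train_loss`` (mean of batch
    losses) and ``val_loss``, plus the index of the best epoch.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != net.n_tasks:
        raise ValueError(f"Y must have shape (n, {net.n_tasks})")
    n = X.shape[0]
    if n == 0:
        raise ValueError("no training samples")
    if not (0.0 < validation_fraction <= 0.5):
        raise ValueError("validation_fraction must lie in (0, 0.5]")
    n_val = max(1, int(round(validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training samples")
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[train_idx], Y[train_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    params = net.parameters()
    opt = _AdamFamily(params, learning_rate, variant=optimizer)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = net.get_state()
    best_epoch = -1
    bad_epochs = 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(X_tr))
        batch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            out, cache = net.forward(X_tr[idx], train=True, rng=rng)
            err = out - Y_tr[idx]
            loss = float(np.mean(err**2))
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}, batch {start // batch_size} "
                    f"(optimizer={optimizer}, lr={learning_rate})"
                )
            grads = net.backward((2.0 / err.size) * err, cache)
            opt.step(params, grads)
            batch_losses.append(loss)
        val_loss = _mse(net.predict(X_val), Y_val)
        if not math.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > patience:
                break
    net.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return history
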