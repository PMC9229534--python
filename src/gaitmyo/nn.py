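"""Feed-forward network for per-cycle activity regression.

A deliberately small, dependency-free multilayer perceptron: fully connected
hidden layers with a configurable activation, a linear single output, Adam
or plain SGD, and log-cosh / MSE / MAE losses.  The regularizer randomly
discards a fraction of the *connections between nodes* during training
(inverted scaling keeps activations unbiased; inference uses the full
network).  Connection-level masking is the default because in layers only
twelve units wide deleting whole units destroys most of the network's
capacity, while deleting 20% of each unit's incoming weights regularizes
without crippling it; classic unit dropout is available as
``dropout_kind="unit"``.  Log-cosh behaves like a smooth
L2 near zero and like L1 in the tails, which makes the fit robust to the
occasional mis-segmented gait cycle.  Training supports mini-batches and
early stopping on a held-out slice of the training data with best-weight
restoration.  All randomness flows from one seeded generator, so a fixed
seed reproduces weights bit-for-bit on a fixed numpy version.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, NumericalError

ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
}

#: loss(e) and dloss/de for residual e = prediction - target (per-sample mean taken outside)
LOSSES = {
    "logcosh": (lambda e: np.logaddexp(e, -e) - np.log(2.0), np.tanh),
    "mse": (lambda e: e**2, lambda e: 2.0 * e),
    "mae": (np.abs, np.sign),
}

OPTIMIZERS = ("adam", "sgd")


@dataclass
class Hyperparams:
    """Network and training configuration.

    Defaults are the tuned combination for this problem: seven hidden layers
    of twelve rectified-linear units, Adam on a log-cosh loss, and 20% of
    connections dropped during training for robustness.
    """

    n_hidden_layers: int = 7
    n_units: int = 12
    activation: str = "relu"
    optimizer: str = "adam"
    loss: str = "logcosh"
    dropout_rate: float = 0.2
    dropout_kind: str = "connection"  # "connection" (weights) or "unit" (activations)
    epochs: int = 1000
    batch_size: int = 32
    patience: int = 50
    learning_rate: float = 1e-3
    val_fraction: float = 0.1  # slice of the training data watched for early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ConfigError(
                f"unknown activation {self.activation!r}; supported: {sorted(ACTIVATIONS)}"
            )
        if self.loss not in LOSSES:
            raise ConfigError(f"unknown loss {self.loss!r}; supported: {sorted(LOSSES)}")
        if self.optimizer not in OPTIMIZERS:
            raise ConfigError(
                f"unknown optimizer {self.optimizer!r}; supported: {sorted(OPTIMIZERS)}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.dropout_kind not in ("connection", "unit"):
            raise ConfigError("dropout_kind must be 'connection' or 'unit'")
        if self.n_hidden_layers < 1 or self.n_units < 1:
            raise ConfigError("layer and unit counts must be >= 1")

    def replace(self, **kw) -> "Hyperparams":
        return replace(self, **kw)


@dataclass
class MLP:
    """Weights + shape of a feed-forward regressor."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hyperparams: Hyperparams
    n_features: int
    n_outputs: int = 1
    history: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    # -- forward ------------------------------------------------------------
    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Returns (output, cache).  Stochastic masking is active only when a
        generator is given (training); inference runs the full network.

        cache entries per layer: (input, pre-activation, unit mask,
        effective weight matrix, weight mask)."""
        act, _ = ACTIVATIONS[self.hyperparams.activation]
        hp = self.hyperparams
        p = hp.dropout_rate if rng is not None else 0.0
        a = X
        cache = []
        for li in range(len(self.weights) - 1):
            W, wmask = self.weights[li], None
            if p > 0.0 and hp.dropout_kind == "connection":
                # one mask per mini-batch: drop individual connections
                wmask = (rng.random(W.shape) >= p) / (1.0 - p)
                W = W * wmask
            z = a @ W + self.biases[li]
            h = act(z)
            umask = None
            if p > 0.0 and hp.dropout_kind == "unit":
                umask = (rng.random(h.shape) >= p) / (1.0 - p)
                h = h * umask
            cache.append((a, z, umask, W, wmask))
            a = h
        out = a @ self.weights[-1] + self.biases[-1]
        cache.append((a, None, None, self.weights[-1], None))
        return out, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference (no connections dropped)."""
        out, _ = self._forward(np.asarray(X, dtype=float))
        return out[:, 0] if self.n_outputs == 1 else out

    # -- backward -----------------------------------------------------------
    def _gradients(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        _, dact = ACTIVATIONS[self.hyperparams.activation]
        _, dloss = LOSSES[self.hyperparams.loss]
        out, cache = self._forward(X, rng=rng)
        n = X.shape[0]
        delta = dloss(out - y.reshape(out.shape)) / n
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        for li in range(len(self.weights) - 1, -1, -1):
            a_in, _, _, W_eff, wmask = cache[li]
            g = a_in.T @ delta
            gW[li] = g * wmask if wmask is not None else g
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ W_eff.T
                _, z_prev, umask_prev, _, _ = cache[li - 1]
                if umask_prev is not None:
                    delta = delta * umask_prev
                delta = delta * dact(z_prev)
        return gW, gb

    def loss_value(self, X: np.ndarray, y: np.ndarray) -> float:
        loss, _ = LOSSES[self.hyperparams.loss]
        pred = self.predict(X)
        return float(np.mean(loss(pred - np.asarray(y, dtype=float))))


def build_network(hyperparams: Hyperparams, n_features: int, n_outputs: int = 1) -> MLP:
    """Untrained network with shape-appropriate (He/Xavier) initialization."""
    hp = hyperparams
    rng = np.random.default_rng(hp.seed)
    sizes = [n_features] + [hp.n_units] * hp.n_hidden_layers + [n_outputs]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in) if hp.activation == "relu" else np.sqrt(1.0 / fan_in)
        weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLP(weights=weights, biases=biases, hyperparams=hp, n_features=n_features,
               n_outputs=n_outputs)


def train_network(
    net: MLP, X: np.ndarray, y: np.ndarray, verbose: bool = False
) -> MLP:
    """Mini-batch training with early stopping; modifies and returns ``net``.

    A ``val_fraction`` slice of (X, y) is held out to monitor generalization;
    training stops once its loss has not improved for ``patience`` epochs and
    the best-scoring weights are restored.  Non-finite losses abort with
    diagnostics.
    """
    hp = net.hyperparams
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise NumericalError(f"bad training shapes X{X.shape}, y{y.shape}")
    rng = np.random.default_rng(hp.seed)

    n_val = int(round(hp.val_fraction * X.shape[0]))
    perm = rng.permutation(X.shape[0])
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    monitor = (Xval, yval) if n_val >= 2 else (Xtr, ytr)

    m, v = None, None
    if hp.optimizer == "adam":
        m = [np.zeros_like(w) for w in net.weights + net.biases]
        v = [np.zeros_like(w) for w in net.weights + net.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_loss, best_state, since_best = np.inf, None, 0
    history = {"loss": [], "val_loss": []}

    for epoch in range(hp.epochs):
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], hp.batch_size):
            batch = order[start : start + hp.batch_size]
            gW, gb = net._gradients(Xtr[batch], ytr[batch], rng)
            grads = gW + gb
            params = net.weights + net.biases
            step += 1
            for i, (p_arr, g_arr) in enumerate(zip(params, grads)):
                if hp.optimizer == "adam":
                    m[i] = beta1 * m[i] + (1 - beta1) * g_arr
                    v[i] = beta2 * v[i] + (1 - beta2) * g_arr**2
                    mhat = m[i] / (1 - beta1**step)
                    vhat = v[i] / (1 - beta2**step)
                    p_arr -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
                else:
                    p_arr -= hp.learning_rate * g_arr

        tr_loss = net.loss_value(Xtr, ytr)
        val_loss = net.loss_value(*monitor)
        history["loss"].append(tr_loss)
        history["val_loss"].append(val_loss)
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise NumericalError(
                f"non-finite loss at epoch {epoch} (train={tr_loss}, val={val_loss}); "
                f"lr={hp.learning_rate}, loss={hp.loss}"
            )
        if val_loss < best_loss - 1e-12:
            best_loss, since_best = val_loss, 0
            best_state = ([w.copy() for w in net.weights], [b.copy() for b in net.biases])
        else:
            since_best += 1
            if since_best >= hp.patience:
                break
        if verbose and epoch % 50 == 0:
            print(f"epoch {epoch}: loss={tr_loss:.5f} val={val_loss:.5f}")

    if best_state is not None:
        net.weights, net.biases = best_state
    net.history = history
    return net
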