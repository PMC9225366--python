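"""MLP regression from per-vertex strain invariants to muscle activity.

A deliberately light network - three hidden ReLU layers with dropout - maps a
frame's strain-invariant vector (restricted to a reliable axial band of the
template) to the normalized activity of two muscles.  Training uses plain
stochastic gradient descent on the mean squared error, Gaussian weight
initialisation, and treats all frames of one action as a single batch (one
gradient step per action per epoch).  Inputs are standardized per feature
using training-set statistics.  Dropout is disabled at inference, so
prediction is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh


@dataclass
class PredictorConfig:
    """Architecture and training settings of the strain-to-activity MLP."""

    input_dim: int
    hidden_layers: tuple = (512, 128, 32)
    output_dim: int = 2
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) != 3:
            raise ValueError("the network uses exactly three hidden layers")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def select_vertices(template: SurfaceMesh, axial_band: tuple[float, float],
                    axis: int = 2) -> np.ndarray:
    """Indices of template vertices whose axial coordinate lies in the band.

    Restricts the strain input to the reliable mid-section of the surface
    (scan sequences typically lose the top and bottom of the field of view).
    Deterministic ascending order.
    """
    lo, hi = axial_band
    if hi <= lo:
        raise ValueError("empty axial band")
    z = template.vertices[:, axis]
    idx = np.flatnonzero((z >= lo) & (z <= hi))
    if len(idx) == 0:
        raise ValueError("axial band selects no vertices")
    return idx


class _MLP:
    """Bare numpy MLP: ReLU hiddens, linear output, inverted dropout."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.W = [rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                             size=(dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def forward(self, X: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Returns (output, cache) - cache holds activations and dropout masks."""
        h = X
        cache = []
        L = len(self.W)
        for layer, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if layer < L - 1:
                a = np.maximum(z, 0.0)
                if dropout > 0.0:
                    mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                    a = a * mask
                else:
                    mask = None
                cache.append((h, z, mask))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h, cache

    def backward(self, grad_out: np.ndarray, cache, dropout: float):
        """Gradients of the loss w.r.t. all weights, given d(loss)/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        for layer in reversed(range(len(self.W))):
            h_in, z, mask = cache[layer]
            if layer < len(self.W) - 1:
                if mask is not None:
                    g = g * mask
                g = g * (z > 0)
            gW[layer] = h_in.T @ g
            gb[layer] = g.sum(axis=0)
            g = g @ self.W[layer].T
        return gW, gb

    def sgd_step(self, gW, gb, lr: float) -> None:
        for layer in range(len(self.W)):
            self.W[layer] -= lr * gW[layer]
            self.b[layer] -= lr * gb[layer]


@dataclass
class PredictorResults:
    """A trained strain-to-activity network with its normalisation statistics."""

    config: PredictorConfig
    weights: list = field(repr=False)
    biases: list = field(repr=False)
    feature_mean: np.ndarray = field(repr=False)
    feature_std: np.ndarray = field(repr=False)
    loss_history: np.ndarray = field(repr=False)

    def _net(self) -> _MLP:
        net = _MLP.__new__(_MLP)
        net.W, net.b = self.weights, self.biases
        return net

    def predict(self, strain: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off) on one frame or a batch."""
        X = np.atleast_2d(np.asarray(strain, float))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim} strain inputs, got {X.shape[1]}")
        Xs = (X - self.feature_mean) / self.feature_std
        out, _ = self._net().forward(Xs)
        return out[0] if np.asarray(strain).ndim == 1 else out

    def summary(self) -> str:
        c = self.config
        lines = [
            "Strain-to-activity MLP",
            "=" * 30,
            f"architecture        {c.input_dim} -> "
            + " -> ".join(map(str, c.hidden_layers)) + f" -> {c.output_dim}",
            f"dropout             {c.dropout_rate}",
            f"epochs              {c.epochs} (SGD, lr={c.learning_rate})",
            f"final training MSE  {self.loss_history[-1]:.5g}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize config, weights and normalisation statistics to JSON."""
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "loss_history": self.loss_history.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PredictorResults":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        return cls(PredictorConfig(**cfg),
                   [np.asarray(W) for W in payload["weights"]],
                   [np.asarray(b) for b in payload["biases"]],
                   np.asarray(payload["feature_mean"]),
                   np.asarray(payload["feature_std"]),
                   np.asarray(payload["loss_history"]))


class ActivityPredictor:
    """Model object: learn muscle activity from per-frame strain vectors.

    Parameters
    ----------
    strain_by_action : list of (frames, input_dim) arrays
        Strain-invariant inputs, one matrix per recorded action.
    activity_by_action : list of (frames, output_dim) arrays
        MVC-normalized activity targets aligned to the strain frames.
    config : PredictorConfig, optional
        Built from the data dimensions if omitted.
    """

    def __init__(self, strain_by_action, activity_by_action,
                 config: PredictorConfig | None = None):
        if len(strain_by_action) < 1:
            raise ValueError("need at least one action")
        if len(strain_by_action) != len(activity_by_action):
            raise ValueError("strain and activity action counts differ")
        self.X = [np.asarray(x, float) for x in strain_by_action]
        self.Y = [np.atleast_2d(np.asarray(y, float)) for y in activity_by_action]
        for x, y in zip(self.X, self.Y):
            if x.shape[0] != y.shape[0]:
                raise ValueError("frames per action must match between strain "
                                 "and activity")
            if not np.isfinite(x).all():
                raise ValueError("strain inputs contain missing values; filter "
                                 "vertices first")
        input_dim = self.X[0].shape[1]
        output_dim = self.Y[0].shape[1]
        self.config = config or PredictorConfig(input_dim, output_dim=output_dim)
        if self.config.input_dim != input_dim:
            raise ValueError(f"config.input_dim={self.config.input_dim} but data "
                             f"has {input_dim} features")

    def fit(self) -> PredictorResults:
        """SGD on the MSE, one gradient step per action per epoch."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        Xall = np.concatenate(self.X)
        mean = Xall.mean(axis=0)
        std = Xall.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        Xs = [(x - mean) / std for x in self.X]

        dims = [cfg.input_dim, *cfg.hidden_layers, cfg.output_dim]
        net = _MLP(dims, rng)
        loss_history = np.empty(cfg.epochs)
        n_actions = len(Xs)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n_actions)
            total, count = 0.0, 0
            for a in order:
                X, Y = Xs[a], self.Y[a]
                out, cache = net.forward(X, cfg.dropout_rate, rng)
                err = out - Y
                loss = float((err**2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf training loss at epoch {epoch}")
                grad = 2.0 * err / err.size
                gW, gb = net.backward(grad, cache, cfg.dropout_rate)
                net.sgd_step(gW, gb, cfg.learning_rate)
                total += loss * len(X)
                count += len(X)
            loss_history[epoch] = total / count
        return PredictorResults(cfg, net.W, net.b, mean, std, loss_history)
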