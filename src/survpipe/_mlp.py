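"""Minimal seeded multilayer perceptron with Adam, dropout and batch norm.

Kept deliberately small: dense layers with ReLU, inverted dropout, optional
batch normalisation with running statistics, and a linear output head.  The
caller supplies the loss gradient with respect to the raw outputs, so the
same backbone serves any head (here: softplus interval hazards).
All randomness flows through a caller-provided Generator, which makes
training bit-reproducible for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

_BN_EPS = 1e-5


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray
    # batch-norm parameters (None when disabled)
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    run_mean: np.ndarray | None = None
    run_var: np.ndarray | None = None


class MLP:
    """Fully connected network: input -> hidden... -> linear output."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...],
        out_dim: int,
        *,
        dropout: float = 0.0,
        batch_norm: bool = False,
        rng: np.random.Generator,
    ) -> None:
        if dropout < 0 or dropout >= 1:
            raise ValueError("dropout must be in [0, 1)")
        self.dropout = float(dropout)
        self.batch_norm = bool(batch_norm)
        self.layers: list[_Layer] = []
        dims = [in_dim, *hidden, out_dim]
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / max(d_in, 1))  # He init; input dim may be 0
            layer = _Layer(
                W=rng.normal(0.0, scale, size=(d_in, d_out)),
                b=np.zeros(d_out),
            )
            if self.batch_norm and i < len(dims) - 2:  # hidden layers only
                layer.gamma = np.ones(d_out)
                layer.beta = np.zeros(d_out)
                layer.run_mean = np.zeros(d_out)
                layer.run_var = np.ones(d_out)
            self.layers.append(layer)
        self._adam_m: list[dict[str, np.ndarray]] | None = None
        self._adam_v: list[dict[str, np.ndarray]] | None = None
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def forward(
        self, X: np.ndarray, *, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Forward pass; caches intermediates when training for backward()."""
        self._cache: list[dict] = []
        h = X
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            z = h @ layer.W + layer.b
            cache: dict = {"x": h}
            if i < last:
                if layer.gamma is not None:
                    if training:
                        mean = z.mean(axis=0)
                        var = z.var(axis=0)
                        layer.run_mean = 0.9 * layer.run_mean + 0.1 * mean
                        layer.run_var = 0.9 * layer.run_var + 0.1 * var
                    else:
                        mean, var = layer.run_mean, layer.run_var
                    zhat = (z - mean) / np.sqrt(var + _BN_EPS)
                    cache.update(zhat=zhat, var=var)
                    z = layer.gamma * zhat + layer.beta
                a = np.maximum(z, 0.0)
                cache["relu_mask"] = z > 0
                if training and self.dropout > 0:
                    keep = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                    a = a * keep
                    cache["drop"] = keep
                h = a
            else:
                h = z
            self._cache.append(cache)
        return h

    # --------------------------------------------------------------- backward

    def backward(self, grad_out: np.ndarray) -> list[dict[str, np.ndarray]]:
        """Backprop a gradient w.r.t. the raw outputs; returns per-layer grads."""
        grads: list[dict[str, np.ndarray]] = [dict() for _ in self.layers]
        g = grad_out
        last = len(self.layers) - 1
        for i in range(last, -1, -1):
            layer, cache = self.layers[i], self._cache[i]
            if i < last:
                if "drop" in cache:
                    g = g * cache["drop"]
                g = g * cache["relu_mask"]
                if layer.gamma is not None:
                    zhat, var = cache["zhat"], cache["var"]
                    grads[i]["gamma"] = (g * zhat).sum(axis=0)
                    grads[i]["beta"] = g.sum(axis=0)
                    n = g.shape[0]
                    gz = g * layer.gamma
                    inv = 1.0 / np.sqrt(var + _BN_EPS)
                    g = inv * (gz - gz.mean(axis=0) - zhat * (gz * zhat).mean(axis=0))
            grads[i]["W"] = cache["x"].T @ g
            grads[i]["b"] = g.sum(axis=0)
            g = g @ layer.W.T
        return grads

    # ------------------------------------------------------------------- adam

    def adam_step(
        self, grads: list[dict[str, np.ndarray]], lr: float, beta1: float = 0.9,
        beta2: float = 0.999, eps: float = 1e-8,
    ) -> None:
        if self._adam_m is None:
            self._adam_m = [{k: np.zeros_like(v) for k, v in g.items()} for g in grads]
            self._adam_v = [{k: np.zeros_like(v) for k, v in g.items()} for g in grads]
        self._adam_t += 1
        t = self._adam_t
        for layer, g, m, v in zip(self.layers, grads, self._adam_m, self._adam_v):
            for key, grad in g.items():
                m[key] = beta1 * m[key] + (1 - beta1) * grad
                v[key] = beta2 * v[key] + (1 - beta2) * grad**2
                mhat = m[key] / (1 - beta1**t)
                vhat = v[key] / (1 - beta2**t)
                param = getattr(layer, key) if key in ("W", "b") else getattr(layer, key)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    def reset_optimizer(self) -> None:
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    def clone(self) -> "MLP":
        """Deep copy of parameters and optimizer state."""
        return copy.deepcopy(self)

    # --------------------------------------------------------- (de)serialise

    def state(self) -> dict:
        out = {"dropout": self.dropout, "batch_norm": self.batch_norm, "layers": []}
        for layer in self.layers:
            d = {"W": layer.W.tolist(), "b": layer.b.tolist()}
            if layer.gamma is not None:
                d.update(
                    gamma=layer.gamma.tolist(), beta=layer.beta.tolist(),
                    run_mean=layer.run_mean.tolist(), run_var=layer.run_var.tolist(),
                )
            out["layers"].append(d)
        return out

    @classmethod
    def from_state(cls, state: dict) -> "MLP":
        obj = cls.__new__(cls)
        obj.dropout = state["dropout"]
        obj.batch_norm = state["batch_norm"]
        obj.layers = []
        for d in state["layers"]:
            layer = _Layer(W=np.asarray(d["W"], dtype=float), b=np.asarray(d["b"], dtype=float))
            if "gamma" in d:
                layer.gamma = np.asarray(d["gamma"], dtype=float)
                layer.beta = np.asarray(d["beta"], dtype=float)
                layer.run_mean = np.asarray(d["run_mean"], dtype=float)
                layer.run_var = np.asarray(d["run_var"], dtype=float)
            obj.layers.append(layer)
        obj._adam_m = None
        obj._adam_v = None
        obj._adam_t = 0
        return obj
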