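"""Feed-forward decoder with explicit backpropagation, and Adam.

The decoder maps a latent vector through fully connected layers with a
rectifier after every layer, including the output, so the final activations
are nonnegative per-gene relative expression levels. Gradients are computed
by hand because the package carries no autodiff dependency; a finite-
difference check in the test suite guards the derivation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Decoder", "Adam"]


class Decoder:
    """ReLU multilayer perceptron ``D → hidden... → G`` with ReLU output.

    Weights are initialized uniform in ``±1/sqrt(fan_in)`` (the standard
    fan-in scheme); hidden biases likewise; the output bias is set to a
    small positive constant (0.1) so every gene starts with a live,
    positive mean and receives gradient from the first step.
    """

    OUTPUT_BIAS_INIT = 0.1

    def __init__(self, layer_widths: Sequence[int], rng: np.random.Generator):
        widths = list(layer_widths)
        if len(widths) < 2 or any(w < 1 for w in widths):
            raise ValueError("layer widths must be >= 1 with >= 2 layers")
        self.widths = widths
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            if i == len(widths) - 2:
                self.biases.append(np.full(fan_out, self.OUTPUT_BIAS_INIT))
            else:
                self.biases.append(rng.uniform(-bound, bound, size=fan_out))
        self._cache: list[np.ndarray] | None = None

    @property
    def latent_dim(self) -> int:
        return self.widths[0]

    @property
    def output_dim(self) -> int:
        return self.widths[-1]

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, z: np.ndarray, cache: bool = False) -> np.ndarray:
        """Activations of the output layer for latent rows ``z`` (N×D)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent dimension mismatch: got {z.shape[1]}, "
                f"expected {self.latent_dim}"
            )
        acts = [z]
        h = z
        for w, b in zip(self.weights, self.biases):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        self._cache = acts if cache else None
        return h

    def backward(self, grad_out: np.ndarray):
        """Backpropagate ``dL/d(output)`` from the last cached forward.

        Returns ``(grad_z, grad_weights, grad_biases)``. The subgradient of
        the rectifier at 0 is taken as 0.
        """
        if self._cache is None:
            raise RuntimeError("forward(cache=True) must precede backward()")
        acts = self._cache
        g = np.asarray(grad_out, dtype=float)
        grad_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        grad_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore
        for i in range(len(self.weights) - 1, -1, -1):
            g = g * (acts[i + 1] > 0)  # through the layer's ReLU
            grad_w[i] = acts[i].T @ g
            grad_b[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return g, grad_w, grad_b

    def copy(self) -> "Decoder":
        new = object.__new__(Decoder)
        new.widths = list(self.widths)
        new.weights = [w.copy() for w in self.weights]
        new.biases = [b.copy() for b in self.biases]
        new._cache = None
        return new


class Adam:
    """Adam over a list of parameter arrays, updated in place.

    Matches the standard algorithm with bias correction; the model uses
    betas (0.5, 0.9) throughout.
    """

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        betas: tuple[float, float] = (0.5, 0.9),
        eps: float = 1e-8,
    ):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = np.zeros(len(params), dtype=int)
        # per-row step counts, created lazily for row-indexed updates
        self.t_rows: dict[int, np.ndarray] = {}

    def step(self, grads: list[np.ndarray], indices=None) -> None:
        """Apply one update from ``grads`` (same order as ``params``).

        ``indices`` optionally restricts the update of each parameter to a
        row subset (used for per-sample representation rows, so moment
        state advances only for rows that actually received a gradient).
        """
        if self.lr == 0.0:
            return
        for i, g in enumerate(grads):
            if g is None:
                continue
            p, m, v = self.params[i], self.m[i], self.v[i]
            if indices is None:
                self.t[i] += 1
                t = self.t[i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**t)
                vhat = v / (1 - self.b2**t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            else:
                idx = indices[i]
                if i not in self.t_rows:
                    self.t_rows[i] = np.zeros(p.shape[0], dtype=int)
                self.t_rows[i][idx] += 1
                t = self.t_rows[i][idx][:, None]
                m[idx] = self.b1 * m[idx] + (1 - self.b1) * g
                v[idx] = self.b2 * v[idx] + (1 - self.b2) * g * g
                mhat = m[idx] / (1 - self.b1**t)
                vhat = v[idx] / (1 - self.b2**t)
                p[idx] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
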