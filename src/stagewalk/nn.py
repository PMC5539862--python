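"""A small feed-forward network trained with resilient backpropagation.

Architecture: fully connected layers with logistic (sigmoid) activations
throughout, including the output layer; one bias unit per layer; squared
error loss E = 0.5 * sum (o - y)^2.

Training is Rprop+ (resilient backpropagation with weight backtracking):
each weight keeps its own step size, grown by ``eta_plus`` while the
partial derivative keeps its sign and shrunk by ``eta_minus`` when it flips;
on a sign flip the previous update is undone if the error increased.  Only
the sign of the gradient is used, which makes training insensitive to the
scale of the (standardised) inputs.  Training stops when the largest
absolute partial derivative falls below ``threshold`` or after
``max_iter`` full-batch iterations; non-convergence is flagged, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class RpropNet:
    hidden: tuple[int, ...] = (175,)
    n_outputs: int = 1
    max_iter: int = 1000
    threshold: float = 0.01  # stop when max |dE/dw| drops below this
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_init: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-9
    seed: int = 0
    weights: list[np.ndarray] = field(default_factory=list, repr=False)
    converged: bool = False
    n_iter: int = 0

    def _init_weights(self, n_inputs: int) -> None:
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        sizes = [n_inputs, *self.hidden, self.n_outputs]
        self.weights = [
            rng.normal(0.0, 0.5, size=(sizes[i] + 1, sizes[i + 1]))  # +1: bias row
            for i in range(len(sizes) - 1)
        ]

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for w in self.weights:
            a = np.hstack([acts[-1], np.ones((acts[-1].shape[0], 1))])
            acts.append(_sigmoid(a @ w))
        return acts

    def _gradients(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[list[np.ndarray], float]:
        acts = self._forward(x)
        out = acts[-1]
        err = 0.5 * float(np.sum((out - y) ** 2))
        delta = (out - y) * out * (1.0 - out)
        grads: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        for k in range(len(self.weights) - 1, -1, -1):
            a = np.hstack([acts[k], np.ones((acts[k].shape[0], 1))])
            grads[k] = a.T @ delta
            if k > 0:
                back = delta @ self.weights[k][:-1].T  # drop bias row
                delta = back * acts[k] * (1.0 - acts[k])
        return grads, err

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RpropNet":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite training features")
        self._init_weights(x.shape[1])

        deltas = [np.full_like(w, self.delta_init) for w in self.weights]
        prev_grads = [np.zeros_like(w) for w in self.weights]
        prev_steps = [np.zeros_like(w) for w in self.weights]
        prev_err = np.inf
        self.converged = False

        for it in range(1, self.max_iter + 1):
            grads, err = self._gradients(x, y)
            gmax = max(float(np.max(np.abs(g))) for g in grads)
            if gmax < self.threshold:
                self.converged = True
                self.n_iter = it
                return self
            for w, g, gp, d, sp in zip(
                self.weights, grads, prev_grads, deltas, prev_steps
            ):
                sign = np.sign(g)
                prod = gp * g
                inc, dec = prod > 0, prod < 0
                d[inc] = np.minimum(d[inc] * self.eta_plus, self.delta_max)
                d[dec] = np.maximum(d[dec] * self.eta_minus, self.delta_min)
                step = -sign * d
                if err > prev_err:  # weight backtracking on sign change
                    step[dec] = -sp[dec]
                else:
                    step[dec] = 0.0
                g = g.copy()
                g[dec] = 0.0  # skip an adaptation step after a flip
                w += step
                sp[:] = step
                gp[:] = g
            prev_err = err
        self.n_iter = self.max_iter
        return self

    def predict_raw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self._forward(x)[-1]
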