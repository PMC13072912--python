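"""A small deterministic feed-forward network trained with full-batch Adam.

Implemented directly in numpy so that runs are bit-reproducible from a
single integer seed: fan-in uniform initialization, inverted dropout on
the hidden layers, and RMSE (over all outputs jointly) as the loss.
"""

from __future__ import annotations

import numpy as np

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8


class MLP:
    """Fully connected ReLU network; state is a flat list of (W, b) pairs."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        self.layer_sizes = list(layer_sizes)
        self.params: list[list[np.ndarray]] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            b = rng.uniform(-bound, bound, size=fan_out)
            self.params.append([W, b])

    @property
    def n_layers(self) -> int:
        return len(self.params)

    def forward(self, X: np.ndarray, dropout_p: float = 0.0,
                rng: np.random.Generator | None = None):
        """Return (output, cache); dropout is applied only when p > 0."""
        a = X
        acts = [a]
        masks: list[np.ndarray | None] = []
        for li, (W, b) in enumerate(self.params):
            z = a @ W + b
            if li < self.n_layers - 1:
                a = np.maximum(z, 0.0)
                if dropout_p > 0.0:
                    mask = (rng.random(a.shape) >= dropout_p) / (1.0 - dropout_p)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z
            acts.append(a)
        return acts[-1], (acts, masks)

    def backward(self, grad_out: np.ndarray, cache) -> list[list[np.ndarray]]:
        """Gradients of the loss w.r.t. every parameter, reusing the cache."""
        acts, masks = cache
        g = grad_out
        grads: list[list[np.ndarray] | None] = [None] * self.n_layers
        for li in range(self.n_layers - 1, -1, -1):
            a_in = acts[li]
            grads[li] = [a_in.T @ g, g.sum(axis=0)]
            if li > 0:
                g = g @ self.params[li][0].T
                if masks[li - 1] is not None:
                    g = g * masks[li - 1]
                g = g * (acts[li] > 0)
        return grads  # type: ignore[return-value]

    def state(self) -> list[list[np.ndarray]]:
        return [[W.copy(), b.copy()] for W, b in self.params]

    def load_state(self, state: list[list[np.ndarray]]) -> None:
        self.params = [[W.copy(), b.copy()] for W, b in state]


class Adam:
    """Adaptive-moment optimizer over an MLP's parameter list."""

    def __init__(self, net: MLP, lr: float):
        self.net = net
        self.lr = lr
        self.t = 0
        self.m = [[np.zeros_like(p) for p in pair] for pair in net.params]
        self.v = [[np.zeros_like(p) for p in pair] for pair in net.params]

    def step(self, grads: list[list[np.ndarray]]) -> None:
        self.t += 1
        c1 = 1.0 - ADAM_BETA1 ** self.t
        c2 = 1.0 - ADAM_BETA2 ** self.t
        for li, pair in enumerate(self.net.params):
            for pi in range(2):
                g = grads[li][pi]
                self.m[li][pi] = ADAM_BETA1 * self.m[li][pi] + (1 - ADAM_BETA1) * g
                self.v[li][pi] = ADAM_BETA2 * self.v[li][pi] + (1 - ADAM_BETA2) * g * g
                mh = self.m[li][pi] / c1
                vh = self.v[li][pi] / c2
                pair[pi] -= self.lr * mh / (np.sqrt(vh) + ADAM_EPS)
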