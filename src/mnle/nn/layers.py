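"""Feed-forward building blocks and an Adam optimizer."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected network with ReLU (default) or tanh hidden layers.

    Weights use Glorot-uniform initialization drawn from ``rng`` so that
    construction is reproducible from a seed.
    """

    def __init__(self, in_dim: int, hidden: tuple[int, ...], out_dim: int,
                 rng: np.random.Generator, activation: str = "relu"):
        dims = [in_dim, *hidden, out_dim]
        self.dims = dims
        if activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (d_in + d_out))
            self.weights.append(Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                                       requires_grad=True))
            self.biases.append(Tensor(np.zeros(d_out), requires_grad=True))

    @property
    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n - 1:
                h = h.relu() if self.activation == "relu" else h.tanh()
        return h

    def forward_numpy(self, x: np.ndarray) -> np.ndarray:
        """Gradient-free forward pass for evaluation and sampling."""
        h = np.asarray(x, dtype=float)
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w.data + b.data
            if i < n - 1:
                h = np.maximum(h, 0.0) if self.activation == "relu" else np.tanh(h)
        return h

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w.data.copy()
            out[f"b{i}"] = b.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if state[f"w{i}"].shape != w.data.shape:
                raise ValueError(
                    f"weight shape mismatch at layer {i}: "
                    f"{state[f'w{i}'].shape} vs {w.data.shape}"
                )
            w.data = state[f"w{i}"].copy()
            b.data = state[f"b{i}"].copy()


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
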