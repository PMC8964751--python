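"""Neural-network building blocks on top of the autodiff core.

Layers hold :class:`Parameter` tensors and are callable on :class:`Tensor`
inputs.  Initialization is Glorot-uniform and fully determined by the
numpy ``Generator`` passed in, which is what makes whole training runs
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Parameter", "Linear", "MLP", "TypedMLP", "GRUCell", "Adam", "glorot"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(shape, rng: np.random.Generator, fan_in: int | None = None,
           fan_out: int | None = None) -> np.ndarray:
    fan_in = shape[-2] if fan_in is None else fan_in
    fan_out = shape[-1] if fan_out is None else fan_out
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(glorot((in_dim, out_dim), rng))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Two-layer perceptron with ELU after the hidden layer.

    ``final_activation`` adds an ELU on the output as well (used for the
    message-passing maps, where the embedding stays in activation space);
    output heads keep it off.
    """

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator, final_activation: bool = True):
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng)
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        h = self.fc1(x).elu()
        out = self.fc2(h)
        return out.elu() if self.final_activation else out


class TypedMLP(Module):
    """A bank of per-edge-type two-layer perceptrons evaluated in one batched
    matmul: weights are stacked along a leading type axis."""

    def __init__(self, n_types: int, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator):
        self.n_types = n_types
        self.w1 = Parameter(
            glorot((n_types, in_dim, hidden_dim), rng, fan_in=in_dim, fan_out=hidden_dim)
        )
        self.b1 = Parameter(np.zeros((n_types, 1, hidden_dim)))
        self.w2 = Parameter(
            glorot((n_types, hidden_dim, out_dim), rng, fan_in=hidden_dim, fan_out=out_dim)
        )
        self.b2 = Parameter(np.zeros((n_types, 1, out_dim)))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (rows, in_dim) -> (n_types, rows, out_dim)."""
        rows, in_dim = x.shape
        x3 = x.reshape(1, rows, in_dim)
        h = (x3 @ self.w1 + self.b1).elu()
        return (h @ self.w2 + self.b2).elu()


class GRUCell(Module):
    """Standard gated recurrent unit (reset/update gates, candidate state).

    The three gate projections are fused into single input-side and
    hidden-side matmuls and split afterwards.
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.w_i = Parameter(
            glorot((in_dim, 3 * hidden_dim), rng, fan_in=in_dim, fan_out=hidden_dim)
        )
        self.w_h = Parameter(
            glorot((hidden_dim, 3 * hidden_dim), rng, fan_in=hidden_dim, fan_out=hidden_dim)
        )
        self.b_i = Parameter(np.zeros(3 * hidden_dim))
        self.b_h = Parameter(np.zeros(3 * hidden_dim))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.hidden_dim
        gi = x @ self.w_i + self.b_i
        gh = h @ self.w_h + self.b_h
        r = (gi[..., :d] + gh[..., :d]).sigmoid()
        z = (gi[..., d:2 * d] + gh[..., d:2 * d]).sigmoid()
        n = (gi[..., 2 * d:] + r * gh[..., 2 * d:]).tanh()
        return z * h + (1.0 - z) * n


class Adam:
    """Adam optimizer with optional exponential learning-rate decay."""

    def __init__(self, params: list[Parameter], lr: float = 5e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_decay: float = 1.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def decay_lr(self) -> None:
        self.lr *= self.lr_decay
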