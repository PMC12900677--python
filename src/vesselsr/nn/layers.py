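"""Parameter containers, layers and the Adam optimiser for the numpy engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal within ±2 std, the usual transformer initialiser."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


def kaiming(rng: np.random.Generator, shape) -> np.ndarray:
    """He-normal initialisation for conv weights (fan-in over C*kh*kw)."""
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Minimal module base: parameters are discovered by attribute walk."""

    def parameters(self) -> list[Parameter]:
        out = []
        for p in self.named_parameters().values():
            out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        found: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                found[key] = val
            elif isinstance(val, Module):
                found.update(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        found.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        found[f"{key}.{i}"] = item
        return found

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = self.named_parameters()
        missing = set(named) - set(state)
        extra = set(state) - set(named)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in named.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float64).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 std: float = 0.02, zero_init: bool = False):
        if zero_init:
            self.weight = Parameter(np.zeros((d_in, d_out)))
        else:
            self.weight = Parameter(trunc_normal(rng, (d_in, d_out), std))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad_mode: str = "zeros", zero_init: bool = False):
        if zero_init:
            self.weight = Parameter(np.zeros((c_out, c_in, k, k)))
        else:
            self.weight = Parameter(kaiming(rng, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.k = k
        self.pad_mode = pad_mode

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.k // 2,
                        pad_mode=self.pad_mode)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.gamma, self.beta)


class Adam:
    """Standard Adam with bias correction; state is part of the checkpoint."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
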