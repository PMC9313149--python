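"""Neural-network layer primitives built on the autodiff engine.

Provides a light ``Module`` hierarchy (named parameters, state dicts for
checkpointing), Xavier/truncated-normal initializers, and an Adam optimizer
with L2 weight decay and a step learning-rate schedule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._tensor import DTYPE, Tensor, conv2d, layer_norm, leaky_relu, matmul, maxpool2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    # resample outside two standard deviations, the usual token-embedding init
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(DTYPE)


class Module:
    """Base class: child modules and parameters are discovered from attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def zero_(self) -> None:
        """Set every learnable parameter to zero (used by identity tests)."""
        for p in self.parameters():
            p.data[...] = 0.0

    # -- checkpointing --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data[...] = state[name]

    def save(self, path: str | Path) -> None:
        """Serialize parameters (npz) with a JSON name-to-shape manifest sidecar."""
        path = Path(path)
        state = self.state_dict()
        np.savez(path, **state)
        manifest = {name: list(arr.shape) for name, arr in state.items()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))

    def load(self, path: str | Path) -> None:
        with np.load(Path(path)) as archive:
            self.load_state_dict({k: archive[k] for k in archive.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(
            xavier_uniform(rng, in_features, out_features, (in_features, out_features))
        )
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv2d(Module):
    """Stride-1 convolution; padding defaults to 'same' for odd kernels."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None):
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.weight = Parameter(
            xavier_uniform(rng, fan_in, fan_out, (out_ch, in_ch, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE))
        self.padding = (kernel - 1) // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.size)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.slope)


class Adam:
    """Adam with L2 weight decay added to the gradient (coupled, as in
    reference deep-learning frameworks' default ``weight_decay``)."""

    def __init__(self, params: list[Parameter], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def step_lr(lr0: float, epoch: int, step: int = 10, gamma: float = 0.1) -> float:
    """Step-decayed learning rate: lr0 * gamma ** floor(epoch / step)."""
    return lr0 * gamma ** (epoch // step)
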