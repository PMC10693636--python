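"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, layernorm, linear

# Global train/eval switch (dropout is identity in eval mode).
_training = False


def set_training(flag: bool) -> None:
    global _training
    _training = flag


def is_training() -> bool:
    return _training


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery via attribute traversal."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            if isinstance(obj, Parameter):
                params.append(obj)
            elif isinstance(obj, Module):
                stack.extend(obj.__dict__.values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
            elif isinstance(obj, dict):
                stack.extend(obj.values())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.w, self.b)


class Conv1d(Module):
    def __init__(self, n_in: int, n_out: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in * kernel_size))
        self.w = Parameter(rng.normal(0.0, scale, (kernel_size, n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, dilation=self.dilation)


class LayerNorm(Module):
    def __init__(self, n_channels: int):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return layernorm(x, self.gamma, self.beta)


class Dropout(Module):
    """Inverted dropout; active only while the training flag is set."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not _training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.data.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class DilatedResidualUnit(Module):
    """Two dilated convolutions with normalization, ReLU and a residual add.

    The pairing of convolutions per dilation level is what gives a stack of
    n units the receptive field 1 + 2*(k-1)*(2^n - 1) when dilations grow
    as 1, 2, ..., 2^(n-1).
    """

    def __init__(self, n_in: int, n_out: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        self.conv1 = Conv1d(n_in, n_out, kernel_size, dilation, rng)
        self.norm1 = LayerNorm(n_out)
        self.conv2 = Conv1d(n_out, n_out, kernel_size, dilation, rng)
        self.norm2 = LayerNorm(n_out)
        self.proj = None if n_in == n_out else Conv1d(n_in, n_out, 1, 1, rng)
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2 ** 31)))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop(self.norm1(self.conv1(x)).relu())
        h = self.norm2(self.conv2(h))
        res = x if self.proj is None else self.proj(x)
        return self.drop((h + res).relu())


class TCNBlock(Module):
    """n residual units with exponentially growing dilation (1, 2, ..., 2^(n-1))."""

    def __init__(self, n_in: int, n_channels: int, kernel_size: int,
                 n_dilated_layers: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        self.units = [
            DilatedResidualUnit(
                n_in if i == 0 else n_channels, n_channels,
                kernel_size, 2 ** i, rng, dropout=dropout)
            for i in range(n_dilated_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for unit in self.units:
            x = unit(x)
        return x


class Adam(Module):
    """Adam / rectified Adam (RAdam) optimizer.

    RAdam (the default) rectifies the adaptive learning rate while its
    variance estimate is unreliable in early steps, removing the need for
    an explicit warmup at relatively large learning rates.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, rectified: bool = True):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.rectified = rectified
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1t = self.b1 ** t
        b2t = self.b2 ** t
        if self.rectified:
            rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
            if rho > 4.0:
                r = np.sqrt(((rho - 4) * (rho - 2) * self.rho_inf)
                            / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho))
            else:
                r = None  # variance not tractable yet: un-adapted SGD-with-momentum step
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            mhat = self.m[i] / (1 - b1t)
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            if self.rectified:
                if r is None:
                    p.data -= (self.lr * mhat).astype(np.float32)
                    continue
                vhat = np.sqrt(self.v[i] / (1 - b2t))
                p.data -= (self.lr * r * mhat / (vhat + self.eps)).astype(np.float32)
            else:
                vhat = np.sqrt(self.v[i] / (1 - b2t))
                p.data -= (self.lr * mhat / (vhat + self.eps)).astype(np.float32)
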