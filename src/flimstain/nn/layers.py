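"""Network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "InstanceNorm2d", "Dropout", "Sequential",
           "LeakyReLU", "ReLU"]


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state("", state)
        return state

    def _collect_state(self, prefix: str, state: dict) -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                state[prefix + k] = v.data
            elif isinstance(v, Module):
                v._collect_state(f"{prefix}{k}.", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{prefix}{k}.{i}.", state)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_tensors("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, t in own.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = np.array(state[k], dtype=t.data.dtype)

    def _collect_tensors(self, prefix: str, out: dict) -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[prefix + k] = v
            elif isinstance(v, Module):
                v._collect_tensors(f"{prefix}{k}.", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_tensors(f"{prefix}{k}.{i}.", out)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        # He-style fan-in scaling
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_ch, in_ch, k, k)).astype(dtype),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
                     if bias else None)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation with learnable affine."""

    def __init__(self, ch: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones((1, ch, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1), dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class Dropout(Module):
    """Inverted dropout; the generator's stochasticity source at train time."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.dtype))


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
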