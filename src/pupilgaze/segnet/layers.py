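"""Layer abstractions over the autodiff primitives."""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

from pupilgaze.segnet import autodiff as ad
from pupilgaze.segnet.autodiff import Tensor


class Module:
    """Base class with recursive parameter / buffer discovery."""

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, np.ndarray):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data[...] = arr
            else:
                buffers[name][...] = arr


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        fan_in = cin * k * k
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:  # He initialization suits the LeakyReLU blocks
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var, training
        )


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(1.0 / fin), size=(fin, fout))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)


class ConvBlock(Module):
    """Four conv layers, each followed by batch norm and LeakyReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, slope: float):
        self.convs = [Conv2d(cin if i == 0 else cout, cout, 3, rng) for i in range(4)]
        self.norms = [BatchNorm2d(cout) for _ in range(4)]
        self.slope = slope

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = ad.leaky_relu(norm(conv(x), training), self.slope)
        return x
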