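"""Layer abstractions over the autodiff tensors: conv/linear/pool modules
with He-style initialization from an explicit NumPy Generator, so every model
build is reproducible from a single seed."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Conv2d", "ConvTranspose2x2", "Linear", "ReLU", "Sigmoid",
    "MaxPool2x2", "Sequential",
]


class Module:
    """Base class: recursive parameter collection and train/eval flag."""

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

    def train(self):
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self):
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[prefix + k] = v.data
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data[...] = np.asarray(state[prefix + k], dtype=v.data.dtype).reshape(v.data.shape)
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return self

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_he(rng, (c_out, c_in, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution: exact 2x spatial upsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he(rng, (c_in, c_out, 2, 2), c_in * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_he(rng, (f_in, f_out), f_in), requires_grad=True)
        self.bias = Tensor(np.zeros(f_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2x2()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
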