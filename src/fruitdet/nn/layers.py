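"""Layer modules over the autograd core: conv blocks, norm, containers."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor, batchnorm2d, conv2d, upsample2x


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, t) for name, t in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [
            (prefix + n, getattr(self, n))
            for n in getattr(self, "_buffer_names", ())
        ]
        for cname, child in self._children.items():
            out.extend(child.buffers(prefix + cname + "."))
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self._children.values():
            child.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = cin * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for relu nets
        self.register(
            "weight",
            rng.normal(0.0, scale, size=(cout, cin, kernel, kernel)).astype(DTYPE),
        )
        if bias:
            self.register("bias", np.zeros(cout, dtype=DTYPE))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register("gamma", np.ones(channels, dtype=DTYPE))
        self.register("beta", np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample2x(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)
        for i, m in enumerate(modules):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


def conv_block(cin: int, cout: int, rng: np.random.Generator, stride: int = 1,
               kernel: int = 3, norm: bool = True) -> Sequential:
    """conv → batchnorm → relu, the workhorse block of backbone and neck."""
    layers: list[Module] = [Conv2d(cin, cout, kernel, stride, bias=not norm, rng=rng)]
    if norm:
        layers.append(BatchNorm2d(cout))
    layers.append(ReLU())
    return Sequential(*layers)


class Adam(Module):
    """Adam: adaptive-moment stochastic optimizer."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        super().__init__()
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
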