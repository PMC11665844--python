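"""Neural-network layer and optimizer primitives on top of :mod:`ddanet.autodiff`.

Mirrors the familiar module/parameter idiom: layers register
:class:`Parameter` leaves and child modules by attribute assignment,
``state_dict`` flattens them to name → array, and :class:`Adam` implements
the adaptive-moment optimizer the training protocol prescribes.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, batch_norm2d, conv2d, max_pool2d

#: storage/compute dtype for model parameters; single precision is ample for
#: segmentation training and roughly halves memory traffic on CPU
DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -- traversal ------------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for name, child in self._children.items():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in state dict")
            if state[key].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: checkpoint {state[key].shape} "
                    f"vs model {p.data.shape}")
            p.data = np.asarray(state[key], dtype=p.data.dtype)
        for name in self._buffers:
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing buffer {key!r} in state dict")
            self._buffers[name] = np.asarray(state[key], dtype=self._buffers[name].dtype)
            object.__setattr__(self, name, self._buffers[name])
        for name, child in self._children.items():
            child.load_state_dict(state, prefix + name + ".")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._children[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, idx: int) -> Module:
        return self._list[idx]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution, He-normal initialised from a caller-supplied RNG."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch moments (gradients flow through them);
    evaluation mode uses the running estimates, making inference
    deterministic.  ``eps=0`` gives an exact identity for freshly
    initialised layers in evaluation mode, which analytic tests exploit.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))
        self.eps, self.momentum = eps, momentum
        self.num_features = num_features

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if self.training:
            out, mu, var = batch_norm2d(x, self.weight, self.bias, self.eps)
            self._buffers["running_mean"] = (
                (1 - self.momentum) * self._buffers["running_mean"] + self.momentum * mu)
            self._buffers["running_var"] = (
                (1 - self.momentum) * self._buffers["running_var"] + self.momentum * var)
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
            return out
        mu = self._buffers["running_mean"].reshape(1, c, 1, 1)
        sd = np.sqrt(self._buffers["running_var"].reshape(1, c, 1, 1) + self.eps)
        xhat = (x - mu) * (1.0 / sd)
        return self.weight.reshape(1, c, 1, 1) * xhat + self.bias.reshape(1, c, 1, 1)

    def reset_to_identity(self) -> None:
        """Unit scale, zero shift, identity running statistics, eps 0."""
        self.weight.data = np.ones(self.num_features, dtype=DTYPE)
        self.bias.data = np.zeros(self.num_features, dtype=DTYPE)
        self._buffers["running_mean"] = np.zeros(self.num_features, dtype=DTYPE)
        self._buffers["running_var"] = np.ones(self.num_features, dtype=DTYPE)
        object.__setattr__(self, "running_mean", self._buffers["running_mean"])
        object.__setattr__(self, "running_var", self._buffers["running_var"])
        self.eps = 0.0


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Adam:
    """Adaptive-moment estimation optimizer (bias-corrected)."""

    def __init__(self, params, lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
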