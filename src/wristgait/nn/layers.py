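"""Neural-network building blocks for 1-D accelerometer windows.

The encoder follows the pre-activation ("V2") residual design: each block
applies norm -> ReLU -> conv twice around an identity (or 1x1-projected)
shortcut, and the network ends with a global average pool and a linear
projection to the embedding dimension.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, batchnorm, conv1d


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self):
        self._params: "OrderedDict[str, Tensor]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        return self._buffers[name]

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for name, m in self._modules.items():
            out.extend(m.named_buffers(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.array(state[n], dtype=np.float64)
        for n, _ in self.named_buffers():
            self._set_buffer(n, np.array(state["buffer:" + n], dtype=np.float64))

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]] = value

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = self.register_parameter(
            "weight", _he_normal(rng, (out_channels, in_channels, kernel_size), fan_in)
        )
        self.bias = self.register_parameter("bias", np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, length) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register_parameter("gamma", np.ones(channels))
        self.beta = self.register_parameter("beta", np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm(x, self.gamma, self.beta, self.eps)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mu - rm)
            rv += self.momentum * (var - rv)
            return out
        mu = Tensor(self._buffers["running_mean"][None, :, None])
        var = Tensor(self._buffers["running_var"][None, :, None])
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = self.register_parameter(
            "weight", _he_normal(rng, (in_features, out_features), in_features)
        )
        self.bias = self.register_parameter("bias", np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ResidualBlock(Module):
    """Pre-activation residual block: BN-ReLU-conv3 twice, projected shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bn1 = self.add_module("bn1", BatchNorm1d(in_channels))
        self.conv1 = self.add_module(
            "conv1", Conv1d(in_channels, out_channels, 3, stride=stride, padding=1, rng=rng)
        )
        self.bn2 = self.add_module("bn2", BatchNorm1d(out_channels))
        self.conv2 = self.add_module(
            "conv2", Conv1d(out_channels, out_channels, 3, stride=1, padding=1, rng=rng)
        )
        if stride != 1 or in_channels != out_channels:
            self.shortcut = self.add_module(
                "shortcut", Conv1d(in_channels, out_channels, 1, stride=stride,
                                   bias=False, rng=rng)
            )
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(x).relu()
        sc = self.shortcut(h) if self.shortcut is not None else x
        h = self.conv1(h)
        h = self.bn2(h).relu()
        h = self.conv2(h)
        return h + sc


class ResNetEncoder1d(Module):
    """Feature extractor mapping (B, 3, L) windows to (B, feature_dim) embeddings."""

    def __init__(self, in_channels: int, channels: list[int], strides: list[int],
                 feature_dim: int, input_length: int, stem_kernel: int = 5,
                 stem_stride: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        if len(channels) != len(strides):
            raise ValueError("channels and strides must have equal length")
        rng = rng or np.random.default_rng(0)
        self.feature_dim = feature_dim
        self.input_length = input_length
        pad = stem_kernel // 2
        self.stem = self.add_module(
            "stem", Conv1d(in_channels, channels[0], stem_kernel,
                           stride=stem_stride, padding=pad, rng=rng)
        )
        length = (input_length + 2 * pad - stem_kernel) // stem_stride + 1
        prev = channels[0]
        self.n_blocks = len(channels)
        for i, (c, s) in enumerate(zip(channels, strides)):
            self.add_module(f"block{i}", ResidualBlock(prev, c, s, rng))
            length = (length + 2 - 3) // s + 1
            prev = c
        if length < 2:
            raise ValueError(
                f"input length {input_length} is incompatible with the downsampling schedule"
            )
        self.final_length = length
        self.bn_out = self.add_module("bn_out", BatchNorm1d(prev))
        self.fc_out = self.add_module("fc_out", Linear(prev, feature_dim, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        for i in range(self.n_blocks):
            h = self._modules[f"block{i}"](h)
        h = self.bn_out(h).relu()
        h = h.mean(axis=2)          # global average pool -> (B, C)
        return self.fc_out(h)


class MLPHead(Module):
    """Three fully-connected layers; optional ReLU between layers.

    ``nonlinear=False`` reproduces the purely linear stack (no activation
    between layers); ``nonlinear=True`` inserts ReLU after the first two.
    """

    def __init__(self, in_dim: int, out_dim: int, hidden_dim: int | None = None,
                 nonlinear: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden_dim = hidden_dim or in_dim
        self.nonlinear = nonlinear
        self.fc1 = self.add_module("fc1", Linear(in_dim, hidden_dim, rng=rng))
        self.fc2 = self.add_module("fc2", Linear(hidden_dim, hidden_dim, rng=rng))
        self.fc3 = self.add_module("fc3", Linear(hidden_dim, out_dim, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        if self.nonlinear:
            h = h.relu()
        h = self.fc2(h)
        if self.nonlinear:
            h = h.relu()
        return self.fc3(h)


class LinearHead(Module):
    """Single linear output layer (the fine-tuning gait head)."""

    def __init__(self, in_dim: int, out_dim: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.fc = self.add_module("fc", Linear(in_dim, out_dim, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(x)
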