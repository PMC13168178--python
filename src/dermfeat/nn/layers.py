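"""Layer modules on top of the autograd engine.

Includes the attention blocks the dual-stream network is built from:
squeeze-excite channel gating, the residual squeeze-excite (RSE) unit and
the convolutional block attention module (CBAM).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter registry plus train/eval mode switching."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        t.requires_grad = True  # persists even if created under no_grad
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def num_parameters(self) -> int:
        """Total trainable parameter count."""
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping of parameters and buffers (for IO)."""
        out = {}
        for name, p in self._params.items():
            out[name] = p.data
        for name, buf in getattr(self, "_buffers", {}).items():
            out[name] = buf
        for mname, m in self._modules.items():
            for k, v in m.state_arrays().items():
                out[f"{mname}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=np.float32)
        for name in getattr(self, "_buffers", {}):
            self._buffers[name] = np.asarray(state[prefix + name],
                                             dtype=np.float32)
        for mname, m in self._modules.items():
            m.load_state_arrays(state, prefix=f"{prefix}{mname}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng, stride: int = 1,
                 padding: str = "same", bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        self.w = self.add_param("w", _he_normal(rng, (cout, cin, k, k),
                                                cin * k * k))
        self.b = self.add_param("b", np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, self.stride, self.padding)


class Dense(Module):
    def __init__(self, fin: int, fout: int, rng, bias: bool = True):
        super().__init__()
        self.w = self.add_param("w", _he_normal(rng, (fin, fout), fin))
        self.b = self.add_param("b", np.zeros(fout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.w)
        if self.b is not None:
            out = ag.add(out, self.b)
        return out


class BatchNorm(Module):
    """Batch normalization over axis 1 (channels/features), any rank."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param("gamma", np.ones(c, np.float32))
        self.beta = self.add_param("beta", np.zeros(c, np.float32))
        self._buffers = {"running_mean": np.zeros(c, np.float32),
                         "running_var": np.ones(c, np.float32)}

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = [1] * x.ndim
        shape[1] = -1
        gamma = ag.reshape(self.gamma, shape)
        beta = ag.reshape(self.beta, shape)
        if self.training:
            mu = ag.mean(x, axis=axes, keepdims=True)
            diff = ag.add(x, ag.mul(mu, ag.as_tensor(-1.0)))
            var = ag.mean(ag.power(diff, 2.0), axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                m * self._buffers["running_mean"] + (1 - m) * mu.data.ravel())
            self._buffers["running_var"] = (
                m * self._buffers["running_var"] + (1 - m) * var.data.ravel())
            xhat = ag.mul(diff, ag.rsqrt(var, self.eps))
        else:
            mu = self._buffers["running_mean"].reshape(shape)
            sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(shape)
            xhat = ag.mul(ag.add(x, ag.as_tensor(-mu)),
                          ag.as_tensor((1.0 / sd).astype(np.float32)))
        return ag.add(ag.mul(xhat, gamma), beta)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.rate, self.rng, self.training)


class GlobalAvgPool(Module):
    """NCHW → NC mean pooling."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.mean(x, axis=(2, 3), keepdims=False)


class SEBlock(Module):
    """Squeeze-excite channel gating: GAP → C/r ReLU → C sigmoid → scale."""

    def __init__(self, c: int, ratio: int, rng):
        super().__init__()
        if ratio > c:
            raise ValueError(f"SE ratio {ratio} exceeds channel count {c}")
        self.fc1 = Dense(c, c // ratio, rng)
        self.fc2 = Dense(c // ratio, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = ag.mean(x, axis=(2, 3), keepdims=False)
        s = ag.relu(self.fc1(s))
        s = ag.sigmoid(self.fc2(s))
        gate = ag.reshape(s, (x.shape[0], x.shape[1], 1, 1))
        return ag.mul(x, gate)


class RSEBlock(Module):
    """Residual squeeze-excite unit.

    Inner branch g(x) = SE(BN(Conv(Dropout(GeLU(BN(Conv(x))))))); merged with
    the block input either by addition (1x1 projection when channel counts or
    spatial strides differ) or by channel concatenation, then GeLU.
    """

    def __init__(self, cin: int, filters: int, rng, se_ratio: int = 16,
                 dropout: float = 0.2, merge: str = "add", stride: int = 1):
        super().__init__()
        if merge not in ("add", "concat"):
            raise ValueError(f"unknown merge mode {merge!r}")
        self.merge = merge
        self.conv1 = Conv2d(cin, filters, 3, rng, stride=stride)
        self.bn1 = BatchNorm(filters)
        self.drop = Dropout(dropout, rng)
        self.conv2 = Conv2d(filters, filters, 3, rng)
        self.bn2 = BatchNorm(filters)
        self.se = SEBlock(filters, se_ratio, rng)
        self.proj = None
        if merge == "add" and (cin != filters or stride != 1):
            self.proj = Conv2d(cin, filters, 1, rng, stride=stride)
        self.out_channels = filters if merge == "add" else cin + filters

    def forward(self, x: Tensor) -> Tensor:
        g = self.bn1(self.conv1(x))
        g = self.drop(ag.gelu(g))
        g = self.se(self.bn2(self.conv2(g)))
        if self.merge == "add":
            skip = self.proj(x) if self.proj is not None else x
            return ag.gelu(ag.add(skip, g))
        return ag.gelu(ag.concat([x, g], axis=1))


class CBAM(Module):
    """Convolutional block attention: channel then spatial attention."""

    def __init__(self, c: int, rng, ratio: int = 16, spatial_kernel: int = 7):
        super().__init__()
        hidden = max(c // ratio, 1)
        self.fc1 = Dense(c, hidden, rng)          # shared MLP
        self.fc2 = Dense(hidden, c, rng)
        self.spatial = Conv2d(2, 1, spatial_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = ag.mean(x, axis=(2, 3), keepdims=False)
        mx = ag.max_along(ag.max_along(x, 3, keepdims=False), 2, keepdims=False)
        att = ag.sigmoid(ag.add(self.fc2(ag.relu(self.fc1(avg))),
                                self.fc2(ag.relu(self.fc1(mx)))))
        x = ag.mul(x, ag.reshape(att, (n, c, 1, 1)))
        savg = ag.mean(x, axis=1, keepdims=True)
        smax = ag.max_along(x, 1, keepdims=True)
        smap = ag.sigmoid(self.spatial(ag.concat([savg, smax], axis=1)))
        return ag.mul(x, smap)
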