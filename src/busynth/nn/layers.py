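"""Neural-network building blocks on top of the autograd engine.

Conventions follow the DCGAN / image-to-image translation literature:
NCHW layout, weights drawn from N(0, 0.02), LeakyReLU slope 0.2 in
discriminators, spectral normalization by power iteration on the
(out, in*k*k) weight matrix.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, as_tensor
from .convops import conv2d, conv_transpose2d

__all__ = [
    "he_init",
    "Module",
    "Sequential",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "InstanceNorm2d",
    "Dropout",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
]

_WEIGHT_STD = 0.02


def he_init(module: "Module", rng: np.random.Generator) -> "Module":
    """Re-draw every weight at He scale sqrt(2 / fan_in).

    The default N(0, 0.02) init is the adversarial-training convention; for
    plainly supervised models it starves deep activations and stalls the
    first epochs, so the task models re-initialize variance-preserving.
    """
    for _, layer in module.named_modules():
        if isinstance(layer, Conv2d):
            fan_in = int(np.prod(layer.weight.data.shape[1:]))
        elif isinstance(layer, ConvTranspose2d):
            shp = layer.weight.data.shape
            fan_in = int(shp[0] * shp[2] * shp[3])
        elif isinstance(layer, Dense):
            fan_in = int(layer.weight.data.shape[0])
        else:
            continue
        layer.weight.data = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), layer.weight.data.shape
        ).astype(layer.weight.data.dtype)
    return module


class Module:
    """Base class: tracks child modules/parameters via attribute scan."""

    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _local_params(self) -> dict[str, Tensor]:
        return {
            name: value
            for name, value in vars(self).items()
            if isinstance(value, Tensor) and value.requires_grad
        }

    def _local_buffers(self) -> dict[str, np.ndarray]:
        return {}

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._local_params().items()]
        for cname, child in self.children():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._local_buffers().items()]
        for cname, child in self.children():
            out.extend(child.named_buffers(prefix + cname + "."))
        return out

    # -- modes -------------------------------------------------------------
    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for _, child in self.children():
            child.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({n: np.asarray(b).copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name in params:
                params[name].data = np.array(value)
            else:
                self._load_buffer(name, value)

    def named_modules(self, prefix: str = "") -> list[tuple[str, "Module"]]:
        out = [(prefix.rstrip("."), self)]
        for cname, child in self.children():
            out.extend(child.named_modules(prefix + cname + "."))
        return out

    def _load_buffer(self, name: str, value: np.ndarray) -> None:
        path, _, leaf = name.rpartition(".")
        modules = dict(self.named_modules())
        if path not in modules or not hasattr(modules[path], leaf):
            raise KeyError(f"unknown state entry {name!r}")
        setattr(modules[path], leaf, np.array(value))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, _WEIGHT_STD, (n_in, n_out)).astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class _SpectralNormMixin:
    """Shared power-iteration machinery for spectrally normalized weights."""

    # long warmup: random init matrices have clustered top singular values,
    # so a handful of iterations under-estimates sigma by >0.1%
    def _init_sn(self, rng: np.random.Generator, n_out: int, power_iterations: int, warmup: int = 100):
        self.power_iterations = power_iterations
        self.u = rng.normal(size=n_out).astype(self.weight.dtype)
        self.u /= np.linalg.norm(self.u) + 1e-12
        self._power_iterate(warmup)

    def _weight_matrix(self) -> np.ndarray:
        return self.weight.data.reshape(self.weight.data.shape[0], -1)

    def _power_iterate(self, n_iter: int) -> np.ndarray:
        wmat = self._weight_matrix()
        u = self.u
        for _ in range(n_iter):
            v = wmat.T @ u
            v /= np.linalg.norm(v) + 1e-12
            u = wmat @ v
            u /= np.linalg.norm(u) + 1e-12
        self.u = u
        v = wmat.T @ u
        v /= np.linalg.norm(v) + 1e-12
        return v

    def _normalized_weight(self) -> Tensor:
        v = self._power_iterate(self.power_iterations if self.training else 0)
        wflat = self.weight.reshape(self.weight.data.shape[0], -1)
        # sigma as a graph node linear in W (u, v held fixed), as in standard SN
        sigma = as_tensor(self.u[None, :]) @ wflat @ as_tensor(v[:, None])
        wbar = wflat / sigma
        return wbar.reshape(*self.weight.data.shape)


class Conv2d(Module, _SpectralNormMixin):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        spectral_norm: bool = False,
        power_iterations: int = 1,
        dtype=np.float32,
    ):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.spectral_norm = spectral_norm
        self.weight = Tensor(
            rng.normal(0.0, _WEIGHT_STD, (c_out, c_in, kernel, kernel)).astype(dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True) if bias else None
        if spectral_norm:
            self._init_sn(rng, c_out, power_iterations)

    def effective_weight(self) -> Tensor:
        return self._normalized_weight() if self.spectral_norm else self.weight

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_weight(), self.bias, self.stride, self.padding)

    def _local_buffers(self):
        return {"u": self.u} if self.spectral_norm else {}


class ConvTranspose2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 2,
        padding: int = 1,
        output_padding: int = 0,
        bias: bool = True,
        dtype=np.float32,
    ):
        super().__init__()
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.weight = Tensor(
            rng.normal(0.0, _WEIGHT_STD, (c_in, c_out, kernel, kernel)).astype(dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding, self.output_padding)


def _norm_op(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...], eps: float) -> Tensor:
    """Fused normalize-scale-shift with analytic backward.

    dx = (gamma/std) * (dy - mean(dy) - xhat * mean(dy * xhat)) over the
    normalization axes; one op instead of a chain of elementwise nodes.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = Tensor(gamma.data * xhat + beta.data, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            reduce_axes = tuple(i for i in range(g.ndim) if gamma.data.shape[i] == 1)
            gamma._accum((g * xhat).sum(axis=reduce_axes, keepdims=True))
        if beta.requires_grad:
            reduce_axes = tuple(i for i in range(g.ndim) if beta.data.shape[i] == 1)
            beta._accum(g.sum(axis=reduce_axes, keepdims=True))
        if x.requires_grad:
            gy = gamma.data * g
            mean_gy = gy.mean(axis=axes, keepdims=True)
            mean_gy_xhat = (gy * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv_std * (gy - mean_gy - xhat * mean_gy_xhat))

    out._backward = backward
    return out, mu, var


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, channels, 1, 1), dtype=dtype)

    def _local_buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = _norm_op(x, self.gamma, self.beta, (0, 2, 3), self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
            return out
        xhat = (x - as_tensor(self.running_mean)) / (
            as_tensor(np.sqrt(self.running_var + self.eps))
        )
        return self.gamma * xhat + self.beta


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return _norm_op(x, self.gamma, self.beta, (2, 3), self.eps)[0]


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        u = self.rng.random(x.data.shape, dtype=np.float32)
        keep = (u >= self.p).astype(x.data.dtype)
        keep *= 1.0 / (1.0 - self.p)
        return x * as_tensor(keep)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
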