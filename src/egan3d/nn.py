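"""Neural-network layers built on the autodiff core.

Conventions follow the usual deep-learning layout: volumes are
``[N, C, D, H, W]``, 2D maps ``[N, C, H, W]``.  Parameters are plain
:class:`~egan3d.autodiff.Tensor` objects with ``requires_grad=True``,
collected recursively by :meth:`Module.parameters`.  Weight
initialisation is zero-mean Gaussian with configurable standard
deviation (default 0.02), drawn from a caller-supplied generator so
whole-network initialisation is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

DTYPE = np.float32
INIT_STD = 0.02


class Module:
    """Minimal parameter container with train/eval mode."""

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

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out: dict[str, np.ndarray] = {}
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Module):
                out.update(v.buffers(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.buffers(prefix=f"{key}.{i}."))
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                out[key] = v
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # state round-trip for checkpoints ------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for k, v in self.buffers().items():
            state["buffer:" + k] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        bufs = self.buffers()
        for k, v in state.items():
            if k.startswith("buffer:"):
                bufs[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = v.astype(params[k].data.dtype)


def gaussian_init(shape, rng: np.random.Generator, std: float = INIT_STD) -> Tensor:
    """Weight tensor drawn i.i.d. from N(0, std^2)."""
    return Tensor(rng.normal(0.0, std, size=shape).astype(DTYPE), requires_grad=True)


def zeros_param(shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=DTYPE), requires_grad=True)


class Conv3d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=0, std=INIT_STD):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = gaussian_init((cout, cin, k, k, k), rng, std)
        self.bias = zeros_param((1, cout, 1, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, stride=self.stride, padding=self.padding) + self.bias


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=0, std=INIT_STD):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = gaussian_init((cout, cin, k, k), rng, std)
        self.bias = zeros_param((1, cout, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, stride=self.stride, padding=self.padding) + self.bias


class AxisConv(Module):
    """Separable convolution: a 1D kernel acting along one spatial axis.

    The kernel spans a contiguous window of length ``k``; with
    ``collapse=True`` it spans the whole axis and the axis disappears from
    the output (the full-extent "long-range" convolution).  Otherwise the
    axis is partitioned into ``extent // k`` non-overlapping blocks
    (stride = kernel length), each contracted to one output position --
    the "local" convolution of the encoder.
    """

    def __init__(self, cin, cout, k, rng, std=INIT_STD):
        super().__init__()
        self.k = k
        self.weight = gaussian_init((cout, cin, k), rng, std)
        self.bias = zeros_param((cout,))  # reshaped to the output rank at call time

    def __call__(self, x: Tensor, axis: int, collapse: bool) -> Tensor:
        """``x``: [N, C, d0, d1, ...]; ``axis`` indexes the spatial dims."""
        spatial = x.ndim - 2
        letters = "dhwuv"[:spatial]
        ax = letters[axis]
        if collapse:
            if x.shape[2 + axis] != self.k:
                raise ValueError(
                    f"collapse AxisConv kernel {self.k} != axis extent {x.shape[2 + axis]}"
                )
            rest = letters.replace(ax, "")
            sub = f"nc{letters},oc{ax}->no{rest}"
            out = x.einsum(sub, self.weight)
        else:
            extent = x.shape[2 + axis]
            if extent % self.k:
                raise ValueError(f"axis extent {extent} not divisible by kernel {self.k}")
            nb = extent // self.k
            new_shape = list(x.shape)
            new_shape[2 + axis : 3 + axis] = [nb, self.k]
            big = letters[:axis] + "b" + ax + letters[axis:].replace(ax, "", 1)
            outsub = letters[:axis] + "b" + letters[axis:].replace(ax, "", 1)
            sub = f"nc{big},oc{ax}->no{outsub}"
            out = x.reshape(new_shape).einsum(sub, self.weight)
        bias = self.bias.reshape((1, self.weight.shape[0]) + (1,) * (out.ndim - 2))
        return out + bias


class BatchNorm3d(Module):
    """Channelwise batch normalisation over [N, C, D, H, W].

    Train mode normalises with batch statistics and updates running
    estimates; eval mode uses the running estimates, so translation
    outputs are deterministic.
    """

    def __init__(self, channels, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=DTYPE), requires_grad=True)
        self.beta = zeros_param((1, channels, 1, 1, 1))
        self.running_mean = np.zeros((1, channels, 1, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, channels, 1, 1, 1), dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import batch_norm

        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = ((x.data - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu
            self.running_var *= 1 - m
            self.running_var += m * var
            return batch_norm(x, self.gamma, self.beta, mu, var, self.eps, True)
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.eps, False)


class Adam:
    """Adam optimiser (decoupled from the modules; holds per-param state)."""

    def __init__(self, params: list[Tensor], lr=1e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self):
        return {
            "t": self.t,
            "m": [a.copy() for a in self.m],
            "v": [a.copy() for a in self.v],
        }

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for a, b in zip(self.m, state["m"]):
            a[...] = b
        for a, b in zip(self.v, state["v"]):
            a[...] = b
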