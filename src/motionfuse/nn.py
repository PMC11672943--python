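"""Neural-network layers, losses and the SGD optimizer used by the models.

Built directly on :mod:`motionfuse.autodiff`.  Layout conventions follow
the usual deep-learning ones: feature maps are ``(N, C, H, W)`` (for the
skeleton models ``H`` is time and ``W`` is the joint axis), linear inputs
are ``(N, F)``.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv2d

__all__ = [
    "Module", "Parameter", "Sequential", "Identity",
    "Conv2d", "Linear", "BatchNorm1d", "BatchNorm2d", "GroupNorm",
    "ReLU", "SiLU", "Sigmoid", "MaxPool2d",
    "global_avg_pool", "cross_entropy", "SGD", "Adam", "count_parameters",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def astype(self, dtype):
        """Cast all parameters and buffers in place (used by gradient checks)."""
        for m in self.modules():
            for name, value in vars(m).items():
                if isinstance(value, Parameter):
                    value.data = value.data.astype(dtype)
                elif isinstance(value, np.ndarray):
                    setattr(m, name, value.astype(dtype))
        return self

    def named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_modules(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{full}.{i}.")

    def named_buffers(self):
        """Non-learnable ndarray state (e.g. batch-norm running statistics)."""
        for mod_name, mod in self.named_modules():
            for attr, value in vars(mod).items():
                if isinstance(value, np.ndarray) and not isinstance(value, Parameter):
                    yield (f"{mod_name}.{attr}" if mod_name else attr), mod, attr

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod, attr in self.named_buffers():
            state[name] = getattr(mod, attr).copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = {name: (mod, attr) for name, mod, attr in self.named_buffers()}
        own = set(params) | set(buffers)
        if own != set(state):
            missing = own ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)
        for name, (mod, attr) in buffers.items():
            old = getattr(mod, attr)
            setattr(mod, attr, np.asarray(state[name], dtype=old.dtype).reshape(old.shape))


def count_parameters(module: Module) -> int:
    """Total number of learnable scalar entries, by direct enumeration."""
    return int(sum(p.data.size for p in module.parameters()))


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size,
                 stride=(1, 1), padding=(0, 0), groups=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        if isinstance(stride, int):
            stride = (stride, stride)
        if isinstance(padding, int):
            padding = (padding, padding)
        rng = rng or np.random.default_rng()
        kh, kw = kernel_size
        fan_in = in_channels // groups * kh * kw
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_channels, in_channels // groups, kh, kw)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class _Norm(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def _affine_shape(self, ndim):
        shape = [1] * ndim
        shape[1] = -1
        return tuple(shape)

    def _batch_norm(self, x, reduce_axes):
        """Fused forward/backward batch normalization (one graph node)."""
        shape = self._affine_shape(x.ndim)
        weight, bias = self.weight, self.bias
        xd = x.data
        if self.training:
            mean = xd.mean(axis=reduce_axes, keepdims=True)
            centered = xd - mean
            var = (centered * centered).mean(axis=reduce_axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.reshape(-1).astype(self.running_mean.dtype))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.reshape(-1).astype(self.running_var.dtype))
        else:
            mean = self.running_mean.reshape(shape).astype(xd.dtype)
            var = self.running_var.reshape(shape).astype(xd.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean) * inv
        w = weight.data.reshape(shape)
        out = xhat * w + bias.data.reshape(shape)
        n = xd.size // w.size
        training = self.training

        def bw(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=reduce_axes).reshape(-1))
            if weight.requires_grad:
                weight._accum((g * xhat).sum(axis=reduce_axes).reshape(-1))
            if x.requires_grad:
                gx = g * w
                if training:
                    # standard batch-norm backward through the batch statistics
                    gm = gx.sum(axis=reduce_axes, keepdims=True)
                    gv = (gx * xhat).sum(axis=reduce_axes, keepdims=True)
                    x._accum(inv * (gx - gm / n - xhat * gv / n))
                else:
                    x._accum(gx * inv)

        from .autodiff import Tensor
        return Tensor._make(out, (x, weight, bias), bw)


class BatchNorm2d(_Norm):
    def forward(self, x):
        return self._batch_norm(x, (0, 2, 3))


class BatchNorm1d(_Norm):
    """Accepts (N, C) or (N, C, L)."""

    def forward(self, x):
        return self._batch_norm(x, (0,) if x.ndim == 2 else (0, 2))


class GroupNorm(Module):
    """Per-sample normalization over channel groups (affine per channel)."""

    def __init__(self, num_groups, num_channels, eps=1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must divide into groups")
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))
        self.num_groups, self.eps = num_groups, eps

    def forward(self, x):
        N, C = x.shape[:2]
        spatial = x.shape[2:]
        g = self.num_groups
        xg = x.reshape(N, g, C // g, *spatial)
        axes = tuple(range(2, xg.ndim))
        mean = xg.mean(axis=axes, keepdims=True)
        centered = xg - mean
        var = (centered * centered).mean(axis=axes, keepdims=True)
        xhat = (centered * (var + self.eps) ** -0.5).reshape(N, C, *spatial)
        shape = (1, C) + (1,) * len(spatial)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    """Non-overlapping max pooling; kernel must tile the input exactly."""

    def __init__(self, kernel_size):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        self.kernel_size = kernel_size

    def forward(self, x):
        kh, kw = self.kernel_size
        N, C, H, W = x.shape
        if H % kh or W % kw:
            raise ValueError(
                f"MaxPool2d: input ({H},{W}) not divisible by kernel ({kh},{kw})")
        x = x.reshape(N, C, H // kh, kh, W // kw, kw)
        return x.max(axis=5).max(axis=3)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; labels are 0-based integer classes."""
    logp = logits.log_softmax(axis=1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=np.intp)]
    return -picked.mean()


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self._t
        bc2 = 1 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    """SGD with (optionally Nesterov) momentum and decoupled L2 weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, nesterov=True, weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.nesterov, self.weight_decay = nesterov, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            update = g + self.momentum * v if self.nesterov else v
            p.data = p.data - self.lr * update

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
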