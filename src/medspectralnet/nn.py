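"""Neural-network layers on top of the autograd engine.

Conventions follow the common CNN stacks: convolutions use Kaiming-normal
(fan-out) weight init, batch norm keeps running statistics for eval mode,
biases default to zero so that identity/zero-propagation properties of the
architecture hold exactly at initialization.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

DTYPE = np.float32


class Module:
    """Base class: parameter/buffer registry, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True
        self._buffers = {}

    # -- registry -----------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix=""):
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def register_buffer(self, name, array):
        self._buffers[name] = array

    def named_buffers(self, prefix=""):
        for name, arr in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), arr
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_buffers(sub)

    # -- modes ---------------------------------------------------------------
    def train(self):
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for _, m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization ---------------------------------------------------------
    def state_dict(self):
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            elif kind == "buffer":
                owner, _, leaf = name.rpartition(".")
                for mod_name, mod in self.named_modules():
                    if mod_name == owner and leaf in mod._buffers:
                        mod._buffers[leaf] = np.asarray(value, dtype=mod._buffers[leaf].dtype)
                        break
                else:
                    raise KeyError(f"unknown buffer {name!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming_normal(rng, shape, fan_out):
    std = np.sqrt(2.0 / fan_out)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng, stride=1,
                 padding=0, groups=1, bias=True, zero_init_bias=True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_out = out_channels * k * k // groups
        self.weight = Parameter(_kaiming_normal(rng, (out_channels, in_channels // groups, k, k), fan_out))
        if bias:
            if zero_init_bias:
                b = np.zeros(out_channels, dtype=DTYPE)
            else:
                bound = 1.0 / np.sqrt(in_channels * k * k / groups)
                b = rng.uniform(-bound, bound, out_channels).astype(DTYPE)
            self.bias = Parameter(b)
        else:
            self.bias = None
        self._name = type(self).__name__

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"{self._name}: expected {self.in_channels} input channels, got {x.shape[1]}")
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                         self.groups, op_name=self._name)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True, zero_init_bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter((rng.standard_normal((out_features, in_features)) * std).astype(DTYPE))
        if bias:
            b = np.zeros(out_features, dtype=DTYPE)
            if not zero_init_bias:
                bound = 1.0 / np.sqrt(in_features)
                b = rng.uniform(-bound, bound, out_features).astype(DTYPE)
            self.bias = Parameter(b)
        else:
            self.bias = None
        self._name = type(self).__name__

    def forward(self, x):
        ag._record_macs(self._name, self.in_features * self.out_features)
        return ag.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))

    def forward(self, x):
        gamma = ag.reshape(self.weight, (1, self.num_features, 1, 1))
        beta = ag.reshape(self.bias, (1, self.num_features, 1, 1))
        if self.training:
            mu = ag.mean(x, axis=(0, 2, 3), keepdims=True)
            xc = ag.sub(x, mu)
            var = ag.mean(ag.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            inv = ag.pow_(ag.add(var, self.eps), -0.5)
            xn = ag.mul(xc, inv)
            m = self.momentum
            self._buffers["running_mean"] = ((1 - m) * self._buffers["running_mean"]
                                             + m * mu.data.reshape(-1)).astype(DTYPE)
            self._buffers["running_var"] = ((1 - m) * self._buffers["running_var"]
                                            + m * var.data.reshape(-1)).astype(DTYPE)
        else:
            rm = self._buffers["running_mean"].reshape(1, -1, 1, 1)
            rv = self._buffers["running_var"].reshape(1, -1, 1, 1)
            xn = ag.mul(ag.sub(x, rm), 1.0 / np.sqrt(rv + self.eps))
        return ag.add(ag.mul(xn, gamma), beta)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class GELU(Module):
    def forward(self, x):
        return ag.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ag.maxpool2d(x, self.kernel_size, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def global_avg_pool(x, keepdims=True):
    """Spatial mean per channel (GAP), B×C×H×W -> B×C×1×1 (or B×C)."""
    return ag.mean(x, axis=(2, 3), keepdims=keepdims)


def cross_entropy(logits, labels):
    """Mean cross-entropy of integer labels on raw logits."""
    logp = ag.log_softmax(logits, axis=1)
    picked = ag.select_rows(logp, np.asarray(labels))
    return ag.neg(ag.mean(picked))


def assign_layer_names(model, prefix="model"):
    """Give every leaf layer its qualified name (used by the MAC profiler)."""
    for name, mod in model.named_modules():
        if isinstance(mod, (Conv2d, Linear)):
            mod._name = f"{prefix}.{name}" if (prefix and name) else (name or prefix)
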