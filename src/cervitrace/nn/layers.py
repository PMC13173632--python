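"""Layer modules built on the autodiff ops: Conv2d, ConvTranspose2d,
BatchNorm2d, MaxPool2d, ReLU, Sigmoid, ZeroPad2d.

Parameters are leaf Tensors; ``Module.parameters()`` walks the tree in
a stable order so optimizer state and checkpoints are reproducible.
Initialization is He-uniform from a caller-supplied Generator.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for attr in vars(self).values():
            if isinstance(attr, Module):
                mods.extend(attr.modules())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters + batchnorm running stats)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def __call__(self, *args):
        return self.forward(*args)


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, pad=0, *, rng, dtype=np.float32):
        super().__init__()
        self.stride, self.pad = stride, pad
        fan_in = cin * kernel * kernel
        self.weight = Tensor(he_uniform(rng, (cout, cin, kernel, kernel), fan_in, dtype))
        self.bias = Tensor(np.zeros(cout, dtype=dtype))

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Kernel == stride == factor: exact inverse of a stride-``factor`` pooling."""

    def __init__(self, cin, cout, factor=2, *, rng, dtype=np.float32):
        super().__init__()
        self.factor = factor
        fan_in = cin * factor * factor
        self.weight = Tensor(he_uniform(rng, (cin, cout, factor, factor), fan_in, dtype))
        self.bias = Tensor(np.zeros(cout, dtype=dtype))

    def forward(self, x):
        return ad.conv_transpose2d(x, self.weight, self.bias, self.factor)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(c, dtype=dtype))
        self.beta = Tensor(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x):
        return ad.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class MaxPool2d(Module):
    def __init__(self, kernel, stride, pad=0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        return ad.max_pool2d(x, self.kernel, self.stride, self.pad)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)
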