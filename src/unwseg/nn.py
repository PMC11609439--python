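"""Parameters, layers and the SGD optimizer used by the segmentation network.

Everything is float32 on the network path; initialisation is He-style and
fully determined by the RNG handed in, so a seed pins the whole model.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv1x1, relu

__all__ = ["Parameter", "Module", "Conv3x3", "Conv1x1", "DoubleConv", "SGD"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32),
                         requires_grad=True)


class Module:
    """Lightweight parameter container with recursive traversal."""

    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def state_dict(self):
        return {i: p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data = np.asarray(state[i], dtype=p.data.dtype).reshape(p.shape)

    def n_params(self):
        return int(sum(p.size for p in self.parameters()))


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
        np.float32)


class Conv3x3(Module):
    def __init__(self, cin, cout, rng, zero_init=False):
        if zero_init:
            self.weight = Parameter(np.zeros((cout, cin, 3, 3)))
        else:
            self.weight = Parameter(_he(rng, (cout, cin, 3, 3), cin * 9))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias)


class Conv1x1(Module):
    def __init__(self, cin, cout, rng):
        self.weight = Parameter(_he(rng, (cout, cin), cin))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x):
        return conv1x1(x, self.weight, self.bias)


class DoubleConv(Module):
    """conv3x3 -> ReLU -> conv3x3 -> ReLU (the classic U-stage block)."""

    def __init__(self, cin, cout, rng, n_convs=2):
        self.convs = [Conv3x3(cin if i == 0 else cout, cout, rng)
                      for i in range(n_convs)]

    def __call__(self, x):
        for c in self.convs:
            x = relu(c(x))
        return x


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay.

    v <- momentum * v + grad + weight_decay * p;  p <- p - lr * v
    """

    def __init__(self, params, lr=5e-4, momentum=0.9, weight_decay=5e-4,
                 clip_norm=None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _clip(self):
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in self.params if p.grad is not None))
        if total > self.clip_norm and total > 0:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale

    def step(self):
        if self.clip_norm is not None:
            self._clip()
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def state_dict(self):
        return {"lr": self.lr, "momentum": self.momentum,
                "weight_decay": self.weight_decay,
                "velocity": [v.copy() for v in self.velocity]}

    def load_state_dict(self, state):
        self.lr = state["lr"]
        self.momentum = state["momentum"]
        self.weight_decay = state["weight_decay"]
        self.velocity = [np.asarray(v) for v in state["velocity"]]
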