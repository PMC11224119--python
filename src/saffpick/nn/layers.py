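"""Layer abstractions over the autodiff core: modules, convolutions, BN."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable layer with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float64).reshape(
                    params[name].data.shape
                )
            elif name in buffers:
                buffers[name][...] = np.asarray(value, dtype=np.float64)
            else:
                raise KeyError(f"unknown state entry {name!r}")


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Dense or depthwise 2-D convolution with He-normal init."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=None, dilation=1,
                 groups=1, bias=True, rng=None, init_std=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:  # "same" for stride 1, halving for stride 2
            padding = dilation * (kernel - 1) // 2
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_ch // groups) * kernel * kernel
        std = init_std if init_std is not None else np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization with cumulative running statistics.

    Running statistics are the plain average of per-batch statistics seen so
    far, which makes short desk-scale training runs deterministic and keeps
    eval-mode behavior close to train-mode on small fixed datasets.
    """

    def __init__(self, channels, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._count = 0

    def forward(self, x):
        if self.training:
            out, mu, var = ad.batchnorm_train(x, self.gamma, self.beta, self.eps)
            self._count += 1
            k = 1.0 / self._count
            self.running_mean += k * (np.atleast_1d(mu) - self.running_mean)
            self.running_var += k * (np.atleast_1d(var) - self.running_var)
            return out
        return ad.batchnorm_eval(x, self.gamma, self.beta,
                                 self.running_mean, self.running_var, self.eps)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class ConvBNReLU(Sequential):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, dilation=1, groups=1):
        super().__init__(
            Conv2d(in_ch, out_ch, kernel, stride=stride, dilation=dilation,
                   groups=groups, bias=False, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
        )


class DepthwiseSeparableConv(Module):
    """k×k per-channel (optionally dilated) conv then 1×1 cross-channel conv.

    Parameter cost is k²·C_in + C_in·C_out against k²·C_in·C_out for the
    dense equivalent.
    """

    def __init__(self, in_ch, out_ch, kernel=3, dilation=1, stride=1, rng=None,
                 bias=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depthwise = Conv2d(in_ch, in_ch, kernel, stride=stride,
                                dilation=dilation, groups=in_ch, bias=False, rng=rng)
        self.pointwise = Conv2d(in_ch, out_ch, 1, bias=bias, rng=rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))

    @staticmethod
    def parameter_count(kernel: int, in_ch: int, out_ch: int) -> int:
        return kernel * kernel * in_ch + in_ch * out_ch

    @staticmethod
    def standard_parameter_count(kernel: int, in_ch: int, out_ch: int) -> int:
        return kernel * kernel * in_ch * out_ch
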