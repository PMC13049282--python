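"""Layer and module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F


class Module:
    """Base class: tracks parameters, supports state dicts and modes."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self._buffers: dict[str, dict] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        sd = {prefix + k: v.data.copy() for k, v in self._params.items()}
        for k, buf in self._buffers.items():
            for bk, bv in buf.items():
                sd[f"{prefix}{k}.{bk}"] = np.asarray(bv).copy()
        for name, child in self._children.items():
            sd.update(child.state_dict(prefix + name + "."))
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray], prefix: str = ""):
        for k, v in self._params.items():
            v.data = np.asarray(sd[prefix + k], dtype=np.float64).copy()
        for k, buf in self._buffers.items():
            for bk in buf:
                buf[bk] = np.asarray(sd[f"{prefix}{k}.{bk}"], dtype=np.float64).copy()
        for name, child in self._children.items():
            child.load_state_dict(sd, prefix + name + ".")

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        super().__init__()
        w = np.zeros((cout, cin, k, k)) if zero_init else \
            _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.register("weight", w)
        if bias:
            self.register("bias", np.zeros(cout))
        else:
            self.bias = None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.register("gamma", np.ones(channels))
        self.register("beta", np.zeros(channels))
        self._buffers["running"] = {"mean": np.zeros(channels),
                                    "var": np.ones(channels)}

    def __call__(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(x, self.gamma, self.beta,
                             running=self._buffers["running"],
                             training=self.training)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        w = np.zeros((fout, fin)) if zero_init else \
            _he_init(rng, (fout, fin), fin)
        self.register("weight", w)
        self.register("bias", np.zeros(fout))

    def __call__(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class Adam:
    """Adam with optional polynomial learning-rate decay lr·(1−t/T)^power."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 total_steps: int | None = None, poly_power: float = 0.9):
        self.params = params
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.total_steps = total_steps
        self.poly_power = poly_power
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    @property
    def lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * (1.0 - frac) ** self.poly_power

    def step(self):
        lr = self.lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
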