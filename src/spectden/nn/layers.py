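"""Layer modules over the autodiff engine: convolutions, batch norm, dropout.

Parameters are float32.  Every module draws its initial weights from an
``np.random.Generator`` passed in by the builder so that network construction
is fully deterministic.
"""

from __future__ import annotations

import numpy as np

from . import _convops
from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter registry and train/eval mode propagation."""

    def __init__(self):
        self.training = True
        self._modules: list[Module] = []
        self._params: dict[str, Tensor] = {}

    def add_module(self, m: "Module") -> "Module":
        self._modules.append(m)
        return m

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        # per-type counters keep names stable when optional modules (e.g.
        # attention gates) are interleaved with the shared structure
        out = {prefix + k: v for k, v in self._params.items()}
        counters: dict[str, int] = {}
        for m in self._modules:
            t = type(m).__name__
            i = counters.get(t, 0)
            counters[t] = i + 1
            out.update(m.named_parameters(f"{prefix}{t}{i}."))
        return out

    def train(self) -> None:
        self.training = True
        for m in self._modules:
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules:
            m.eval()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for k, v in self.buffers().items():
            out["buffer:" + k] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        bufs = self.buffers()
        for k, v in state.items():
            if k.startswith("buffer:"):
                bufs[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = v

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = dict(getattr(self, "_buffers", {}))
        out = {prefix + k: v for k, v in out.items()}
        counters: dict[str, int] = {}
        for m in self._modules:
            t = type(m).__name__
            i = counters.get(t, 0)
            counters[t] = i + 1
            out.update(m.buffers(f"{prefix}{t}{i}."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv3d(Module):
    """3x3x3 convolution, stride 1 or 2, padding 1, He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True):
        super().__init__()
        self.stride = stride
        std = np.sqrt(2.0 / (27 * c_in))
        self.w = self.add_param("w", rng.normal(0.0, std, size=(27, c_in, c_out)))
        self.b = self.add_param("b", np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, stride=self.stride)


class Conv1x1(Module):
    """Pointwise convolution (channel mixing only)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True, bias_init: float = 0.0):
        super().__init__()
        std = np.sqrt(2.0 / c_in)
        self.w = self.add_param("w", rng.normal(0.0, std, size=(c_in, c_out)))
        self.b = (self.add_param("b", np.full(c_out, bias_init, dtype=np.float64))
                  if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1x1(x, self.w, self.b)


class BatchNorm(Module):
    """Batch normalization over all non-channel axes.

    Normalizes by the statistics of the current batch in BOTH training and
    evaluation — at batch size 1 this is instance normalization, the
    convention of the pix2pix family of image-to-image models, and it avoids
    the train/eval distribution gap that population statistics suffer from
    at tiny batch sizes.  Evaluation therefore stays deterministic for a
    given input.
    """

    def __init__(self, c: int):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(c))
        self.beta = self.add_param("beta", np.zeros(c))

    def __call__(self, x: Tensor) -> Tensor:
        n = x.data.size // x.data.shape[-1]
        if n == 1:
            # variance of a single sample is undefined; apply the affine
            # part only instead of collapsing the activation to zero
            return ag.add(ag.mul(x, self.gamma), self.beta)
        axes = tuple(range(x.data.ndim - 1))
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        return ag.batchnorm(x, self.gamma, self.beta, mean, var, self.training)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.rate, self.rng, self.training)


class Adam:
    """Adam optimizer with the conventional bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self._scratch = [np.empty_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        # fold the bias corrections into the step size (fused in-place update)
        alpha = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.ascontiguousarray(p.grad, dtype=p.data.dtype)
            _convops.adam_update(p.data.reshape(-1), g.reshape(-1),
                                 self.m[i].reshape(-1), self.v[i].reshape(-1),
                                 self.b1, self.b2, alpha, self.eps,
                                 scratch=self._scratch[i].reshape(-1))
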