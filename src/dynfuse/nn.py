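"""Neural-network layers and optimization on top of :mod:`dynfuse.tensor`.

Layers follow the familiar torch-ish surface (``Module`` with named
parameters, train/eval modes, ``Sequential``) but are deliberately small:
only the pieces the fusion architecture needs exist.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Linear", "ReLU", "GELU", "Tanh", "Dropout", "LayerNorm",
    "BatchNorm1d", "Sequential", "Identity", "AdamW", "clip_grad_norm",
]


class Module:
    """Base class: recursive named-parameter collection and mode switching."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[full] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(full))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{full}.{i}"))
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{full}.{key}"))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(value, dict):
                for item in value.values():
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

    # -- flat state for checkpointing ------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for name, mod in self._named_modules():
            for key, arr in getattr(mod, "_buffers", {}).items():
                state[f"{name}.{key}" if name else key] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = {f"{name}.{key}" if name else key: (mod, key)
                   for name, mod in self._named_modules()
                   for key in getattr(mod, "_buffers", {})}
        for key, arr in state.items():
            if key in params:
                if params[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{params[key].data.shape} vs {arr.shape}")
                params[key].data = np.array(arr, dtype=np.float64)
            elif key in buffers:
                mod, bkey = buffers[key]
                mod._buffers[bkey] = np.array(arr, dtype=np.float64)
            else:
                raise KeyError(f"unexpected state key: {key}")

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Module):
                yield from value._named_modules(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{full}.{i}")
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{full}.{key}")


class Linear(Module):
    """Affine map ``x @ W.T + b`` with Kaiming-uniform initialization."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(6.0 / in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(out_features, in_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.T
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Owns its RNG for determinism."""

    def __init__(self, p: float = 0.3, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    """Normalize the last axis to zero mean / unit variance, then affine."""

    def __init__(self, dim: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.dim = dim
        if affine:
            self.gamma = Tensor(np.ones(dim), requires_grad=True)
            self.beta = Tensor(np.zeros(dim), requires_grad=True)
        else:
            self.gamma = None
            self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xhat = centered * (var + self.eps).pow(-0.5)
        if self.gamma is not None:
            xhat = xhat * self.gamma + self.beta
        return xhat


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for eval."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._buffers = {"running_mean": np.zeros(dim), "running_var": np.ones(dim)}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = ((1 - m) * self._buffers["running_mean"]
                                             + m * mu.data.ravel())
            self._buffers["running_var"] = ((1 - m) * self._buffers["running_var"]
                                            + m * var.data.ravel())
            xhat = centered * (var + self.eps).pow(-0.5)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            xhat = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        return xhat * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class AdamW(Module):
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = dict(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`.

    Returns the pre-clip global norm.
    """
    tensors = list(params.values()) if isinstance(params, dict) else list(params)
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in tensors if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in tensors:
            if p.grad is not None:
                p.grad *= scale
    return total
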