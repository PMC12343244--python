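"""Neural building blocks: modules, linear/embedding layers, layer norm, GRU."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Linear", "Embedding", "LayerNorm", "GRU", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    """Minimal module with recursive parameter discovery and state dicts."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, tensor in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Lookup table; rows addressed by integer indices."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(num_embeddings, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return ag.gather_rows(self.weight, np.asarray(indices, dtype=np.intp))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, eps=self.eps)


class GRU(Module):
    """Single-direction gated recurrent unit over a padded batch.

    Input ``x`` is B x T x d_in; returns the B x T x d_h sequence of hidden
    states.  Padded timesteps are processed too, but causality means outputs
    at valid positions never depend on trailing padding; callers pool only
    over valid positions.
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        d = hidden_dim
        self.w_z = Tensor(glorot(rng, in_dim, d), requires_grad=True)
        self.u_z = Tensor(glorot(rng, d, d), requires_grad=True)
        self.b_z = Tensor(np.zeros(d), requires_grad=True)
        self.w_r = Tensor(glorot(rng, in_dim, d), requires_grad=True)
        self.u_r = Tensor(glorot(rng, d, d), requires_grad=True)
        self.b_r = Tensor(np.zeros(d), requires_grad=True)
        self.w_h = Tensor(glorot(rng, in_dim, d), requires_grad=True)
        self.u_h = Tensor(glorot(rng, d, d), requires_grad=True)
        self.b_h = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        x = ag.as_tensor(x)
        batch, steps, _ = x.shape
        h = Tensor(np.zeros((batch, self.hidden_dim)))
        outputs = []
        for t in range(steps):
            xt = x[:, t, :]
            z = ag.sigmoid(xt @ self.w_z + h @ self.u_z + self.b_z)
            r = ag.sigmoid(xt @ self.w_r + h @ self.u_r + self.b_r)
            cand = ag.tanh(xt @ self.w_h + (r * h) @ self.u_h + self.b_h)
            h = (1.0 - z) * h + z * cand
            outputs.append(h)
        return ag.stack(outputs, axis=1)
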