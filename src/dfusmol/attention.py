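"""Masked dual-channel (global/local) attention over fused motif features.

The fused motif matrix H (N x d, N = n motifs + the [GLOBAL] node) is split
along the feature axis into two halves.  The first half feeds a *global*
channel whose raw attention scores are elementwise-multiplied by the motif
distance matrix D; the second half feeds a *local* channel masked by the
adjacency matrix A:

    Attention_c = softmax((Q K^T  *  mask) / sqrt(d/2)) V        per head

Multiplicative masking is applied exactly as written: a zero mask entry
zeroes the raw score (it does not remove the key from the softmax).  An
``additive_neg_inf`` mode — zero mask entries mapped to -inf before the
softmax — is available as a configurable alternative, as is ``none``.

Each stacked layer concatenates the two channel outputs, adds the residual
and applies layer normalization.  The refined [GLOBAL] row, scaled by a
learnable alpha, is finally added to the encoder's molecule embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag

MASK_MODES = ("multiplicative", "additive_neg_inf", "none")


@dataclass
class AttentionConfig:
    """Shape and behaviour of the attention stack.

    ``model_dim`` is split into two equal channel subspaces, each divided
    among ``heads_per_channel`` heads.  ``alpha_init`` seeds the learnable
    scalar that gates the motif contribution into the final representation.
    """

    model_dim: int = 256
    heads_per_channel: int = 4
    num_layers: int = 2
    alpha_init: float = 0.1
    mask_mode: str = "multiplicative"
    distance_transform: str = "identity"   # or "reciprocal"
    self_loops: bool = False

    def __post_init__(self):
        if self.model_dim % 2:
            raise ValueError("model_dim must be even (two equal channel subspaces)")
        if (self.model_dim // 2) % self.heads_per_channel:
            raise ValueError("channel width must be divisible by heads_per_channel")
        if self.mask_mode not in MASK_MODES:
            raise ValueError(f"mask_mode must be one of {MASK_MODES}")
        if self.distance_transform not in ("identity", "reciprocal"):
            raise ValueError("distance_transform must be 'identity' or 'reciprocal'")


@dataclass
class MoleculeRepresentation:
    """Final vector M' = M + alpha * H'[GLOBAL]."""

    vector: np.ndarray


def channel_attention(h_c, mask, w_q, w_k, w_v, n_heads: int = 1,
                      mask_mode: str = "multiplicative",
                      return_weights: bool = False):
    """One channel of masked multi-head attention.

    ``h_c`` is N x (d/2); Q, K, V projections are (d/2) x (d/2) and split
    into ``n_heads`` equal feature chunks.  Scores are scaled by sqrt(d/2).
    Returns the N x (d/2) output, and optionally the per-head softmax
    weight matrices.
    """
    h_c = ag.as_tensor(h_c)
    n, width = h_c.shape
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != (n, n):
        raise ValueError(f"mask shape {mask.shape} does not match {n} motif rows")
    q = h_c @ ag.as_tensor(w_q)
    k = h_c @ ag.as_tensor(w_k)
    v = h_c @ ag.as_tensor(w_v)
    head_dim = width // n_heads
    scale = float(np.sqrt(width))
    outputs, weights = [], []
    for h in range(n_heads):
        sl = slice(h * head_dim, (h + 1) * head_dim)
        scores = q[:, sl] @ k[:, sl].T
        if mask_mode == "multiplicative":
            scores = scores * Tensor(mask)
        elif mask_mode == "additive_neg_inf":
            # replacement, not addition: a fully-masked row degrades to the
            # uniform distribution instead of silently ignoring the mask
            keep = (mask != 0).astype(np.float64)
            scores = scores * Tensor(keep) + Tensor(np.where(mask == 0, -1e9, 0.0))
        attn = ag.softmax(scores / scale, axis=-1)
        outputs.append(attn @ v[:, sl])
        weights.append(attn)
    out = ag.concat(outputs, axis=1)
    if return_weights:
        return out, weights
    return out


class GLAttentionLayer(nn.Module):
    """One global-local layer: two masked channels, concat, residual, LayerNorm."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.config = config
        half = config.model_dim // 2
        self.wq_g = Tensor(nn.glorot(rng, half, half), requires_grad=True)
        self.wk_g = Tensor(nn.glorot(rng, half, half), requires_grad=True)
        self.wv_g = Tensor(nn.glorot(rng, half, half), requires_grad=True)
        self.wq_l = Tensor(nn.glorot(rng, half, half), requires_grad=True)
        self.wk_l = Tensor(nn.glorot(rng, half, half), requires_grad=True)
        self.wv_l = Tensor(nn.glorot(rng, half, half), requires_grad=True)
        self.norm = nn.LayerNorm(config.model_dim)

    def forward(self, h: Tensor, adjacency: np.ndarray, distance: np.ndarray,
                return_weights: bool = False):
        cfg = self.config
        half = cfg.model_dim // 2
        h = ag.as_tensor(h)
        h_g, h_l = h[:, :half], h[:, half:]
        out_g, w_g = channel_attention(h_g, distance, self.wq_g, self.wk_g, self.wv_g,
                                       cfg.heads_per_channel, cfg.mask_mode,
                                       return_weights=True)
        out_l, w_l = channel_attention(h_l, adjacency, self.wq_l, self.wk_l, self.wv_l,
                                       cfg.heads_per_channel, cfg.mask_mode,
                                       return_weights=True)
        out = self.norm(h + ag.concat([out_g, out_l], axis=1))
        if return_weights:
            return out, {"global": w_g, "local": w_l}
        return out


class GLTransformer(nn.Module):
    """L stacked global-local attention layers plus the learnable alpha."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.layers = [GLAttentionLayer(config, rng) for _ in range(config.num_layers)]
        self.alpha = Tensor(np.array(config.alpha_init), requires_grad=True)

    def prepare_masks(self, adjacency: np.ndarray, distance: np.ndarray,
                      use_adjacency: bool = True, use_distance: bool = True):
        """Apply ablations and configured transforms to the raw matrices."""
        cfg = self.config
        a = np.asarray(adjacency, dtype=np.float64)
        d = np.asarray(distance, dtype=np.float64)
        if cfg.self_loops:
            a = np.clip(a + np.eye(len(a)), 0, 1)
        if cfg.distance_transform == "reciprocal":
            with np.errstate(divide="ignore"):
                d = np.where(d > 0, 1.0 / d, 0.0)
        if not use_adjacency:
            a = np.ones_like(a)
        if not use_distance:
            d = np.ones_like(d)
        return a, d

    def forward(self, h: Tensor, adjacency: np.ndarray, distance: np.ndarray) -> Tensor:
        for layer in self.layers:
            h = layer.forward(h, adjacency, distance)
        return h

    def attention_weights(self, h, adjacency: np.ndarray, distance: np.ndarray,
                          layer_index: int = -1) -> dict[str, list[np.ndarray]]:
        """Per-head N x N softmax matrices of one layer (rows sum to 1)."""
        n_layers = len(self.layers)
        if not (-n_layers <= layer_index < n_layers):
            raise IndexError(f"layer index {layer_index} out of range for {n_layers} layers")
        layer_index %= n_layers
        h = ag.as_tensor(h)
        captured = None
        for i, layer in enumerate(self.layers):
            if i == layer_index:
                h, captured = layer.forward(h, adjacency, distance, return_weights=True)
            else:
                h = layer.forward(h, adjacency, distance)
        return {channel: [w.data.copy() for w in ws] for channel, ws in captured.items()}


def finalize(molecule_embedding, h_refined, alpha, global_index: int) -> Tensor:
    """M' = M + alpha * H'[GLOBAL]; with alpha = 0 this is exactly M."""
    m = ag.as_tensor(molecule_embedding)
    h = ag.as_tensor(h_refined)
    return m + ag.as_tensor(alpha) * h[global_index]
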