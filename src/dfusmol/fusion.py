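"""Atom-to-motif projection and additive identity fusion.

Atomic embeddings are aggregated onto motifs through the binary motif-atom
association matrix F, normalized by the molecule's total atom count m,
linearly projected and passed through ReLU:

    H_atomic = ReLU((1/m) F X W_G + b_G)

Each motif row is then fused additively with the motif's identity embedding
looked up from a trainable table, and the [GLOBAL] node's embedding —
carrying no atomic signal by construction — is appended as the final row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag


@dataclass
class FusedMotifFeatures:
    """(n+1) x d' fused motif matrix; the last row is the [GLOBAL] node."""

    H: np.ndarray
    global_index: int


def project_atoms_to_motifs(association, atom_embeddings, weight, bias,
                            n_atoms: int | None = None, per_motif_norm: bool = False) -> Tensor:
    """ReLU((1/m) F X W_G + b_G) as a differentiable tensor.

    With ``per_motif_norm`` the 1/m factor is replaced by each motif's own
    atom count (row sums of F), removing the size bias the global factor
    only partially addresses.
    """
    f = np.asarray(association, dtype=np.float64)
    x = ag.as_tensor(atom_embeddings)
    if f.shape[1] != x.shape[0]:
        raise ValueError(f"association has {f.shape[1]} atom columns but embeddings have "
                         f"{x.shape[0]} rows")
    if per_motif_norm:
        norm = f.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        f_scaled = f / norm
    else:
        m = float(n_atoms if n_atoms is not None else f.shape[1])
        f_scaled = f / m
    return nn.relu(Tensor(f_scaled) @ x @ ag.as_tensor(weight) + ag.as_tensor(bias))


def fuse(projected, identity_embeddings, global_embedding) -> Tensor:
    """Motif rows = projection + identity embedding; [GLOBAL] row appended."""
    projected = ag.as_tensor(projected)
    identity_embeddings = ag.as_tensor(identity_embeddings)
    if projected.shape != identity_embeddings.shape:
        raise ValueError(f"shape mismatch: {projected.shape} vs {identity_embeddings.shape}")
    g = ag.as_tensor(global_embedding)
    g2 = g if g.ndim == 2 else g.reshape(1, -1)
    return ag.concat([projected + identity_embeddings, g2], axis=0)


class MotifFusion(nn.Module):
    """Trainable fusion block: projection weights plus the embedding table.

    The table holds one row per vocabulary index (the last vocabulary index
    is [UNK]) plus a dedicated final row for the [GLOBAL] node.
    """

    def __init__(self, atom_dim: int, motif_dim: int, vocab_size: int,
                 rng: np.random.Generator | None = None, per_motif_norm: bool = False):
        rng = rng or np.random.default_rng(0)
        self.per_motif_norm = per_motif_norm
        self.weight = Tensor(nn.glorot(rng, atom_dim, motif_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(motif_dim), requires_grad=True)
        self.embeddings = nn.Embedding(vocab_size + 1, motif_dim, rng)
        self.global_row = vocab_size

    def __call__(self, association: np.ndarray, atom_embeddings, motif_indices: np.ndarray) -> Tensor:
        projected = project_atoms_to_motifs(
            association, atom_embeddings, self.weight, self.bias,
            per_motif_norm=self.per_motif_norm)
        identity = self.embeddings(np.asarray(motif_indices, dtype=np.intp))
        global_emb = self.embeddings(np.array([self.global_row], dtype=np.intp))
        return fuse(projected, identity, global_emb)
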