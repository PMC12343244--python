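"""Communicative message passing over directed molecular graphs.

Node and edge hidden states are updated jointly: each node aggregates its
incoming directed-edge features as SUM * MAX (elementwise product of the
elementwise sum and elementwise max), adds the message to its own state, and
each edge is refreshed from its source node minus the reverse edge — the
subtraction stops a bond's message from echoing straight back to where it
came from.  After K rounds a COMMUNICATE step (linear + ReLU over the sum of
final node state, final message, and projected input feature) produces the
per-atom embeddings, and a bidirectional GRU over the canonically ordered
atom sequence followed by mean pooling yields the molecule embedding.

Batches of molecules are processed as one disjoint union graph; segment
reductions keep everything vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .chem_graph import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph
from .nn import Tensor
from .nn import autograd as ag


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with per-molecule bookkeeping."""

    atom_features: np.ndarray     # (sum_m, d0_atom)
    edge_inputs: np.ndarray       # (E, d0_atom + d0_bond): source atom + bond features
    edge_sources: np.ndarray      # (E,) global atom indices
    edge_targets: np.ndarray      # (E,)
    reverse_index: np.ndarray     # (E,)
    mol_of_atom: np.ndarray       # (sum_m,)
    atom_counts: np.ndarray       # (B,)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_mols(self) -> int:
        return len(self.atom_counts)

    @property
    def atom_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.atom_counts)])

    @classmethod
    def from_graphs(cls, graphs: Sequence[MolecularGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("cannot batch zero molecules")
        if any(g.n_atoms == 0 for g in graphs):
            raise ValueError("cannot encode an empty molecular graph")
        atom_feats, edge_inputs = [], []
        srcs, dsts, revs, mol_ids = [], [], [], []
        atom_off = edge_off = 0
        for i, g in enumerate(graphs):
            atom_feats.append(g.atom_features)
            mol_ids.extend([i] * g.n_atoms)
            if g.n_edges:
                src = g.edge_sources
                edge_inputs.append(np.hstack([g.atom_features[src], g.bond_features]))
                srcs.append(src + atom_off)
                dsts.append(g.edge_targets + atom_off)
                revs.append(g.reverse_index + edge_off)
            atom_off += g.n_atoms
            edge_off += g.n_edges
        cat = (lambda parts, w: np.concatenate(parts) if parts else np.zeros((0,) if w is None else (0, w)))
        return cls(
            atom_features=np.vstack(atom_feats),
            edge_inputs=cat(edge_inputs, ATOM_FEATURE_DIM + BOND_FEATURE_DIM),
            edge_sources=cat(srcs, None).astype(np.intp),
            edge_targets=cat(dsts, None).astype(np.intp),
            reverse_index=cat(revs, None).astype(np.intp),
            mol_of_atom=np.array(mol_ids, dtype=np.intp),
            atom_counts=np.array([g.n_atoms for g in graphs], dtype=np.intp),
        )


@dataclass
class EncoderOutput:
    """Per-atom embeddings X_i and the pooled molecule embedding M."""

    atom_embeddings: np.ndarray    # (m, d)
    molecule_embedding: np.ndarray  # (d,)


@dataclass
class PaddedBatch:
    """Atom-embedding matrices padded with zero rows to a common length."""

    features: np.ndarray    # (B, M_max, d)
    atom_counts: np.ndarray  # (B,)


# ---------------------------------------------------------------------------
# functional message-passing operations (also used as the public op surface)


def aggregate_incoming(edge_hidden, incoming: Sequence[Sequence[int]]) -> Tensor:
    """Per-node message: elementwise (SUM of incoming) * (MAX of incoming).

    ``incoming[v]`` lists the edge rows that point at node v; nodes with no
    incoming edges get the zero vector.
    """
    edge_hidden = ag.as_tensor(edge_hidden)
    d = edge_hidden.shape[1]
    rows = []
    for edge_ids in incoming:
        if len(edge_ids) == 0:
            rows.append(Tensor(np.zeros(d)))
            continue
        feats = ag.gather_rows(edge_hidden, np.asarray(edge_ids, dtype=np.intp))
        s = feats.sum(axis=0)
        mx = ag.segment_max(feats, np.zeros(len(edge_ids), dtype=np.intp), 1)[0]
        rows.append(s * mx)
    return ag.stack(rows, axis=0)


def update_node(h_prev, message) -> Tensor:
    """Node update: new state = previous state + aggregated message."""
    h_prev, message = ag.as_tensor(h_prev), ag.as_tensor(message)
    if h_prev.shape != message.shape:
        raise ValueError(f"shape mismatch: {h_prev.shape} vs {message.shape}")
    return h_prev + message

def update_edge(h_source, h_reverse, h_initial, weight) -> Tensor:
    """Edge update: ReLU(W (h_u - h_vu) + h_uv^0)."""
    message = ag.as_tensor(h_source) - ag.as_tensor(h_reverse)
    return nn.relu(message @ ag.as_tensor(weight) + ag.as_tensor(h_initial))


def pad_batch(atom_matrices: Sequence[np.ndarray]) -> PaddedBatch:
    """Pad each m_i x d matrix with zero rows up to M_max = max(m_i)."""
    widths = {np.asarray(x).shape[1] for x in atom_matrices}
    if len(widths) != 1:
        raise ValueError(f"inconsistent feature widths across molecules: {sorted(widths)}")
    d = widths.pop()
    counts = np.array([np.asarray(x).shape[0] for x in atom_matrices], dtype=np.intp)
    m_max = int(counts.max())
    out = np.zeros((len(atom_matrices), m_max, d))
    for i, x in enumerate(atom_matrices):
        out[i, : counts[i]] = x
    return PaddedBatch(features=out, atom_counts=counts)


# ---------------------------------------------------------------------------


class CMPNNEncoder(nn.Module):
    """K-round communicative message passing plus GRU readout.

    Parameters
    ----------
    hidden_dim:
        Width d of node/edge hidden states and of the output embeddings.
    depth:
        Number K of message-passing rounds (edges are refreshed between
        rounds, so K rounds use K-1 edge-update weight matrices).
    readout:
        ``"gru_mean"`` (bidirectional GRU over the canonical atom order, mean
        pooled, then projected back to d) or plain ``"mean"``.
    """

    def __init__(self, hidden_dim: int = 256, depth: int = 3,
                 readout: str = "gru_mean", rng: np.random.Generator | None = None):
        if depth < 0:
            raise ValueError("depth must be >= 0")
        if readout not in ("gru_mean", "mean"):
            raise ValueError(f"unknown readout: {readout!r}")
        rng = rng or np.random.default_rng(0)
        self.hidden_dim = hidden_dim
        self.depth = depth
        self.readout = readout
        self.atom_proj = nn.Linear(ATOM_FEATURE_DIM, hidden_dim, rng)
        self.bond_proj = nn.Linear(ATOM_FEATURE_DIM + BOND_FEATURE_DIM, hidden_dim, rng)
        self.edge_updates = [nn.Linear(hidden_dim, hidden_dim, rng, bias=False)
                             for _ in range(max(depth - 1, 0))]
        self.communicate = nn.Linear(hidden_dim, hidden_dim, rng)
        if readout == "gru_mean":
            self.gru_fwd = nn.GRU(hidden_dim, hidden_dim, rng)
            self.gru_bwd = nn.GRU(hidden_dim, hidden_dim, rng)
            self.readout_proj = nn.Linear(2 * hidden_dim, hidden_dim, rng)

    # -- message passing --------------------------------------------------
    def atom_hidden(self, batch: GraphBatch) -> Tensor:
        """Run message passing and COMMUNICATE; returns (sum_m, d) embeddings."""
        n = batch.n_atoms
        x = nn.relu(self.atom_proj(Tensor(batch.atom_features)))
        h_node = x
        if batch.edge_inputs.shape[0]:
            e0 = nn.relu(self.bond_proj(Tensor(batch.edge_inputs)))
            h_edge = e0
        else:
            e0 = h_edge = None
        message = Tensor(np.zeros((n, self.hidden_dim)))
        for k in range(self.depth):
            if h_edge is not None:
                message = (ag.segment_sum(h_edge, batch.edge_targets, n)
                           * ag.segment_max(h_edge, batch.edge_targets, n))
            h_node = h_node + message
            if k < self.depth - 1 and h_edge is not None:
                edge_msg = (ag.gather_rows(h_node, batch.edge_sources)
                            - ag.gather_rows(h_edge, batch.reverse_index))
                h_edge = nn.relu(edge_msg @ self.edge_updates[k].weight + e0)
        return nn.relu(self.communicate(h_node + message + x))

    # -- readout -----------------------------------------------------------
    def _gru_readout(self, atom_hidden: Tensor, batch: GraphBatch) -> Tensor:
        counts = batch.atom_counts
        b, t = batch.n_mols, int(counts.max())
        offsets = batch.atom_offsets
        # pad via gather from an extended matrix whose last row is zero
        zero_row = Tensor(np.zeros((1, self.hidden_dim)))
        ext = ag.concat([atom_hidden, zero_row], axis=0)
        pad_row = atom_hidden.shape[0]
        pad_idx = np.full((b, t), pad_row, dtype=np.intp)
        rev_idx = np.tile(np.arange(t, dtype=np.intp), (b, 1))  # within-batch involution
        for i in range(b):
            m = counts[i]
            pad_idx[i, :m] = offsets[i] + np.arange(m)
            rev_idx[i, :m] = np.arange(m)[::-1]
        padded = ag.gather_rows(ext, pad_idx.reshape(-1)).reshape(b, t, self.hidden_dim)
        flat_rev = (rev_idx + np.arange(b)[:, None] * t).reshape(-1)

        out_f = self.gru_fwd(padded)
        rev_in = ag.gather_rows(padded.reshape(b * t, self.hidden_dim), flat_rev)
        out_b = self.gru_bwd(rev_in.reshape(b, t, self.hidden_dim))
        out_b = ag.gather_rows(out_b.reshape(b * t, self.hidden_dim), flat_rev)
        both = ag.concat([out_f.reshape(b * t, self.hidden_dim), out_b], axis=1)
        both = self.readout_proj(both).reshape(b, t, self.hidden_dim)

        mask = (pad_idx != pad_row).astype(np.float64)[:, :, None]
        pooled = (both * Tensor(mask)).sum(axis=1) / Tensor(counts[:, None].astype(np.float64))
        return pooled

    def forward(self, batch: GraphBatch) -> tuple[Tensor, Tensor]:
        """Returns (atom embeddings (sum_m, d), molecule embeddings (B, d))."""
        atom_hidden = self.atom_hidden(batch)
        if self.readout == "mean":
            sums = ag.segment_sum(atom_hidden, batch.mol_of_atom, batch.n_mols)
            pooled = sums / Tensor(batch.atom_counts[:, None].astype(np.float64))
        else:
            pooled = self._gru_readout(atom_hidden, batch)
        return atom_hidden, pooled

    def encode(self, graph: MolecularGraph) -> EncoderOutput:
        """Encode a single molecule (inference convenience; no gradients kept)."""
        batch = GraphBatch.from_graphs([graph])
        atoms, mols = self.forward(batch)
        return EncoderOutput(atom_embeddings=atoms.data.copy(),
                             molecule_embedding=mols.data[0].copy())
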