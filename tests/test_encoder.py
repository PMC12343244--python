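"""Communicative message passing: functional ops, loop-oracle equivalence,
padding, locality and determinism."""

from __future__ import annotations

import numpy as np
import pytest

from dfusmol.chem_graph import smiles_to_graph
from dfusmol.encoder import (
    CMPNNEncoder,
    GraphBatch,
    aggregate_incoming,
    pad_batch,
    update_edge,
    update_node,
)
from dfusmol.nn import Tensor

from conftest import random_molgraph


# ---------------------------------------------------------------------------
# loop oracle: re-derives the encoder's atom embeddings with explicit
# per-node / per-edge python loops from the same weights


def loop_oracle_atom_embeddings(encoder: CMPNNEncoder, graph) -> np.ndarray:
    def lin(layer, v):
        out = v @ layer.weight.data
        return out + layer.bias.data if layer.bias is not None else out

    relu = lambda a: np.maximum(a, 0.0)
    n, d = graph.n_atoms, encoder.hidden_dim
    x = np.array([relu(lin(encoder.atom_proj, graph.atom_features[i])) for i in range(n)])
    e0 = {}
    for e, (u, v) in enumerate(graph.edges):
        raw = np.concatenate([graph.atom_features[u], graph.bond_features[e]])
        e0[e] = relu(lin(encoder.bond_proj, raw))
    h_node = {i: x[i].copy() for i in range(n)}
    h_edge = dict(e0)
    message = {i: np.zeros(d) for i in range(n)}

    def aggregate():
        msg = {}
        for i in range(n):
            incoming = [h_edge[e] for e, (_, tgt) in enumerate(graph.edges) if tgt == i]
            if incoming:
                msg[i] = np.sum(incoming, axis=0) * np.max(incoming, axis=0)
            else:
                msg[i] = np.zeros(d)
        return msg

    for k in range(encoder.depth):
        message = aggregate()
        for i in range(n):
            h_node[i] = h_node[i] + message[i]
        if k < encoder.depth - 1:
            new_edges = {}
            for e, (u, _) in enumerate(graph.edges):
                m_uv = h_node[u] - h_edge[graph.reverse_index[e]]
                new_edges[e] = relu(m_uv @ encoder.edge_updates[k].weight.data + e0[e])
            h_edge = new_edges
    return np.array([relu(lin(encoder.communicate, h_node[i] + message[i] + x[i]))
                     for i in range(n)])


# ---------------------------------------------------------------------------
# functional ops


def test_single_incoming_edge_message_is_square():
    h = Tensor(np.array([[1.0, -2.0, 3.0]]))
    msg = aggregate_incoming(h, [[0]])
    np.testing.assert_allclose(msg.data, [[1.0, 4.0, 9.0]])  # h * h elementwise


def test_sum_times_elementwise_max():
    h = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    msg = aggregate_incoming(h, [[0, 1]])
    np.testing.assert_allclose(msg.data, [[1.0, 1.0]])


def test_isolated_node_gets_zero_message():
    h = Tensor(np.array([[1.0, 1.0]]))
    msg = aggregate_incoming(h, [[0], []])
    np.testing.assert_allclose(msg.data[1], 0.0)


def test_update_node_is_vector_addition():
    h = Tensor(np.array([1.0, 2.0]))
    np.testing.assert_allclose(update_node(h, Tensor(np.array([3.0, -1.0]))).data, [4.0, 1.0])
    np.testing.assert_allclose(update_node(h, Tensor(np.zeros(2))).data, h.data)
    with pytest.raises(ValueError):
        update_node(h, Tensor(np.zeros(3)))


def test_update_edge_relu_of_difference():
    eye = np.eye(2)
    out = update_edge(Tensor(np.array([1.0, -2.0])), Tensor(np.zeros(2)),
                      Tensor(np.zeros(2)), Tensor(eye))
    np.testing.assert_allclose(out.data, [1.0, 0.0])
    # equal source and reverse features: result is ReLU of the initial edge state
    h0 = np.array([0.5, -0.5])
    same = update_edge(Tensor(np.ones(2)), Tensor(np.ones(2)), Tensor(h0), Tensor(eye))
    np.testing.assert_allclose(same.data, np.maximum(h0, 0.0))


# ---------------------------------------------------------------------------
# oracle equivalence


def test_encoder_matches_loop_oracle_on_random_graphs(rng):
    encoder = CMPNNEncoder(hidden_dim=4, depth=3, readout="mean",
                           rng=np.random.default_rng(7))
    for _ in range(50):
        graph = random_molgraph(rng, max_atoms=6)
        batch = GraphBatch.from_graphs([graph])
        atoms, mols = encoder.forward(batch)
        expected = loop_oracle_atom_embeddings(encoder, graph)
        np.testing.assert_allclose(atoms.data, expected, atol=1e-6)
        np.testing.assert_allclose(mols.data[0], expected.mean(axis=0), atol=1e-6)


def test_batched_and_single_molecule_agree(rng):
    encoder = CMPNNEncoder(hidden_dim=8, depth=3, rng=np.random.default_rng(3))
    graphs = [smiles_to_graph(s) for s in ("CCO", "c1ccccc1", "CC(C)(C)C")]
    atoms, mols = encoder.forward(GraphBatch.from_graphs(graphs))
    offset = 0
    for i, g in enumerate(graphs):
        single = encoder.encode(g)
        np.testing.assert_allclose(single.atom_embeddings,
                                   atoms.data[offset:offset + g.n_atoms], atol=1e-9)
        np.testing.assert_allclose(single.molecule_embedding, mols.data[i], atol=1e-9)
        offset += g.n_atoms


def test_zero_depth_uses_projected_inputs_only(rng):
    encoder = CMPNNEncoder(hidden_dim=4, depth=0, readout="mean",
                           rng=np.random.default_rng(5))
    graph = random_molgraph(rng, max_atoms=4)
    atoms, _ = encoder.forward(GraphBatch.from_graphs([graph]))
    expected = loop_oracle_atom_embeddings(encoder, graph)
    np.testing.assert_allclose(atoms.data, expected, atol=1e-9)


def test_single_atom_molecule_encodes():
    encoder = CMPNNEncoder(hidden_dim=8, depth=3, rng=np.random.default_rng(0))
    out = encoder.encode(smiles_to_graph("C"))
    assert out.atom_embeddings.shape == (1, 8)
    assert np.all(np.isfinite(out.molecule_embedding))


def test_empty_batch_and_empty_graph_raise():
    with pytest.raises(ValueError):
        GraphBatch.from_graphs([])


def test_outputs_finite_on_random_molecules(rng):
    encoder = CMPNNEncoder(hidden_dim=16, depth=3, rng=np.random.default_rng(11))
    graphs = [random_molgraph(rng) for _ in range(10)]
    atoms, mols = encoder.forward(GraphBatch.from_graphs(graphs))
    assert np.all(np.isfinite(atoms.data)) and np.all(np.isfinite(mols.data))


def test_k_layer_state_depends_only_on_k_hop_neighbourhood():
    # octane path: perturbing an atom farther than K bonds away leaves a
    # node's pre-readout embedding untouched; a 1-hop perturbation changes it
    k = 2
    encoder = CMPNNEncoder(hidden_dim=6, depth=k, readout="mean",
                           rng=np.random.default_rng(21))
    base = smiles_to_graph("CCCCCCCC")

    def perturbed(atom_idx):
        g = smiles_to_graph("CCCCCCCC")
        g.atom_features = g.atom_features.copy()
        g.atom_features[atom_idx, -1] += 0.5
        # bond inputs embed source atom features; rebuild them
        return GraphBatch.from_graphs([g])

    ref = encoder.forward(GraphBatch.from_graphs([base]))[0].data
    far = encoder.forward(perturbed(6))[0].data        # 6 hops from atom 0
    near = encoder.forward(perturbed(1))[0].data       # 1 hop from atom 0
    np.testing.assert_allclose(far[0], ref[0], atol=1e-12)
    assert not np.allclose(near[0], ref[0])


def test_same_molecule_different_spellings_same_embedding():
    encoder = CMPNNEncoder(hidden_dim=8, depth=3, rng=np.random.default_rng(2))
    a = encoder.encode(smiles_to_graph("OCC"))
    b = encoder.encode(smiles_to_graph("CCO"))
    np.testing.assert_allclose(a.molecule_embedding, b.molecule_embedding, atol=1e-12)


# ---------------------------------------------------------------------------
# padding


def test_pad_batch_appends_zero_rows(rng):
    x1, x2 = rng.normal(size=(3, 2)), rng.normal(size=(5, 2))
    padded = pad_batch([x1, x2])
    assert padded.features.shape == (2, 5, 2)
    np.testing.assert_array_equal(padded.features[0, 3:], 0.0)
    np.testing.assert_allclose(padded.features[0, :3], x1)
    np.testing.assert_allclose(padded.features[1], x2)
    assert list(padded.atom_counts) == [3, 5]


def test_pad_batch_single_molecule_is_identity(rng):
    x = rng.normal(size=(4, 3))
    padded = pad_batch([x])
    np.testing.assert_array_equal(padded.features[0], x)


def test_pad_batch_rejects_mixed_widths(rng):
    with pytest.raises(ValueError):
        pad_batch([rng.normal(size=(3, 2)), rng.normal(size=(3, 4))])
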