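"""Motif fragmentation, vocabulary, and the A/D/F matrices.

The decomposition oracle here is an independent re-statement of the two
cleavage rules built on networkx: ring systems from RDKit bond rings,
broken bonds marked explicitly, fragments as connected components.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from dfusmol.chem_graph import smiles_to_graph
from dfusmol.motif_graph import (
    MotifFragment,
    MotifVocabulary,
    build_motif_graph,
    build_vocabulary,
    decompose,
    shortest_path_matrix,
)

from conftest import CASE_STUDY_SMILES


# ---------------------------------------------------------------------------
# independent oracle: broken-bond marking + connected components (networkx)


def oracle_partition(smiles: str) -> set[frozenset[int]]:
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.MolFromSmiles(smiles)))
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    # ring systems: union of bond rings, merged when they share atoms
    ring_atoms: list[set[int]] = []
    for bond_ring in mol.GetRingInfo().BondRings():
        atoms = set()
        for bi in bond_ring:
            b = mol.GetBondWithIdx(bi)
            atoms |= {b.GetBeginAtomIdx(), b.GetEndAtomIdx()}
        ring_atoms.append(atoms)
    merged = True
    while merged:
        merged = False
        for i in range(len(ring_atoms)):
            for j in range(i + 1, len(ring_atoms)):
                if ring_atoms[i] & ring_atoms[j]:
                    ring_atoms[i] |= ring_atoms.pop(j)
                    merged = True
                    break
            if merged:
                break
    in_system = set().union(*ring_atoms) if ring_atoms else set()
    broken = set()
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if b.IsInRing():
            continue
        if (u in in_system) != (v in in_system):
            broken.add((u, v))
        if (u not in in_system and mol.GetAtomWithIdx(u).GetDegree() >= 3) or \
           (v not in in_system and mol.GetAtomWithIdx(v).GetDegree() >= 3):
            broken.add((u, v))
    g.remove_edges_from(broken)
    return {frozenset(c) for c in nx.connected_components(g)}


def partition_of(smiles: str) -> set[frozenset[int]]:
    return {frozenset(f.atom_indices) for f in decompose(smiles_to_graph(smiles))}


# ---------------------------------------------------------------------------
# decomposition


def test_cyclopropane_is_one_fragment():
    frags = decompose(smiles_to_graph("C1CC1"))
    assert len(frags) == 1
    assert frags[0].atom_indices == frozenset({0, 1, 2})


def test_toluene_splits_into_ring_and_methyl():
    parts = partition_of("Cc1ccccc1")
    assert len(parts) == 2
    assert {len(p) for p in parts} == {1, 6}


def test_neopentane_splits_into_five_singletons():
    parts = partition_of("CC(C)(C)C")
    assert len(parts) == 5
    assert all(len(p) == 1 for p in parts)


def test_case_study_molecule_keeps_ring_systems_intact():
    graph = smiles_to_graph(CASE_STUDY_SMILES)
    frags = decompose(graph)
    assert partition_of(CASE_STUDY_SMILES) == oracle_partition(CASE_STUDY_SMILES)
    mol = graph.mol
    ring_info = mol.GetRingInfo()
    # every ring stays inside a single fragment
    for ring in ring_info.AtomRings():
        owners = {next(i for i, f in enumerate(frags) if a in f.atom_indices) for a in ring}
        assert len(owners) == 1


def test_decompose_matches_oracle_on_curated_suite(curated_suite):
    for smiles in curated_suite:
        assert partition_of(smiles) == oracle_partition(smiles), smiles


def test_fragments_partition_atoms(curated_suite):
    for smiles in curated_suite:
        g = smiles_to_graph(smiles)
        frags = decompose(g)
        counts = sum(len(f.atom_indices) for f in frags)
        assert counts == g.n_atoms
        assert frozenset().union(*[f.atom_indices for f in frags]) == frozenset(range(g.n_atoms))


def test_motif_keys_invariant_to_atom_order(curated_suite, rng):
    for smiles in curated_suite:
        mol = Chem.MolFromSmiles(smiles)
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        scrambled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        keys_a = sorted(f.motif_key for f in decompose(smiles_to_graph(smiles)))
        keys_b = sorted(f.motif_key for f in decompose(smiles_to_graph(scrambled)))
        assert keys_a == keys_b, smiles


# ---------------------------------------------------------------------------
# vocabulary


def test_vocabulary_from_toluene_has_two_keys_plus_unk():
    vocab = build_vocabulary(["Cc1ccccc1"])
    assert set(vocab.key_to_index) == {"C", "c1ccccc1"}
    assert vocab.size == 3
    assert vocab.unk_index == 2
    assert vocab.index_of("c1ccncc1") == vocab.unk_index


def test_vocabulary_ignores_duplicates_and_sorts_keys():
    v1 = build_vocabulary(["Cc1ccccc1", "Cc1ccccc1", "CCO"])
    v2 = build_vocabulary(["CCO", "Cc1ccccc1"])
    assert v1 == v2
    indices = [v1.key_to_index[k] for k in sorted(v1.key_to_index)]
    assert indices == sorted(indices)


def test_vocabulary_empty_corpus_raises():
    with pytest.raises(ValueError):
        build_vocabulary([])


def test_vocabulary_skips_unparseable_entries():
    vocab = build_vocabulary(["Cc1ccccc1", "C("])
    assert set(vocab.key_to_index) == {"C", "c1ccccc1"}
    with pytest.raises(ValueError):
        build_vocabulary(["C(", "not-a-smiles"])


def test_vocabulary_roundtrips_through_file(tmp_path):
    vocab = build_vocabulary(["Cc1ccccc1", "CCO", "c1ccncc1"])
    path = tmp_path / "vocab.tsv"
    vocab.save(path)
    assert MotifVocabulary.load(path) == vocab


# ---------------------------------------------------------------------------
# motif graph matrices


def test_toluene_motif_graph_matrices():
    g = smiles_to_graph("Cc1ccccc1")
    vocab = build_vocabulary(["Cc1ccccc1"])
    mg = build_motif_graph(g, decompose(g), vocab)
    assert mg.adjacency.shape == (3, 3)
    assert mg.association.shape == (2, 7)
    np.testing.assert_array_equal(mg.adjacency, mg.adjacency.T)
    assert np.all(np.diag(mg.adjacency) == 0)
    assert mg.adjacency[0, 1] == 1  # ring and methyl joined by the broken bond
    np.testing.assert_array_equal(mg.association.sum(axis=0), np.ones(7))
    assert sorted(mg.association.sum(axis=1).tolist()) == [1, 6]
    np.testing.assert_array_equal(mg.onehots.sum(axis=1), np.ones(2))


def test_motif_graph_json_export_roundtrips():
    import json

    g = smiles_to_graph("Cc1ccccc1")
    vocab = build_vocabulary(["Cc1ccccc1"])
    mg = build_motif_graph(g, decompose(g), vocab)
    payload = json.loads(json.dumps(mg.as_dict()))
    np.testing.assert_array_equal(np.array(payload["adjacency"]), mg.adjacency)
    np.testing.assert_array_equal(np.array(payload["association"]), mg.association)
    assert payload["global_index"] == mg.global_index


def test_unknown_motif_gets_unk_bit():
    vocab = build_vocabulary(["CCO"])  # no rings in vocabulary
    g = smiles_to_graph("c1ccccc1")
    mg = build_motif_graph(g, decompose(g), vocab)
    assert mg.onehots[0, vocab.unk_index] == 1


def test_single_fragment_molecule_graph():
    g = smiles_to_graph("C1CC1")
    vocab = build_vocabulary(["C1CC1"])
    mg = build_motif_graph(g, decompose(g), vocab)
    assert mg.adjacency.shape == (2, 2)
    off_diag = mg.distance[~np.eye(2, dtype=bool)]
    np.testing.assert_array_equal(off_diag, 1)


def test_global_node_distance_and_adjacency(curated_suite):
    vocab = build_vocabulary(curated_suite)
    for smiles in curated_suite:
        g = smiles_to_graph(smiles)
        mg = build_motif_graph(g, decompose(g), vocab)
        gi = mg.global_index
        assert gi == mg.n_motifs
        np.testing.assert_array_equal(np.delete(mg.distance[gi], gi), 1)
        np.testing.assert_array_equal(np.delete(mg.distance[:, gi], gi), 1)
        np.testing.assert_array_equal(np.delete(mg.adjacency[gi], gi), 1)
        assert mg.distance[gi, gi] == 0


def test_inconsistent_fragment_raises():
    g = smiles_to_graph("CC")
    vocab = build_vocabulary(["CC"])
    bad = [MotifFragment(frozenset({0, 5}), "CC")]
    with pytest.raises(ValueError):
        build_motif_graph(g, bad, vocab)
    with pytest.raises(ValueError):  # does not cover atom 1
        build_motif_graph(g, [MotifFragment(frozenset({0}), "C")], vocab)


# ---------------------------------------------------------------------------
# shortest paths


def test_path_graph_distance():
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    d = shortest_path_matrix(a)
    assert d[0, 2] == 2 and d[0, 1] == 1
    assert np.all(np.diag(d) == 0)


def test_disconnected_pair_gets_sentinel():
    a = np.zeros((2, 2), dtype=int)
    d = shortest_path_matrix(a)
    assert d[0, 1] == d[1, 0] == 3  # sentinel n + 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=10**9))
def test_bfs_matches_floyd_warshall(n, seed):
    rng = np.random.default_rng(seed)
    a = np.triu((rng.random((n, n)) < 0.35).astype(int), k=1)
    a = a + a.T
    d = shortest_path_matrix(a)
    g = nx.from_numpy_array(a)
    oracle = dict(nx.floyd_warshall(g))
    sentinel = n + 1
    for i in range(n):
        for j in range(n):
            expected = oracle[i][j]
            assert d[i, j] == (sentinel if np.isinf(expected) else int(expected))
    # adjacency <=> unit distance
    np.testing.assert_array_equal((d == 1).astype(int), a)
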