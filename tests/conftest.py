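"""Shared fixtures: small molecule suites and random-graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from dfusmol.chem_graph import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph

# the molecule shown in the attention case study, under both readings of its
# ambiguous trailing "(C)" (panel label vs. methyl)
CASE_STUDY_SMILES = "O=C(NCc1cccnc1)C(Cc1cc2cc(ccc2nc1N)-c1ccccc1C)C"
CASE_STUDY_SMILES_NO_TAIL = "O=C(NCc1cccnc1)C(Cc1cc2cc(ccc2nc1N)-c1ccccc1C)"

CURATED_SUITE = [
    "C",                      # single atom
    "CC",                     # one bond
    "CCO",                    # chain
    "C1CC1",                  # cyclopropane: one intact ring
    "c1ccccc1",               # benzene
    "Cc1ccccc1",              # toluene: ring/substituent cleavage
    "CC(C)(C)C",              # neopentane: high-degree acyclic atom
    "CC(C)C",                 # isobutane: degree-3 acyclic atom
    "c1ccc2ccccc2c1",         # naphthalene: fused bicyclic stays whole
    "C1CCC2CCCCC2C1",         # decalin: fused saturated bicyclic
    "c1ccc(-c2ccccc2)cc1",    # biphenyl: two ring systems, direct bond
    "Cc1ccccc1C",             # xylene
    "Nc1ccccc1",              # aniline
    "OC(=O)c1ccccc1",         # benzoic acid
    "Clc1ccccc1Br",           # halogenated ring
    "CCN(CC)CC",              # triethylamine: rule-2 nitrogen
    "CC(N)C(=O)O",            # alanine-like
    "C1CCCCC1CC1CCCCC1",      # two rings with a linker
    "c1ccncc1",               # pyridine
    "CC(C)(C)c1ccccc1",       # tert-butylbenzene: both rules at once
    "O=C(O)CC(Cl)c1ccncc1",   # mixed functionality
    "C1CC2(CC1)CCCC2",        # spiro system: shares one atom
    "CCCCCCCC",               # octane
    "NC(=O)c1ccc(F)cc1",      # amide + fluorine
    "CN(C)c1ccccc1",          # dimethylaniline
    "OCC1CCCCC1O",            # diol on a ring
    "c1cnc2[nH]ccc2c1",       # fused heteroaromatic
    "CC(=O)OC1CCCC1",         # ester linkage to ring
    CASE_STUDY_SMILES,
    CASE_STUDY_SMILES_NO_TAIL,
]


@pytest.fixture(scope="session")
def curated_suite() -> list[str]:
    return list(CURATED_SUITE)


def random_molgraph(rng: np.random.Generator, max_atoms: int = 6) -> MolecularGraph:
    """Synthetic connected graph with random features (not a real molecule).

    Used to probe the message-passing algebra on arbitrary topologies; a
    random spanning tree plus a few extra edges, with both directions of
    every edge carrying identical bond features.
    """
    n = int(rng.integers(1, max_atoms + 1))
    atom_features = rng.normal(size=(n, ATOM_FEATURE_DIM))
    bonds: set[tuple[int, int]] = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        bonds.add((u, v))
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            bonds.add((min(u, v), max(u, v)))
    edges, bond_rows, reverse = [], [], []
    for u, v in sorted(bonds):
        f = rng.normal(size=BOND_FEATURE_DIM)
        base = len(edges)
        edges.append((u, v))
        edges.append((v, u))
        bond_rows.extend([f, f.copy()])
        reverse.extend([base + 1, base])
    return MolecularGraph(
        smiles=f"random-{n}",
        atom_features=atom_features,
        edges=edges,
        bond_features=np.array(bond_rows) if bond_rows else np.zeros((0, BOND_FEATURE_DIM)),
        reverse_index=np.array(reverse, dtype=np.intp),
        mol=None,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
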