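"""SMILES parsing into directed molecular graphs with fixed-width features.

A molecule is a directed graph: every chemical bond contributes two directed
edges (u->v and v->u), which lets the message-passing encoder treat the two
directions of a bond as distinct information channels.  Atom ordering follows
RDKit's canonical order — two SMILES spellings of the same molecule produce
identical graphs.

Feature layout (all one-hot blocks, chemprop-style):

===================  =====  =========================================
block                width  encoding
===================  =====  =========================================
element              101    atomic number 1..100, plus "other"
degree               6      heavy-atom degree 0..5 (out of range -> all zero)
formal charge        6      -2..+2, plus "other"
hybridization        6      SP, SP2, SP3, SP3D, SP3D2, plus "other"
aromaticity          1      0/1 flag
total H count        5      0..4 (clamped)
atomic mass          1      mass / 100 (dimensionless)
===================  =====  =========================================

Bond features: bond-type one-hot (single/double/triple/aromatic), a
conjugation flag and an in-ring flag — 6 entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_ELEMENT_RANGE = 100  # atomic numbers 1..100, then "other"
_DEGREES = list(range(6))
_CHARGES = [-2, -1, 0, 1, 2]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_NUM_H = list(range(5))
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FEATURE_DIM = (_ELEMENT_RANGE + 1) + len(_DEGREES) + (len(_CHARGES) + 1) \
    + (len(_HYBRIDIZATIONS) + 1) + 1 + len(_NUM_H) + 1
BOND_FEATURE_DIM = len(_BOND_TYPES) + 2


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass
class MolecularGraph:
    """Directed molecular graph over heavy atoms.

    ``edges[2*b]`` and ``edges[2*b + 1]`` are the two directions of bond
    ``b``; ``reverse_index`` maps each directed edge to its partner and is an
    involution with no fixed points.
    """

    smiles: str
    atom_features: np.ndarray            # (m, ATOM_FEATURE_DIM)
    edges: list[tuple[int, int]]         # directed (source, target)
    bond_features: np.ndarray            # (2*bonds, BOND_FEATURE_DIM)
    reverse_index: np.ndarray            # (2*bonds,) int
    mol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_sources(self) -> np.ndarray:
        return np.array([u for u, _ in self.edges], dtype=np.intp).reshape(-1)

    @property
    def edge_targets(self) -> np.ndarray:
        return np.array([v for _, v in self.edges], dtype=np.intp).reshape(-1)


def _one_hot(value, choices, with_other: bool = True) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if with_other else 0))
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif with_other:
        vec[-1] = 1.0
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Fixed-width feature vector for one atom; unknown elements land in the
    "other" bucket rather than raising."""
    z = atom.GetAtomicNum()
    element = [0.0] * (_ELEMENT_RANGE + 1)
    if 1 <= z <= _ELEMENT_RANGE:
        element[z - 1] = 1.0
    else:
        element[-1] = 1.0
    degree = _one_hot(atom.GetDegree(), _DEGREES, with_other=False)
    charge = _one_hot(atom.GetFormalCharge(), _CHARGES)
    hybrid = _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
    aromatic = [1.0 if atom.GetIsAromatic() else 0.0]
    num_h = _one_hot(min(atom.GetTotalNumHs(), _NUM_H[-1]), _NUM_H, with_other=False)
    mass = [atom.GetMass() / 100.0]
    return np.array(element + degree + charge + hybrid + aromatic + num_h + mass)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    btype = _one_hot(bond.GetBondType(), _BOND_TYPES, with_other=False)
    if not any(btype):
        # unusual bond orders (dative etc.) bucketed as single
        btype[0] = 1.0
    conj = [1.0 if bond.GetIsConjugated() else 0.0]
    ring = [1.0 if bond.IsInRing() else 0.0]
    return np.array(btype + conj + ring)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    The molecule is canonicalized first so that atom order — and therefore
    every downstream matrix — is independent of how the input SMILES was
    written.  Hydrogens stay implicit.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"empty or non-string SMILES input: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise SmilesParseError(f"canonicalization failed for SMILES: {smiles!r}")

    atom_features = np.array([featurize_atom(a) for a in mol.GetAtoms()]).reshape(
        mol.GetNumAtoms(), ATOM_FEATURE_DIM)
    edges: list[tuple[int, int]] = []
    bond_rows: list[np.ndarray] = []
    reverse: list[int] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        base = len(edges)
        edges.append((u, v))
        edges.append((v, u))
        bond_rows.extend([f, f.copy()])
        reverse.extend([base + 1, base])
    bond_features = (np.array(bond_rows) if bond_rows
                     else np.zeros((0, BOND_FEATURE_DIM)))
    return MolecularGraph(
        smiles=canonical,
        atom_features=atom_features,
        edges=edges,
        bond_features=bond_features,
        reverse_index=np.array(reverse, dtype=np.intp),
        mol=mol,
    )
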