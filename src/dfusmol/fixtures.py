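"""Deterministic synthetic molecules and labels for download-free testing.

Molecules are assembled from a small template grammar rather than random
graphs, so every SMILES is chemically valid without a valence-repair pass
and the two fragmentation rules are exercised by construction:

* *single-core*: one ring core (benzene, pyridine or cyclohexane) carrying
  0-3 substituents — ring/substituent cleavage (rule 1);
* *linked*: two cores joined through a central sp3 carbon that also carries
  a methyl group — an acyclic atom with three heavy neighbours (rule 2);
* *acyclic*: a central carbon with 2-4 substituents — rule 2 plus acyclic
  scaffolds for the scaffold-split machinery.

The first three molecules of every generated set are drawn one from each
kind, so even tiny fixture sets cover both rules.  Regeneration with the
same ``(n, seed)`` is bit-identical.

Label recipes:

``ring_count``
    number of rings (regression; exact from structure);
``has_nitrogen``
    1 if the molecule contains nitrogen (binary classification);
``motif_weighted``
    (# non-ring nitrogens) - (# halogens) + Gaussian noise (sigma = 0.1 by
    default) — a motif-additive property whose signal lives on functional
    groups rather than single atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .pipeline import MoleculeDataset

CORES = ["c1ccccc1", "c1ccncc1", "C1CCCCC1"]
SUBSTITUENTS = ["C", "N", "C(=O)O", "F", "Cl", "Br"]
RECIPES = ("ring_count", "has_nitrogen", "motif_weighted")
_KINDS = ("single_core", "linked", "acyclic")


@dataclass
class SyntheticDataset:
    """Generated SMILES with labels and the parameters that produced them."""

    smiles: list[str]
    labels: np.ndarray
    n: int
    seed: int
    recipe: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"smiles": self.smiles, self.recipe: self.labels})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dataset(self) -> MoleculeDataset:
        return MoleculeDataset(smiles=list(self.smiles), targets=self.labels[:, None],
                               target_names=[self.recipe])


# ---------------------------------------------------------------------------
# molecule assembly


def _attachable_positions(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _attach(mol: Chem.Mol, position: int, substituent: str) -> Chem.Mol:
    sub = Chem.MolFromSmiles(substituent)
    offset = mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(mol, sub))
    combined.AddBond(position, offset, Chem.BondType.SINGLE)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


def _sample_single_core(rng: np.random.Generator) -> Chem.Mol:
    mol = Chem.MolFromSmiles(CORES[rng.integers(len(CORES))])
    n_subs = int(rng.integers(0, 4))
    for _ in range(n_subs):
        positions = _attachable_positions(mol)
        if not positions:
            break
        pos = int(positions[rng.integers(len(positions))])
        mol = _attach(mol, pos, SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))])
    return mol


def _sample_linked(rng: np.random.Generator) -> Chem.Mol:
    """Two cores bridged by a methyl-bearing carbon (acyclic, degree 3)."""
    a = Chem.MolFromSmiles(CORES[rng.integers(len(CORES))])
    b = Chem.MolFromSmiles(CORES[rng.integers(len(CORES))])
    linker = Chem.MolFromSmiles("CC")  # atom 0 = bridge, atom 1 = its methyl
    mol = Chem.CombineMols(Chem.CombineMols(a, b), linker)
    bridge = a.GetNumAtoms() + b.GetNumAtoms()
    pos_a = int(rng.choice(_attachable_positions(a)))
    pos_b = a.GetNumAtoms() + int(rng.choice(_attachable_positions(b)))
    rw = Chem.RWMol(mol)
    rw.AddBond(pos_a, bridge, Chem.BondType.SINGLE)
    rw.AddBond(pos_b, bridge, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _sample_acyclic(rng: np.random.Generator) -> Chem.Mol:
    mol = Chem.MolFromSmiles("C")
    for _ in range(int(rng.integers(2, 5))):
        mol = _attach(mol, 0, SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))])
    return mol


_SAMPLERS = {"single_core": _sample_single_core, "linked": _sample_linked,
             "acyclic": _sample_acyclic}


def generate_molecules(n: int, seed: int = 0, max_attempts: int | None = None) -> list[str]:
    """Deterministic list of ``n`` unique canonical SMILES.

    The first three molecules cover the three template kinds; the rest are
    sampled with weights favouring substituted single cores.  Raises if the
    grammar cannot supply ``n`` unique molecules within the draw budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    if max_attempts is None:
        max_attempts = 300 * n + 1000
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        kind = _KINDS[len(out)] if len(out) < 3 else rng.choice(
            _KINDS, p=[0.45, 0.25, 0.30])
        try:
            mol = _SAMPLERS[kind](rng)
        except Chem.rdchem.MolSanitizeException:  # pragma: no cover - grammar is valence-safe
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles not in seen:
            seen.add(smiles)
            out.append(smiles)
    if len(out) < n:
        raise ValueError(
            f"template grammar exhausted: produced {len(out)} unique molecules "
            f"of the requested {n} after {attempts} draws")
    return out


# ---------------------------------------------------------------------------
# labels


def label_molecules(smiles: Sequence[str], recipe: str, seed: int = 0,
                    sigma: float = 0.1) -> np.ndarray:
    """Structure-derived labels; noise (motif_weighted only) is seeded."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    rng = np.random.default_rng(seed)
    labels = np.zeros(len(smiles))
    for i, s in enumerate(smiles):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES in fixture labelling: {s!r}")
        if recipe == "ring_count":
            labels[i] = float(mol.GetRingInfo().NumRings())
        elif recipe == "has_nitrogen":
            labels[i] = float(any(a.GetAtomicNum() == 7 for a in mol.GetAtoms()))
        else:
            n_amino = sum(1 for a in mol.GetAtoms()
                          if a.GetAtomicNum() == 7 and not a.IsInRing())
            n_halogen = sum(1 for a in mol.GetAtoms()
                            if a.GetAtomicNum() in (9, 17, 35, 53))
            labels[i] = float(n_amino - n_halogen)
    if recipe == "motif_weighted" and sigma > 0:
        labels = labels + rng.normal(0.0, sigma, size=len(smiles))
    return labels


def make_fixture_dataset(n: int, seed: int = 0, recipe: str = "ring_count",
                         sigma: float = 0.1) -> SyntheticDataset:
    smiles = generate_molecules(n, seed=seed)
    labels = label_molecules(smiles, recipe, seed=seed, sigma=sigma)
    return SyntheticDataset(smiles=smiles, labels=labels, n=n, seed=seed, recipe=recipe)
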