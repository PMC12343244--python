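"""Chemistry-rule motif fragmentation and the motif-level graph.

Molecules are partitioned into motifs by two rules:

1. every acyclic bond joining a ring system to a substituent is cleaved
   (a ring system is a maximal set of rings fused by a shared atom or bond);
2. every non-ring atom with three or more heavy-atom neighbours becomes a
   singleton motif — all of its bonds are cleaved.

The broken-bond set is computed first and connected components are taken
afterwards, so the result is order-independent and the fragments partition
the atom set.  Ring systems always stay intact inside one fragment.

The motif graph adds a [GLOBAL] node adjacent to (and at hop distance 1
from) every motif; it aggregates graph-level information in the attention
stack.  Three matrices describe the graph:

* ``A`` — (n+1)x(n+1) binary motif adjacency (two motifs are adjacent iff an
  original bond crosses between them);
* ``D`` — (n+1)x(n+1) shortest-path hop counts, with the [GLOBAL] row/column
  fixed to 1 and disconnected pairs set to the sentinel ``n + 1``;
* ``F`` — n x m binary motif-atom membership (columns sum to one).

Motifs are keyed by the canonical SMILES of the induced fragment, with
broken-bond attachment points left as plain open valences (no dummy atoms).
Unknown keys map to the reserved [UNK] vocabulary index.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem_graph import MolecularGraph, SmilesParseError, smiles_to_graph

logger = logging.getLogger(__name__)

UNK_TOKEN = "[UNK]"


@dataclass(frozen=True)
class MotifFragment:
    """One motif: the atom indices it occupies in the parent molecule and its
    canonical-SMILES key."""

    atom_indices: frozenset[int]
    motif_key: str


class MotifVocabulary:
    """Bijective motif-key index with a reserved trailing [UNK] slot.

    Keys are sorted lexicographically at build time so indices are
    reproducible regardless of corpus order.
    """

    def __init__(self, keys: Sequence[str]):
        unique = sorted(set(keys))
        if not unique:
            raise ValueError("motif vocabulary requires at least one observed motif key")
        self.key_to_index: dict[str, int] = {k: i for i, k in enumerate(unique)}
        self.unk_index: int = len(unique)

    @property
    def size(self) -> int:
        """Total number of indices, including [UNK]."""
        return self.unk_index + 1

    def index_of(self, key: str) -> int:
        return self.key_to_index.get(key, self.unk_index)

    def save(self, path: str | Path) -> None:
        lines = [f"{k}\t{i}" for k, i in sorted(self.key_to_index.items(), key=lambda kv: kv[1])]
        lines.append(f"{UNK_TOKEN}\t{self.unk_index}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MotifVocabulary":
        keys = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, idx = line.rsplit("\t", 1)
            if key == UNK_TOKEN:
                continue
            keys.append((int(idx), key))
        vocab = cls([k for _, k in sorted(keys)])
        return vocab

    def __eq__(self, other) -> bool:
        return isinstance(other, MotifVocabulary) and self.key_to_index == other.key_to_index


@dataclass
class MotifGraph:
    """Motif-level view of one molecule (special [GLOBAL] node included in
    ``adjacency``/``distance`` but not in ``onehots``/``association``)."""

    n_motifs: int
    motif_indices: np.ndarray      # (n,) vocabulary indices (may be UNK)
    onehots: np.ndarray            # (n, L) binary
    adjacency: np.ndarray          # (n+1, n+1) binary, zero diagonal
    distance: np.ndarray           # (n+1, n+1) nonnegative int
    association: np.ndarray        # (n, m) binary
    global_index: int              # row/col of the [GLOBAL] node (== n)

    def as_dict(self) -> dict:
        """JSON-friendly view (nested lists) for debugging and export."""
        return {
            "n_motifs": self.n_motifs,
            "motif_indices": self.motif_indices.tolist(),
            "adjacency": self.adjacency.tolist(),
            "distance": self.distance.tolist(),
            "association": self.association.tolist(),
            "global_index": self.global_index,
        }


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Maximal fused-ring components: rings sharing an atom are merged."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            ring |= s
            systems.remove(s)
        systems.append(ring)
    return systems


def fragment_key(mol: Chem.Mol, atom_indices: Iterable[int]) -> str:
    """Canonical SMILES of the induced fragment (attachment points reduced to
    plain valence)."""
    return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atom_indices), canonical=True)


def decompose(graph: MolecularGraph) -> list[MotifFragment]:
    """Partition a molecule into motif fragments by the two cleavage rules.

    Returns fragments ordered by their smallest atom index.
    """
    mol = graph.mol if graph.mol is not None else Chem.MolFromSmiles(graph.smiles)
    n = mol.GetNumAtoms()
    systems = _ring_systems(mol)
    in_ring_system = [False] * n
    for s in systems:
        for a in s:
            in_ring_system[a] = True

    broken: set[tuple[int, int]] = set()
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bond.IsInRing():
            continue
        # rule 1: acyclic bond with exactly one endpoint inside a ring system
        if in_ring_system[u] != in_ring_system[v]:
            broken.add((min(u, v), max(u, v)))
        # rule 2: bonds incident to a high-degree acyclic atom
        for a in (u, v):
            if not in_ring_system[a] and mol.GetAtomWithIdx(a).GetDegree() >= 3:
                broken.add((min(u, v), max(u, v)))

    # connected components of the molecule minus the broken bonds
    adj: list[list[int]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (min(u, v), max(u, v)) in broken:
            continue
        adj[u].append(v)
        adj[v].append(u)
    seen = [False] * n
    fragments: list[MotifFragment] = []
    for start in range(n):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            a = queue.popleft()
            comp.append(a)
            for b in adj[a]:
                if not seen[b]:
                    seen[b] = True
                    queue.append(b)
        fragments.append(MotifFragment(frozenset(comp), fragment_key(mol, comp)))
    return fragments


def build_vocabulary(corpus: Iterable[str]) -> MotifVocabulary:
    """Collect every unique motif key over a SMILES corpus.

    Unparseable entries are skipped with a warning; an empty (or fully
    unparseable) corpus raises.
    """
    keys: set[str] = set()
    n_seen = 0
    for smiles in corpus:
        n_seen += 1
        try:
            graph = smiles_to_graph(smiles)
        except SmilesParseError:
            logger.warning("skipping unparseable SMILES in vocabulary corpus: %r", smiles)
            continue
        keys.update(f.motif_key for f in decompose(graph))
    if n_seen == 0:
        raise ValueError("vocabulary corpus is empty")
    if not keys:
        raise ValueError("no parseable molecules in vocabulary corpus")
    return MotifVocabulary(sorted(keys))


def shortest_path_matrix(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path hops via BFS from each node.

    ``adjacency`` is the symmetric binary n x n motif adjacency *without* the
    [GLOBAL] node.  Disconnected pairs get the sentinel ``n + 1``, one more
    than any realizable path length.
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("adjacency must be square")
    sentinel = n + 1
    dist = np.full((n, n), sentinel, dtype=np.int64)
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    for src in range(n):
        dist[src, src] = 0
        queue = deque([src])
        while queue:
            cur = queue.popleft()
            for nxt in neighbors[cur]:
                if dist[src, nxt] == sentinel:
                    dist[src, nxt] = dist[src, cur] + 1
                    queue.append(nxt)
    return dist


def build_motif_graph(graph: MolecularGraph, fragments: Sequence[MotifFragment],
                      vocab: MotifVocabulary) -> MotifGraph:
    """Assemble the motif graph (A, D, F, one-hots) for one molecule.

    The [GLOBAL] node occupies the last row/column of ``A`` and ``D``; it is
    adjacent to every motif and at hop distance 1 from each, matching its
    role as a graph-level aggregator.
    """
    m = graph.n_atoms
    n = len(fragments)
    atom_to_motif = np.full(m, -1, dtype=np.int64)
    for i, frag in enumerate(fragments):
        for a in frag.atom_indices:
            if not (0 <= a < m):
                raise ValueError(f"fragment atom index {a} outside molecule of {m} atoms")
            if atom_to_motif[a] != -1:
                raise ValueError(f"atom {a} assigned to two fragments")
            atom_to_motif[a] = i
    if (atom_to_motif == -1).any():
        raise ValueError("fragments do not cover every atom of the molecule")

    core = np.zeros((n, n), dtype=np.int64)
    for u, v in graph.edges:
        mu, mv = atom_to_motif[u], atom_to_motif[v]
        if mu != mv:
            core[mu, mv] = 1
            core[mv, mu] = 1

    adjacency = np.zeros((n + 1, n + 1), dtype=np.int64)
    adjacency[:n, :n] = core
    adjacency[n, :n] = 1
    adjacency[:n, n] = 1

    distance = np.zeros((n + 1, n + 1), dtype=np.int64)
    distance[:n, :n] = shortest_path_matrix(core)
    distance[n, :n] = 1
    distance[:n, n] = 1

    onehots = np.zeros((n, vocab.size), dtype=np.int64)
    indices = np.array([vocab.index_of(f.motif_key) for f in fragments], dtype=np.int64)
    onehots[np.arange(n), indices] = 1

    association = np.zeros((n, m), dtype=np.int64)
    for i, frag in enumerate(fragments):
        association[i, sorted(frag.atom_indices)] = 1

    return MotifGraph(
        n_motifs=n,
        motif_indices=indices,
        onehots=onehots,
        adjacency=adjacency,
        distance=distance,
        association=association,
        global_index=n,
    )


def motif_graph_from_smiles(smiles: str, vocab: MotifVocabulary) -> MotifGraph:
    """Convenience: parse, decompose and assemble in one call."""
    graph = smiles_to_graph(smiles)
    return build_motif_graph(graph, decompose(graph), vocab)
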