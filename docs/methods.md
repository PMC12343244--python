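# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## Molecular graphs and features

Molecules are parsed with RDKit and canonicalized before graph
construction, so atom order — and every downstream matrix — is independent
of how the input SMILES was spelled. The graph is directed: each bond
yields two directed edges that are each other's `reverse_index` partner and
carry identical bond features. Hydrogens stay implicit.

Atom features (126 entries): element one-hot over atomic numbers 1–100
plus an "other" bucket; heavy-atom degree 0–5; formal charge −2…+2 plus
"other"; hybridization (SP, SP2, SP3, SP3D, SP3D2, other); aromaticity
flag; total H count 0–4 (clamped); atomic mass / 100. Bond features (6
entries): type one-hot (single/double/triple/aromatic), conjugation flag,
in-ring flag. Stereochemistry and 3D geometry are deliberately out of
scope: no feature depends on conformers, so the whole pipeline is
deterministic and download-free. Path-position or spatial-distance atom
descriptors would slot in as extra feature blocks but are not implemented.

## Motif decomposition

Two rules, applied by first marking the complete broken-bond set and then
taking connected components (hence order-independent):

1. every acyclic bond with **exactly one** endpoint inside a ring system is
   broken — a ring system being a maximal set of rings merged whenever they
   share an atom (this covers fused and spiro systems, which therefore stay
   intact in one fragment);
2. every non-ring atom with three or more heavy-atom neighbours becomes a
   singleton motif: all bonds incident to it are broken.

Consequences worth noting: a bond directly joining two ring systems
(biphenyl-like) has both endpoints inside ring systems and is *not*
broken, so the two systems share one fragment; and fragments are disjoint
by construction, so motif-graph edges are defined by *crossing bonds* —
motifs i and j are adjacent iff some original bond joins an atom of i to an
atom of j. Motif keys are the canonical SMILES of the induced fragment
with attachment points reduced to plain valence (no dummy atoms); keys are
sorted lexicographically at vocabulary-build time so indices never depend
on corpus order, and the last index is reserved for [UNK].

The motif distance matrix D holds BFS hop counts; disconnected pairs get
the sentinel n + 1 (one more than any realizable path — finite, so the
multiplicative attention mask stays well-defined). The [GLOBAL] node
occupies the last row/column of A and D, adjacent to and at distance 1
from every motif; it is excluded from the one-hot and association
matrices.

## Encoder

Node and edge hidden states (width d, default 256) are initialized by
ReLU-activated linear projections of the raw atom features and of the
source-atom-concatenated bond features respectively. Each of the K rounds
(default 3) aggregates incoming directed edges per node as the elementwise
product SUM ⊙ MAX — the sum carries neighbourhood mass, the elementwise max
keeps the most salient channel — and adds the message to the node state.
Between rounds, each edge is refreshed as ReLU(W_k (h_u − h_vu) + h_uv⁰):
subtracting the reverse edge stops information from echoing straight back.
The elementwise reading of MAX was chosen over picking one whole edge
vector (e.g. by norm) because it is the standard, differentiable
convention. Nodes with no incoming edges receive the zero message, so
single-atom molecules encode cleanly.

After K rounds a COMMUNICATE step — linear + ReLU applied to
h_v(K) + m_v(K) + x_v, with x_v the projected input feature — produces the
atom embeddings. The molecule embedding treats the canonically ordered
atoms as a pseudo-sequence: a bidirectional GRU (one GRU per direction,
outputs concatenated and projected back to d) followed by mean pooling
over real atoms. This reconciles a learned, context-aware readout with
average pooling; a plain `mean` readout is available by configuration.
Batches are processed as one disjoint union graph via segment reductions;
padding for the motif path appends zero rows, and because the association
matrix addresses only real atom columns, padding width cannot affect any
output (asserted in tests).

## Fusion and attention

Atom embeddings are projected onto motifs as ReLU((1/m) F X W_G + b_G)
with m the total atom count — implemented exactly as stated, even though
the per-motif size bias that normalization is meant to address would be
removed more directly by dividing each row by its own motif size; that
variant ships as `per_motif_norm`. Identity embeddings come from a
trainable table with one row per vocabulary index plus a dedicated
[GLOBAL] row; fusion is elementwise addition, and the [GLOBAL] row enters
the attention stack carrying its embedding only (no atomic signal).

Each of the L stacked layers (default 2) splits the d features into two
halves: the first half feeds the *global* channel masked by D, the second
the *local* channel masked by A. Per head (default 4 per channel), raw
scores Q Kᵀ are elementwise-multiplied by the mask and scaled by
√(d/2) before the row softmax. The multiplicative mask is kept as printed:
a zero mask entry zeroes the raw score but still receives softmax weight —
in particular the zero diagonal of A suppresses (not removes) self-scores
in the local channel. Config alternatives exist for all the judgment
calls: `additive_neg_inf` masking (zero entries → −1e9 *replacing* the
score, so a fully-masked row degrades to the uniform distribution),
`self_loops` to add the identity to A, and `distance_transform=reciprocal`
to decay rather than amplify far-pair scores. Outputs of the two channels
are concatenated, added residually and layer-normalized.

The refined matrix is pooled by taking the [GLOBAL] row — the node exists
precisely to aggregate graph-level information; mean pooling over motifs
is the configurable alternative — and combined as M′ = M + α·H′[GLOBAL]
with α a learnable scalar initialized to 0.1 (small initial motif
contribution; the encoder path dominates early training). With α = 0 the
representation is exactly the encoder's, which is also how the
"no attention stack" ablation behaves. The prediction head is
Linear–ReLU–Linear at width d.

## Training pipeline

Scaffold splitting groups molecules by Bemis–Murcko framework (acyclic
molecules key on their own canonical SMILES), sorts clusters by size
descending with ties broken by key, and assigns each cluster to the split
furthest below its quota — largest clusters placed first, ties resolving
train > val > test. On all-singleton inputs this yields exactly the 8:1:1
ratios; the procedure is fully deterministic.

Classification minimizes BCE-with-logits with missing labels (NaN cells)
masked out of the loss; regression minimizes MSE on per-target
standardized labels (train-split statistics, undone at evaluation).
Optimizer is Adam; defaults lr 1e-4, batch 256, 100 epochs. The
best-validation-epoch weights are returned (checkpoint policy: validation
selection, no early stopping or LR schedule). ROC-AUC is averaged over
tasks with both classes present; tasks with one class are skipped with a
warning, and an error is raised only if no task is scorable.

Because no deep-learning framework is part of the dependency set, the
trainable stack runs on the package's own reverse-mode autodiff engine
over float64 NumPy arrays (`dfusmol.nn`): a tape of ~20 primitives
(including segment sum/max for message passing, softmax, layer norm and a
GRU) with gradients verified against central finite differences in the
test suite. Segment-max gradients split evenly across ties.

## Synthetic data and what the benchmarks show

The generator assembles molecules from a fixed template grammar — cores
{benzene, pyridine, cyclohexane}, substituents {methyl, amino, carboxyl,
F, Cl, Br}, 0–3 substituents per core, a methyl-bearing sp3 bridge for
two-core molecules, and fully acyclic branched molecules — guaranteeing
chemical validity and coverage of both cleavage rules without a
valence-repair pass (the first three molecules of any set are drawn one
per template kind). Labels are computed from structure: `ring_count`
(regression), `has_nitrogen` (binary), and `motif_weighted` = #amino −
#halogens + N(0, 0.1²) noise, a property that lives on functional groups.
Generation is bit-identical for fixed (n, seed).

Benchmark problem sizes were fixed once: the learnability runs use 400
molecules, scaffold-split 8:1:1, hidden width 128, lr 1e-3, batch 32, 30
epochs; the ablation comparison uses 300 molecules, width 64, 20 epochs —
sizes at which a single CPU trains each model in tens of seconds while
leaving wide margins on the quality thresholds (ring-count RMSE reaches
≈ 0.01 against a 0.3 bar; nitrogen ROC-AUC saturates at 1.0). The paper-
scale defaults (width 256, lr 1e-4, batch 256, 100 epochs) remain the
`TrainConfig`/`ModelConfig` defaults.

These fixtures demonstrate that the architecture is wired correctly and
can learn structure-derived signals under scaffold shift; they do not
emulate real assay data — label noise is Gaussian or absent, property
ranges are narrow, the chemical space is tiny, and class balance is
benign. Passing them says nothing quantitative about MoleculeNet-scale
performance.

## Numerical and degenerate-input conventions

- Float64 throughout; oracle-equivalence tests assert 1e-6 agreement.
- Softmax subtracts the row max before exponentiation.
- Empty incoming-edge sets aggregate to zero; empty graphs are rejected.
- A single-motif molecule yields 2×2 motif matrices ([GLOBAL] + motif) and
  a two-entry attention row.
- Unparseable SMILES raise a named parse error everywhere except bulk
  vocabulary building (skip with warning) and `predict` (error recorded in
  the output row).
- Vocabulary serialization is a two-column TSV; reloading reproduces
  indices exactly.

## Known limitations

- No stereochemistry, conformers, or 3D-derived features.
- The motif-edge definition ("crossing bonds") is the only reading
  consistent with disjoint fragments; alternative readings based on shared
  atoms would require overlapping fragments.
- Multiplicative masking lets zero-score entries keep softmax mass; the
  additive mode is provided but is not the default.
- The GRU readout processes atoms in canonical order; embeddings are
  deterministic and spelling-invariant, but not invariant to relabeling
  that changes the canonical order itself (canonicalization makes this
  unobservable through the public API).
- Training is single-process CPU; no LR schedules, early stopping, or
  distributed support.
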