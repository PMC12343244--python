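# dfusmol

Dual-granularity molecular property prediction for drug-discovery datasets:
an atomic-level communicative message-passing encoder is fused with a
chemistry-rule **motif graph** through a distance/adjacency-masked
**global-local attention** stack. The package targets the standard
SMILES-with-labels setting (MoleculeNet-style CSVs, single- or multi-task,
classification or regression) and ships a deterministic synthetic-molecule
generator so every stage is testable without downloads.

## The model

A molecule is read twice, at two scales:

1. **Atomic scale.** The SMILES is parsed (RDKit) into a directed graph
   G = (V, E): every bond contributes two directed edges. Atoms carry
   chemprop-style one-hot features (element, degree, charge, hybridization,
   aromaticity, H count, scaled mass); bonds carry type/conjugation/ring
   flags. A communicative message-passing encoder updates node and edge
   hidden states jointly for K rounds:

   - m_v = SUM(h_uv) ⊙ MAX(h_uv) over incoming edges (elementwise),
   - h_v ← h_v + m_v,
   - h_uv ← ReLU(W (h_u − h_vu) + h_uv⁰), where h_vu is the reverse edge,

   followed by a COMMUNICATE step (linear + ReLU over h_v + m_v + x_v)
   giving per-atom embeddings X, and a bidirectional-GRU readout with mean
   pooling giving the molecule embedding M.

2. **Motif scale.** Two cleavage rules fragment the molecule: (1) every
   acyclic bond joining a ring system to a substituent is broken; (2) every
   non-ring atom with ≥ 3 heavy neighbours becomes a singleton motif.
   Fragments partition the atoms; each motif is keyed by its canonical
   SMILES and indexed in a vocabulary with a reserved [UNK] slot. The motif
   graph gains a [GLOBAL] node (hop distance 1 to every motif) and three
   matrices: adjacency **A**, shortest-path distances **D**, and the
   motif-atom association **F**.

Atomic features are projected onto motifs, H_atomic = ReLU((1/m) F X W_G +
b_G), fused additively with trainable motif identity embeddings, and passed
through L stacked attention layers whose feature space is split into two
channels: the *global* channel multiplies its raw attention scores by D,
the *local* channel by A, per head, before the softmax. The refined
[GLOBAL] row, scaled by a learnable α, augments the encoder embedding:
M′ = M + α·H′[GLOBAL], which feeds a feedforward prediction head.
Classification uses BCE-with-logits (missing labels masked) and mean
ROC-AUC; regression uses MSE and RMSE. Datasets are split 8:1:1 by
Bemis-Murcko scaffold so evaluation molecules use unseen core frameworks.

Every layer is built on a small NumPy reverse-mode autodiff engine
(`dfusmol.nn`) with finite-difference-verified gradients; training uses
Adam (defaults: lr 1e-4, batch 256, 100 epochs; the synthetic benchmarks
in this repository use smaller, documented settings — see
`docs/methods.md`).

Ablation switches reproduce the reduced variants from configuration alone:
`use_distance=False` (D → all-ones), `use_adjacency=False` (A → all-ones),
both, or `use_gl_transformer=False` (M′ = M).

## Worked example

```python
from dfusmol import (TaskSpec, TrainConfig, make_fixture_dataset, predict, train)
from dfusmol.model import ModelConfig

dataset = make_fixture_dataset(n=200, seed=0, recipe="ring_count").to_dataset()
config = TrainConfig(lr=1e-3, batch_size=32, epochs=8, seed=0,
                     model=ModelConfig(hidden_dim=64))
result = train(dataset, TaskSpec("regression"), config)
print(result.best_val_metric)
```

Running `python examples/03_train_on_synthetic_data.py` (the same code)
prints the training log and finishes with

```
best val RMSE 0.192 at epoch 8 (targets are integer ring counts, so < 0.5
means the count is usually right)

predicted ring counts for held-out molecules:
          smiles  ring_count_pred
        c1ccccc1         1.147856
C1CCCCC1C1CCCCC1         1.525334
             CCO         0.113357
```

i.e. after eight epochs on 160 training molecules the model reads ring
counts (true values 1, 2, 0 here) from held-out scaffolds to within about
half a ring; the 400-molecule, 30-epoch benchmark in
`scripts/acceptance.py` reaches RMSE ≈ 0.01. The other examples
demonstrate motif decomposition, attention export and the ablation
switches. The same flows are available from the shell:

```bash
dfusmol make-fixtures -n 400 --seed 0 --recipe ring_count -o toy.csv
dfusmol train --data toy.csv --task regression -o run/
dfusmol predict --checkpoint run/ "Cc1ccccc1"
dfusmol attend "Cc1ccccc1" --checkpoint run/ --layer -1 -o attn.json
```

For real benchmarks a hyperparameter search over learning rate
{1e-3, 5e-4, 1e-4}, batch size {64, 128, 256} and attention heads
{2, 4, 8} is the documented protocol; no tuner is bundled.

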