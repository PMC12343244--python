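"""Encode a molecule and export per-head attention over its motifs.

The encoder produces one embedding per atom plus a pooled molecule vector;
the attention stack then scores every motif (and the [GLOBAL] node) against
every other.  The printed [GLOBAL] row shows how much each attention head
looks at each motif — rows always sum to one.
"""

import numpy as np

from dfusmol import (
    DFusMol,
    ModelConfig,
    build_motif_graph,
    build_vocabulary,
    decompose,
    smiles_to_graph,
)

smiles = "O=C(NCc1cccnc1)C(Cc1cc2cc(ccc2nc1N)-c1ccccc1C)C"
graph = smiles_to_graph(smiles)
fragments = decompose(graph)
vocab = build_vocabulary([smiles])
motif_graph = build_motif_graph(graph, fragments, vocab)

model = DFusMol(vocab, n_targets=1,
                config=ModelConfig(hidden_dim=64, depth=3, num_attention_layers=2),
                seed=0)
out = model.encoder.encode(graph)
print(f"{graph.n_atoms} atoms -> atom embeddings {out.atom_embeddings.shape}, "
      f"molecule embedding {out.molecule_embedding.shape}")
print(f"{len(fragments)} motifs:", [f.motif_key for f in fragments])

weights = model.export_attention(graph, motif_graph, layer_index=-1)
gi = motif_graph.global_index
print("\n[GLOBAL]-row attention per head (untrained weights, last layer):")
for channel in ("global", "local"):
    for h, w in enumerate(weights[channel]):
        row = np.round(w[gi], 3)
        print(f"  {channel:6s} head {h}: {row}  (sum {row.sum():.3f})")
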