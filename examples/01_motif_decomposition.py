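"""Fragment a molecule into motifs and inspect the motif-graph matrices.

Toluene splits into two motifs (the benzene ring and the methyl carbon);
the adjacency/distance matrices gain one extra row for the [GLOBAL] node,
which sits at hop distance 1 from every motif.
"""

from dfusmol import build_motif_graph, build_vocabulary, decompose, smiles_to_graph

graph = smiles_to_graph("Cc1ccccc1")
fragments = decompose(graph)
print("motifs of toluene:")
for frag in fragments:
    print(f"  {frag.motif_key:10s} atoms {sorted(frag.atom_indices)}")

vocab = build_vocabulary(["Cc1ccccc1", "CCO", "c1ccncc1"])
motif_graph = build_motif_graph(graph, fragments, vocab)
print(f"\nvocabulary size (incl. [UNK]): {vocab.size}")
print(f"adjacency A ({motif_graph.adjacency.shape[0]} rows; last = [GLOBAL]):")
print(motif_graph.adjacency)
print("distance D (hop counts; [GLOBAL] row fixed to 1):")
print(motif_graph.distance)
print("association F (motif x atom membership; columns sum to 1):")
print(motif_graph.association)
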