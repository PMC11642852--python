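"""Build a token graph for a small synthetic genome and inspect it.

Generates a 600-nt reference with soft-masked and ambiguous bases, runs the
full pipeline (chunk -> clean -> tokenize -> attention -> threshold ->
degree filter) with the deterministic mock attention provider, and prints
the graph summary plus its strongest edges.
"""

import tempfile
from pathlib import Path

from tokengraph import (
    GraphConfig,
    KmerTokenizer,
    MockAttentionProvider,
    SynthGenomeSpec,
    build_reference_graph,
    open_genome,
    synth_genome,
    write_graph,
)

workdir = Path(tempfile.mkdtemp())
fasta = workdir / "demo.fa"
synth_genome(
    SynthGenomeSpec(lengths=(600,), invalid_char_rate=0.05, lowercase_rate=0.2, seed=4),
    fasta,
)

genome = open_genome(fasta)
graph = build_reference_graph(
    genome,
    "chr_t1",
    tokenizer=KmerTokenizer(3),
    provider=MockAttentionProvider(seed=4, L=2, H=2, max_tokens=128),
    config=GraphConfig(theta=0.012, min_degree=2),
    model_max_tokens=128,
)

print(f"reference chr_t1: {graph.n_nodes} token nodes, {graph.n_edges} edges")
print("strongest attention edges (i -- j : weight, token_i token_j):")
for (i, j), w in sorted(graph.edges.items(), key=lambda kv: -kv[1])[:5]:
    ni, nj = graph.nodes[i], graph.nodes[j]
    print(f"  {i:4d} -- {j:4d} : {w:.4f}  {ni.token_string}@{ni.start} {nj.token_string}@{nj.start}")

out = workdir / "chr_t1.json"
write_graph(graph, "node-link-json", out)
print(f"graph written to {out}")
# Each edge weight is the layer/head-averaged attention probability between
# the two tokens; the threshold keeps only pairs at or above theta, and the
# degree filter removed nodes with fewer than 2 such neighbors.
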