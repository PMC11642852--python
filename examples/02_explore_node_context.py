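"""Resolve a clicked node to its genomic context, the way the server does.

Builds a small graph, then asks for the DNA window around one node with
50-nt flanks and the graph neighbors that fall inside the window — the
payload an interactive front end would render as highlighted sequence.
"""

import tempfile
from pathlib import Path

from tokengraph import (
    GraphConfig,
    GraphService,
    KmerTokenizer,
    MockAttentionProvider,
    SynthGenomeSpec,
    build_reference_graph,
    node_context,
    open_genome,
    synth_genome,
)

workdir = Path(tempfile.mkdtemp())
fasta = workdir / "demo.fa"
synth_genome(SynthGenomeSpec(lengths=(400,), seed=8), fasta)
genome = open_genome(fasta)
graph = build_reference_graph(
    genome, "chr_t1", KmerTokenizer(3),
    MockAttentionProvider(seed=8, max_tokens=100),
    GraphConfig(theta=0.013), model_max_tokens=100,
)

view = node_context(graph, genome, node_index=20, flank=50)
print(f"focal token interval: {view.focal_interval}")
print(f"window [{view.window_start}, {view.window_end}): {view.segment[:60]}...")
print(f"{len(view.neighbor_intervals)} neighbors intersect the window:")
for idx, start, end in view.neighbor_intervals[:5]:
    print(f"  node {idx} at [{start}, {end})")

# the same lookup through the service layer that backs the HTTP API
service = GraphService(graph, genome)
hit = service.search("chr_t1", position=view.focal_interval[0])
print(f"position-based search returns node {hit} (the clicked node)")
# The window is the node's interval +/- 50 nt clamped to the reference;
# neighbor intervals are where an interface would paint highlights.
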