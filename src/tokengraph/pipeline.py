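"""End-to-end orchestration: FASTA -> per-reference token graphs.

Ties the stages together in their pipeline order: chunking sized to the
model's token budget, cleaning, tokenization with offset globalization,
per-chunk attention aggregation, upper-triangular thresholding, union of
chunk graphs per reference and finally degree filtering. Attention never
crosses chunk boundaries — the model only ever sees one chunk.
"""

from __future__ import annotations

from .attention import aggregate, raw_attention
from .graph_build import (
    GraphConfig,
    TokenGraph,
    apply_degree_filter,
    build_chunk_graph,
    merge_reference_graph,
)
from .sequence_io import (
    CleanedChunk,
    GenomeSource,
    SequenceChunk,
    clean_chunk,
    compute_chunk_length,
    iter_chunks,
)
from .tokenization import TokenizerAdapter, globalize_offsets, tokenize_chunk

__all__ = ["build_reference_graph", "build_genome_graphs", "sequence_to_graph"]


def _chunk_to_graph(
    cleaned: CleanedChunk,
    tokenizer: TokenizerAdapter,
    provider,
    config: GraphConfig,
    node_index_start: int,
    renormalize: bool,
) -> tuple[TokenGraph | None, int]:
    tokens = tokenize_chunk(cleaned, tokenizer)
    if not tokens:
        return None, node_index_start
    nodes = globalize_offsets(tokens, cleaned, node_index_start)
    tensor = raw_attention(provider, [t[0] for t in tokens])
    attn = aggregate(tensor, renormalize=renormalize)
    graph = build_chunk_graph(nodes, attn, config)
    return graph, node_index_start + len(nodes)


def build_reference_graph(
    genome: GenomeSource,
    reference: str,
    tokenizer: TokenizerAdapter,
    provider,
    config: GraphConfig = GraphConfig(),
    model_max_tokens: int | None = None,
    renormalize: bool = True,
) -> TokenGraph:
    """Run the full pipeline for one reference.

    The chunk length is ``model_max_tokens - tokenizer.n_special_tokens``
    nucleotides (provider capacity is used when ``model_max_tokens`` is
    omitted). The degree filter runs after the chunk-graph union; since no
    cross-chunk edges exist this equals filtering each chunk graph.
    """
    if model_max_tokens is None:
        model_max_tokens = getattr(provider, "max_tokens", 512)
    chunk_length = compute_chunk_length(model_max_tokens, tokenizer.n_special_tokens)
    chunk_graphs = []
    node_counter = 0
    for chunk in iter_chunks(genome, reference, chunk_length):
        graph, node_counter = _chunk_to_graph(
            clean_chunk(chunk), tokenizer, provider, config, node_counter, renormalize
        )
        if graph is not None:
            chunk_graphs.append(graph)
    merged = merge_reference_graph(chunk_graphs, reference=reference)
    return apply_degree_filter(merged, config.min_degree, iterative=config.kcore)


def build_genome_graphs(
    genome: GenomeSource,
    tokenizer: TokenizerAdapter,
    provider,
    config: GraphConfig = GraphConfig(),
    model_max_tokens: int | None = None,
    renormalize: bool = True,
) -> dict[str, TokenGraph]:
    """One graph per reference, in FASTA order."""
    return {
        name: build_reference_graph(
            genome, name, tokenizer, provider, config, model_max_tokens, renormalize
        )
        for name, _ in genome.references
    }


def sequence_to_graph(
    sequence: str,
    tokenizer: TokenizerAdapter,
    provider,
    config: GraphConfig = GraphConfig(),
    reference: str = "seq",
    renormalize: bool = True,
) -> TokenGraph:
    """Pipeline for a bare in-memory sequence treated as one reference.

    Used by the classifier, where each sequence of a labeled pair becomes
    its own single-reference graph. Sequences longer than the provider
    capacity are chunked exactly like genome references.
    """
    max_tokens = getattr(provider, "max_tokens", 512)
    chunk_length = compute_chunk_length(max_tokens, tokenizer.n_special_tokens)
    chunk_graphs = []
    node_counter = 0
    for start in range(0, len(sequence), chunk_length):
        raw = SequenceChunk(
            reference=reference,
            start=start,
            raw_sequence=sequence[start : start + chunk_length],
        )
        graph, node_counter = _chunk_to_graph(
            clean_chunk(raw), tokenizer, provider, config, node_counter, renormalize
        )
        if graph is not None:
            chunk_graphs.append(graph)
    merged = merge_reference_graph(chunk_graphs, reference=reference)
    return apply_degree_filter(merged, config.min_degree, iterative=config.kcore)
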