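import numpy as np
import pytest

from tokengraph.graph_build import TokenGraph
from tokengraph.sequence_io import open_genome
from tokengraph.tokenization import TokenNode


@pytest.fixture
def two_record_fasta(tmp_path):
    """chr_t1: 40 nt (ACGTACGT x5), chr_t2: 12 nt, wrapped at 20 cols."""
    seq1 = "ACGTACGT" * 5
    seq2 = "ACGTACGTACGT"
    path = tmp_path / "two.fa"
    lines = [">chr_t1"]
    for i in range(0, len(seq1), 20):
        lines.append(seq1[i : i + 20])
    lines += [">chr_t2", seq2]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def genome(two_record_fasta):
    g = open_genome(two_record_fasta)
    yield g
    g.close()


def make_token_nodes(m: int, reference: str = "chr_r", k: int = 3) -> list[TokenNode]:
    """m contiguous k-nt token nodes with deterministic ids."""
    return [
        TokenNode(
            token_id=i % 64,
            token_string="ACG",
            reference=reference,
            start=i * k,
            end=(i + 1) * k,
            node_index=i,
        )
        for i in range(m)
    ]


def random_token_graph(rng: np.random.Generator, m: int | None = None,
                       edge_prob: float = 0.3, reference: str = "chr_r") -> TokenGraph:
    """A random but internally consistent token graph for property tests."""
    if m is None:
        m = int(rng.integers(1, 15))
    graph = TokenGraph(reference=reference)
    for node in make_token_nodes(m, reference):
        graph.nodes[node.node_index] = node
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < edge_prob:
                graph.edges[(i, j)] = float(rng.random())
    return graph
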