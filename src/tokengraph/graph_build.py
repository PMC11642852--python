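"""Construction, filtering and serialization of token graphs.

A token graph is undirected and weighted: nodes are tokens anchored to
genomic intervals, and an edge (i, j) with i < j carries the aggregated
attention weight a_ij. Only the upper triangle of the attention matrix is
consulted, which guarantees at most one edge per node pair and no
self-loops. Two orthogonal filters apply: an inclusive edge-weight
threshold (a_ij >= theta) at construction, and a degree-connectivity
threshold that removes weakly connected nodes afterwards.

Each reference is one graph; chunk graphs of a reference are unioned
without creating cross-chunk edges.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .attention import AttentionMatrix
from .tokenization import TokenNode

__all__ = [
    "GraphConfig",
    "TokenGraph",
    "build_chunk_graph",
    "apply_degree_filter",
    "merge_reference_graph",
    "write_graph",
    "read_graph",
    "GRAPH_FORMATS",
]

GRAPH_FORMATS = ("graphml", "node-link-json", "edge-tsv")

_NODE_FIELDS = ("node_index", "token_id", "token_string", "reference", "start", "end")


@dataclass(frozen=True)
class GraphConfig:
    """User-facing graph filtering knobs.

    theta: inclusive edge-weight threshold in [0, 1].
    min_degree: minimum neighbor count a node needs to survive filtering.
    kcore: if True, degree filtering is iterated to a fixed point (k-core)
        instead of the default single pass.
    """

    theta: float = 0.0
    min_degree: int = 0
    kcore: bool = False

    def __post_init__(self):
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if self.min_degree < 0:
            raise ValueError(f"min_degree must be >= 0, got {self.min_degree}")


@dataclass
class TokenGraph:
    """Per-reference undirected weighted graph over token nodes.

    ``edges`` maps (i, j) with i < j to the edge weight; node indices are
    stable identifiers and are never recompacted by filtering.
    """

    reference: str
    nodes: dict[int, TokenNode] = field(default_factory=dict)
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[int, int]:
        deg = {i: 0 for i in self.nodes}
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, node_index: int) -> list[int]:
        if node_index not in self.nodes:
            raise KeyError(f"unknown node {node_index}")
        out = []
        for i, j in self.edges:
            if i == node_index:
                out.append(j)
            elif j == node_index:
                out.append(i)
        return sorted(out)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TokenGraph):
            return NotImplemented
        return (
            self.reference == other.reference
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(reference=self.reference)
        for idx, node in sorted(self.nodes.items()):
            g.add_node(
                idx,
                node_index=node.node_index,
                token_id=node.token_id,
                token_string=node.token_string,
                reference=node.reference,
                start=node.start,
                end=node.end,
            )
        for (i, j), weight in sorted(self.edges.items()):
            g.add_edge(i, j, weight=weight)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "TokenGraph":
        nodes = {}
        for idx, attrs in g.nodes(data=True):
            idx = int(idx)
            nodes[idx] = TokenNode(
                token_id=int(attrs["token_id"]),
                token_string=str(attrs["token_string"]),
                reference=str(attrs["reference"]),
                start=int(attrs["start"]),
                end=int(attrs["end"]),
                node_index=int(attrs["node_index"]),
            )
        edges = {}
        for u, v, attrs in g.edges(data=True):
            i, j = sorted((int(u), int(v)))
            edges[(i, j)] = float(attrs["weight"])
        return cls(reference=str(g.graph.get("reference", "")), nodes=nodes, edges=edges)


def build_chunk_graph(
    tokens: list[TokenNode], attn: AttentionMatrix, config: GraphConfig
) -> TokenGraph:
    """Threshold the upper triangle of an attention matrix into edges.

    For every token pair i < j an edge with weight a_ij is created iff
    a_ij >= theta (inclusive); a_ji is never consulted. All nodes are kept,
    including isolated ones — degree filtering is a separate step.
    """
    m = len(tokens)
    if m != attn.token_count:
        raise ValueError(
            f"{m} tokens but attention matrix is {attn.token_count}x{attn.token_count}"
        )
    reference = tokens[0].reference if tokens else ""
    graph = TokenGraph(reference=reference)
    for node in tokens:
        if node.reference != reference:
            raise ValueError("all tokens of a chunk graph must share one reference")
        graph.nodes[node.node_index] = node
    values = attn.values
    rows, cols = np.triu_indices(m, k=1)
    keep = values[rows, cols] >= config.theta
    for r, c in zip(rows[keep], cols[keep]):
        i = tokens[r].node_index
        j = tokens[c].node_index
        graph.edges[(min(i, j), max(i, j))] = float(values[r, c])
    return graph


def apply_degree_filter(
    graph: TokenGraph, min_degree: int, iterative: bool = False
) -> TokenGraph:
    """Drop nodes with fewer than ``min_degree`` neighbors.

    The default is a single pass over the input graph's degrees: a node
    surviving the pass may end up with fewer neighbors afterwards (its
    neighbors may have been removed). With ``iterative=True`` the pass is
    repeated to a fixed point, which is the classical k-core. Node indices
    are preserved, never recompacted.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    if min_degree == 0:
        return TokenGraph(reference=graph.reference, nodes=dict(graph.nodes), edges=dict(graph.edges))
    current = graph
    while True:
        deg = current.degrees()
        survivors = {i for i, d in deg.items() if d >= min_degree}
        result = TokenGraph(
            reference=current.reference,
            nodes={i: n for i, n in current.nodes.items() if i in survivors},
            edges={
                (i, j): w
                for (i, j), w in current.edges.items()
                if i in survivors and j in survivors
            },
        )
        if not iterative or result.n_nodes == current.n_nodes:
            return result
        current = result


def merge_reference_graph(chunk_graphs: list[TokenGraph], reference: str | None = None) -> TokenGraph:
    """Union the chunk graphs of one reference (disjoint node index sets).

    No cross-chunk edges are created; attention is strictly per-chunk.
    """
    if not chunk_graphs:
        return TokenGraph(reference=reference or "")
    ref = chunk_graphs[0].reference
    merged = TokenGraph(reference=ref)
    for g in chunk_graphs:
        if g.reference != ref:
            raise ValueError(
                f"cannot merge graphs of different references ({g.reference!r} vs {ref!r})"
            )
        overlap = merged.nodes.keys() & g.nodes.keys()
        if overlap:
            raise ValueError(f"chunk graphs share node indices: {sorted(overlap)[:5]}")
        merged.nodes.update(g.nodes)
        merged.edges.update(g.edges)
    return merged


def _infer_format(path: str) -> str:
    if path.endswith(".graphml"):
        return "graphml"
    if path.endswith(".json"):
        return "node-link-json"
    if path.endswith(".tsv"):
        return "edge-tsv"
    raise ValueError(f"cannot infer graph format from {path!r}; pass format explicitly")


def _node_tsv_path(edge_path: str) -> str:
    base = edge_path[:-4] if edge_path.endswith(".tsv") else edge_path
    return base + ".nodes.tsv"


def write_graph(graph: TokenGraph, format: str | None = None, path: str | os.PathLike = "") -> None:
    """Serialize a token graph losslessly.

    Formats: ``graphml``, ``node-link-json`` (the payload the server
    consumes) and ``edge-tsv`` (edge list plus a companion
    ``<stem>.nodes.tsv``). All three round-trip exactly through
    :func:`read_graph`.
    """
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    if fmt == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif fmt == "node-link-json":
        payload = {
            "reference": graph.reference,
            "nodes": [
                {
                    "node_index": n.node_index,
                    "token_id": n.token_id,
                    "token_string": n.token_string,
                    "reference": n.reference,
                    "start": n.start,
                    "end": n.end,
                }
                for _, n in sorted(graph.nodes.items())
            ],
            "links": [
                {"source": i, "target": j, "weight": w}
                for (i, j), w in sorted(graph.edges.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("i\tj\tweight\n")
            for (i, j), w in sorted(graph.edges.items()):
                fh.write(f"{i}\t{j}\t{w!r}\n")
        with open(_node_tsv_path(path), "w") as fh:
            fh.write(f"#reference\t{graph.reference}\n")
            fh.write("\t".join(_NODE_FIELDS) + "\n")
            for _, n in sorted(graph.nodes.items()):
                fh.write(
                    f"{n.node_index}\t{n.token_id}\t{n.token_string}\t"
                    f"{n.reference}\t{n.start}\t{n.end}\n"
                )
    else:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")


def read_graph(path: str | os.PathLike, format: str | None = None) -> TokenGraph:
    """Load a token graph written by :func:`write_graph`."""
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    if fmt == "graphml":
        g = nx.read_graphml(path, node_type=int)
        return TokenGraph.from_networkx(g)
    if fmt == "node-link-json":
        with open(path) as fh:
            payload = json.load(fh)
        graph = TokenGraph(reference=payload["reference"])
        for rec in payload["nodes"]:
            graph.nodes[int(rec["node_index"])] = TokenNode(
                token_id=int(rec["token_id"]),
                token_string=rec["token_string"],
                reference=rec["reference"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                node_index=int(rec["node_index"]),
            )
        for rec in payload["links"]:
            i, j = sorted((int(rec["source"]), int(rec["target"])))
            graph.edges[(i, j)] = float(rec["weight"])
        return graph
    if fmt == "edge-tsv":
        graph = TokenGraph(reference="")
        with open(_node_tsv_path(path)) as fh:
            first = fh.readline()
            if first.startswith("#reference\t"):
                graph.reference = first.rstrip("\n").split("\t", 1)[1]
                fh.readline()  # column header
            for line in fh:
                idx, token_id, token_string, reference, start, end = line.rstrip("\n").split("\t")
                node = TokenNode(
                    token_id=int(token_id),
                    token_string=token_string,
                    reference=reference,
                    start=int(start),
                    end=int(end),
                    node_index=int(idx),
                )
                graph.nodes[node.node_index] = node
                if not graph.reference:
                    graph.reference = reference
        with open(path) as fh:
            fh.readline()
            for line in fh:
                i, j, w = line.rstrip("\n").split("\t")
                i, j = sorted((int(i), int(j)))
                graph.edges[(i, j)] = float(w)
        return graph
    raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
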