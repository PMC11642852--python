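"""Backend JSON API for interactive graph exploration.

Clicking a node in a rendered graph maps to ``GET /node/<i>/context``: the
server fetches the genomic window around the node's interval straight from
the FASTA file and reports which graph neighbors fall inside the window, so
a front end can highlight the focal token and its neighbors in sequence
context. ``GET /graph`` serves the node-link payload (optionally re-filtered
by ``?theta=``) and ``GET /search`` resolves a genomic position to the node
whose interval contains it.

The HTTP layer is a plain WSGI app (stdlib ``wsgiref``); any front end is
out of scope here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from urllib.parse import parse_qs
from wsgiref.simple_server import make_server

from .graph_build import TokenGraph, read_graph
from .sequence_io import GenomeSource, fetch_segment, open_genome

__all__ = ["ContextView", "node_context", "GraphService", "make_wsgi_app", "serve_graph"]

DEFAULT_FLANK = 50


@dataclass(frozen=True)
class ContextView:
    """Genomic context of one clicked node, ready for display."""

    node_index: int
    segment: str
    window_start: int
    window_end: int
    focal_interval: tuple[int, int]
    neighbor_intervals: list[tuple[int, int, int]]  # (node_index, start, end)


def node_context(
    graph: TokenGraph,
    genome: GenomeSource,
    node_index: int,
    flank: int = DEFAULT_FLANK,
) -> ContextView:
    """Fetch the DNA window around a node and locate its graph neighbors.

    The window is the node's interval extended by ``flank`` nucleotides on
    each side, clamped to the reference. Neighbors are the graph-adjacent
    nodes whose intervals intersect the window, sorted by start.
    """
    if node_index not in graph.nodes:
        raise KeyError(f"unknown node {node_index}")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    node = graph.nodes[node_index]
    ref_length = genome.length_of(node.reference)
    window_start = max(0, node.start - flank)
    window_end = min(ref_length, node.end + flank)
    segment = fetch_segment(genome, node.reference, window_start, window_end)
    neighbors = []
    for j in graph.neighbors(node_index):
        nb = graph.nodes[j]
        if nb.start < window_end and nb.end > window_start:
            neighbors.append((j, nb.start, nb.end))
    neighbors.sort(key=lambda item: (item[1], item[0]))
    return ContextView(
        node_index=node_index,
        segment=segment,
        window_start=window_start,
        window_end=window_end,
        focal_interval=(node.start, node.end),
        neighbor_intervals=neighbors,
    )


class GraphService:
    """The API surface behind the HTTP endpoints, usable directly from Python."""

    def __init__(self, graph: TokenGraph, genome: GenomeSource):
        self.graph = graph
        self.genome = genome

    def graph_payload(self, theta: float | None = None) -> dict:
        """Node-link payload; ``theta`` re-filters edges server-side.

        Re-filtering at serve time keeps edges with weight >= theta and
        leaves the node set untouched, matching a rebuild at that theta
        (before any degree filtering).
        """
        g = self.graph
        edges = g.edges
        if theta is not None:
            edges = {k: w for k, w in edges.items() if w >= theta}
        return {
            "reference": g.reference,
            "nodes": [
                {
                    "node_index": n.node_index,
                    "token_id": n.token_id,
                    "token_string": n.token_string,
                    "reference": n.reference,
                    "start": n.start,
                    "end": n.end,
                }
                for _, n in sorted(g.nodes.items())
            ],
            "links": [
                {"source": i, "target": j, "weight": w}
                for (i, j), w in sorted(edges.items())
            ],
        }

    def context_payload(self, node_index: int, flank: int = DEFAULT_FLANK) -> dict:
        view = node_context(self.graph, self.genome, node_index, flank)
        payload = asdict(view)
        payload["focal_interval"] = list(view.focal_interval)
        payload["neighbor_intervals"] = [list(t) for t in view.neighbor_intervals]
        return payload

    def search(self, reference: str, position: int) -> int | None:
        """Node whose genomic interval contains ``position``, or None."""
        for idx, node in sorted(self.graph.nodes.items()):
            if node.reference == reference and node.start <= position < node.end:
                return idx
        return None


def make_wsgi_app(service: GraphService):
    """Wrap a :class:`GraphService` as a WSGI application."""

    def _json(start_response, status: str, payload) -> list[bytes]:
        body = json.dumps(payload).encode("utf-8")
        start_response(
            status,
            [("Content-Type", "application/json"), ("Content-Length", str(len(body)))],
        )
        return [body]

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "/")
        params = parse_qs(environ.get("QUERY_STRING", ""))
        try:
            if path == "/graph":
                theta = None
                if "theta" in params:
                    theta = float(params["theta"][0])
                    if not (0.0 <= theta <= 1.0):
                        raise ValueError("theta out of range")
                return _json(start_response, "200 OK", service.graph_payload(theta))
            if path.startswith("/node/") and path.endswith("/context"):
                node_index = int(path.split("/")[2])
                flank = int(params.get("flank", [DEFAULT_FLANK])[0])
                if flank < 0:
                    raise ValueError("flank must be >= 0")
                try:
                    payload = service.context_payload(node_index, flank)
                except KeyError:
                    return _json(
                        start_response, "404 Not Found",
                        {"error": f"unknown node {node_index}"},
                    )
                return _json(start_response, "200 OK", payload)
            if path == "/search":
                reference = params.get("reference", [service.graph.reference])[0]
                if "position" not in params:
                    raise ValueError("missing 'position' parameter")
                position = int(params["position"][0])
                idx = service.search(reference, position)
                if idx is None:
                    return _json(
                        start_response, "404 Not Found",
                        {"error": f"no node covers {reference}:{position}"},
                    )
                node = service.graph.nodes[idx]
                return _json(
                    start_response, "200 OK",
                    {"node_index": idx, "start": node.start, "end": node.end},
                )
            return _json(start_response, "404 Not Found", {"error": "unknown endpoint"})
        except (ValueError, KeyError) as exc:
            return _json(start_response, "400 Bad Request", {"error": str(exc)})

    return app


def serve_graph(
    graph_path: str, fasta_path: str, host: str = "127.0.0.1", port: int = 8000
) -> None:
    """Serve a graph file over HTTP until interrupted."""
    graph = read_graph(graph_path)
    genome = open_genome(fasta_path)
    app = make_wsgi_app(GraphService(graph, genome))
    with make_server(host, port, app) as server:
        print(f"serving {graph_path} on http://{host}:{port}")
        server.serve_forever()
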