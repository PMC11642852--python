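"""GCN classifier over token graphs for enhancer-promoter interaction.

Each sequence of a labeled pair is pushed through the full graph pipeline
(clean, tokenize, attention, threshold) to become its own single-reference
token graph. A small graph convolutional network then embeds each graph and
a logistic readout on the concatenated pair embedding predicts interaction.

Architecture (fixed but configurable): token-id embedding of width d, two
graph-convolution layers H' = ReLU(D^-1/2 (A + I) D^-1/2 H W) over the
attention-weighted adjacency, mean pooling per graph, then an affine +
sigmoid readout on the concatenation (enhancer embedding, promoter
embedding). Training minimizes binary cross-entropy with Adam; all
randomness derives from a single integer seed, and the parameters with the
best validation Matthews Correlation Coefficient are returned.

The network is implemented directly in NumPy with hand-written gradients:
the model is small and dense, and this keeps inference and training
bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .attention import MockAttentionProvider
from .graph_build import GraphConfig, TokenGraph
from .pipeline import sequence_to_graph
from .tokenization import KmerTokenizer, TokenizerAdapter

__all__ = [
    "LabeledPair",
    "GcnParams",
    "ConfusionCounts",
    "TrainConfig",
    "load_pairs_tsv",
    "write_pairs_tsv",
    "pair_to_graphs",
    "gcn_layer",
    "graph_embedding",
    "predict_pair",
    "train",
    "evaluate",
    "mcc",
]


@dataclass(frozen=True)
class LabeledPair:
    """Two fixed-length sequences with a binary interaction label."""

    seq_a: str
    seq_b: str
    label: int

    def __post_init__(self):
        if not self.seq_a or not self.seq_b:
            raise ValueError("both sequences must be non-empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class GcnParams:
    """All learnable parameters of the pair classifier."""

    embedding: np.ndarray  # (vocab, d)
    W1: np.ndarray  # (d, d)
    W2: np.ndarray  # (d, d)
    w_out: np.ndarray  # (2d,)
    b_out: float

    @property
    def d(self) -> int:
        return self.embedding.shape[1]

    def copy(self) -> "GcnParams":
        return GcnParams(
            embedding=self.embedding.copy(),
            W1=self.W1.copy(),
            W2=self.W2.copy(),
            w_out=self.w_out.copy(),
            b_out=float(self.b_out),
        )

    @classmethod
    def init(cls, vocab_size: int, d: int, rng: np.random.Generator) -> "GcnParams":
        scale = 1.0 / math.sqrt(d)
        return cls(
            embedding=rng.normal(0.0, scale, size=(vocab_size, d)),
            W1=rng.normal(0.0, scale, size=(d, d)),
            W2=rng.normal(0.0, scale, size=(d, d)),
            w_out=rng.normal(0.0, scale, size=(2 * d,)),
            b_out=0.0,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training and graph-construction settings for the classifier.

    Graph construction mirrors the main pipeline: k-mer tokenization,
    deterministic mock attention (or any provider factory), inclusive
    threshold theta. The defaults are modest on purpose — the classifier
    is a straightforward GCN, not a tuned architecture.
    """

    d: int = 32
    lr: float = 1e-3
    epochs: int = 50
    val_fraction: float = 0.25
    k: int = 3
    theta: float = 0.0
    min_degree: int = 0
    attention_seed: int = 0
    L: int = 2
    H: int = 2


def load_pairs_tsv(path) -> list[LabeledPair]:
    """Read a dataset TSV with columns seq_a, seq_b, label (header required)."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["seq_a", "seq_b", "label"]:
            raise ValueError(f"expected header seq_a/seq_b/label, got {header}")
        for line in fh:
            seq_a, seq_b, label = line.rstrip("\n").split("\t")[:3]
            pairs.append(LabeledPair(seq_a=seq_a, seq_b=seq_b, label=int(label)))
    return pairs


def write_pairs_tsv(pairs: list[LabeledPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_a\tseq_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.seq_a}\t{p.seq_b}\t{p.label}\n")


def pair_to_graphs(
    pair: LabeledPair,
    tokenizer: TokenizerAdapter,
    provider,
    config: GraphConfig = GraphConfig(),
) -> tuple[TokenGraph, TokenGraph]:
    """Run both sequences of a pair through the full graph pipeline."""
    graph_a = sequence_to_graph(pair.seq_a, tokenizer, provider, config, reference="seq_a")
    graph_b = sequence_to_graph(pair.seq_b, tokenizer, provider, config, reference="seq_b")
    return graph_a, graph_b


# --- dense graph tensors for the network -----------------------------------

@dataclass(frozen=True)
class _GraphTensors:
    """Compacted view of one graph: token ids plus normalized adjacency.

    The adjacency is kept sparse (CSR): attention graphs are block-diagonal
    per chunk, so long sequences would be wasteful dense.
    """

    ids: np.ndarray  # (m,) int64
    a_hat: sparse.csr_matrix  # (m, m) symmetric-normalized A + I


def _normalized_adjacency(graph: TokenGraph, order: list[int]) -> np.ndarray:
    """Dense D^-1/2 (A + I) D^-1/2; used by the public single-layer op."""
    m = len(order)
    pos = {idx: i for i, idx in enumerate(order)}
    a = np.eye(m)  # unit self-loops
    for (i, j), w in graph.edges.items():
        a[pos[i], pos[j]] = w
        a[pos[j], pos[i]] = w
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _graph_tensors(graph: TokenGraph) -> _GraphTensors:
    if graph.n_nodes == 0:
        raise ValueError("cannot embed an empty graph")
    order = sorted(graph.nodes)
    pos = {idx: i for i, idx in enumerate(order)}
    ids = np.array([graph.nodes[i].token_id for i in order], dtype=np.int64)
    m = len(order)
    rows, cols, vals = [], [], []
    for (i, j), w in graph.edges.items():
        rows += [pos[i], pos[j]]
        cols += [pos[j], pos[i]]
        vals += [w, w]
    rows += list(range(m))
    cols += list(range(m))
    vals += [1.0] * m  # unit self-loops
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    d_inv_sqrt = 1.0 / np.sqrt(np.asarray(a.sum(axis=1)).ravel())
    d = sparse.diags(d_inv_sqrt)
    return _GraphTensors(ids=ids, a_hat=(d @ a @ d).tocsr())


def gcn_layer(H: np.ndarray, graph: TokenGraph, W: np.ndarray) -> np.ndarray:
    """One graph convolution: ReLU(D^-1/2 (A + I) D^-1/2 H W).

    ``A`` is the attention-weighted adjacency with unit self-loops added;
    node rows follow sorted node_index order, compacted to 0..m-1. Isolated
    nodes reduce to ReLU(H_i W).
    """
    order = sorted(graph.nodes)
    if H.shape[0] != len(order):
        raise ValueError(f"H has {H.shape[0]} rows but graph has {len(order)} nodes")
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"feature width {H.shape[1]} does not match W {W.shape}")
    a_hat = _normalized_adjacency(graph, order)
    return np.maximum(a_hat @ H @ W, 0.0)


def _forward_graph(gt: _GraphTensors, params: GcnParams):
    """Two-layer propagation and mean pooling; returns intermediates."""
    x = params.embedding[gt.ids]  # (m, d)
    p1 = gt.a_hat @ x
    h1 = np.maximum(p1 @ params.W1, 0.0)
    p2 = gt.a_hat @ h1
    h2 = np.maximum(p2 @ params.W2, 0.0)
    g = h2.mean(axis=0)
    return x, p1, h1, p2, h2, g


def graph_embedding(graph: TokenGraph, params: GcnParams) -> np.ndarray:
    """d-vector embedding of one graph: mean over final node features."""
    gt = _graph_tensors(graph)
    return _forward_graph(gt, params)[-1]


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def predict_pair(pair_graphs: tuple[TokenGraph, TokenGraph], params: GcnParams) -> float:
    """Interaction probability for an (enhancer, promoter) graph pair.

    Not symmetric in the pair order: the readout sees the concatenation
    (embedding_a, embedding_b).
    """
    ga = graph_embedding(pair_graphs[0], params)
    gb = graph_embedding(pair_graphs[1], params)
    z = float(np.concatenate([ga, gb]) @ params.w_out + params.b_out)
    return _sigmoid(z)


# --- training ---------------------------------------------------------------

class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, values: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        bias1 = 1.0 - self.beta1**self.t
        bias2 = 1.0 - self.beta2**self.t
        for key, grad in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
            values[key] -= self.lr * (self.m[key] / bias1) / (
                np.sqrt(self.v[key] / bias2) + self.eps
            )


def _backward_graph(gt, params, cache, dg, grads):
    """Accumulate parameter gradients for one graph given d(loss)/d(embedding)."""
    x, p1, h1, p2, h2, _ = cache
    m = x.shape[0]
    dh2 = np.broadcast_to(dg / m, h2.shape) * (h2 > 0)
    grads["W2"] += p2.T @ dh2
    dh1 = (gt.a_hat @ dh2) @ params.W2.T * (h1 > 0)
    grads["W1"] += p1.T @ dh1
    dx = (gt.a_hat @ dh1) @ params.W1.T
    np.add.at(grads["embedding"], gt.ids, dx)


def _pair_forward(gta, gtb, params: GcnParams):
    ca = _forward_graph(gta, params)
    cb = _forward_graph(gtb, params)
    z = float(np.concatenate([ca[-1], cb[-1]]) @ params.w_out + params.b_out)
    return ca, cb, z


def evaluate(
    graph_pairs: list[tuple[TokenGraph, TokenGraph]],
    labels: list[int],
    params: GcnParams,
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts of thresholded pair predictions."""
    tp = tn = fp = fn = 0
    for (ga, gb), y in zip(graph_pairs, labels):
        pred = int(predict_pair((ga, gb), params) >= threshold)
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 0 and y == 0:
            tn += 1
        elif pred == 1 and y == 0:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the
    standard convention of returning 0 when any factor under the root is 0.
    """
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def train(
    dataset: list[LabeledPair],
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    provider=None,
    tokenizer: TokenizerAdapter | None = None,
) -> tuple[GcnParams, dict]:
    """Train the pair classifier; returns (best params, training report).

    The dataset is split into train/validation (``val_fraction``) with a
    seed-derived shuffle, graphs are built once up front, and Adam runs
    per-sample updates for ``epochs`` epochs. After each epoch the
    validation MCC is measured; the parameters of the best epoch are
    returned (initial parameters count as epoch 0, so ``epochs=0`` returns
    the untouched initialization).
    """
    labels = {p.label for p in dataset}
    if labels != {0, 1}:
        raise ValueError("training dataset must contain both classes")
    tokenizer = tokenizer or KmerTokenizer(config.k)
    provider = provider or MockAttentionProvider(
        seed=config.attention_seed, L=config.L, H=config.H
    )
    graph_config = GraphConfig(theta=config.theta, min_degree=config.min_degree)

    tensors = []
    ys = []
    for pair in dataset:
        ga, gb = pair_to_graphs(pair, tokenizer, provider, graph_config)
        tensors.append((_graph_tensors(ga), _graph_tensors(gb)))
        ys.append(pair.label)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(config.val_fraction * len(dataset))))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if {ys[i] for i in train_idx} != {0, 1}:
        raise ValueError("train split lost a class; dataset too small or unbalanced")

    params = GcnParams.init(tokenizer.vocab_size, config.d, rng)

    def val_mcc(p: GcnParams) -> float:
        tp = tn = fp = fn = 0
        for i in val_idx:
            gta, gtb = tensors[i]
            _, _, z = _pair_forward(gta, gtb, p)
            pred = int(z >= 0.0)
            y = ys[i]
            tp += pred and y
            tn += (not pred) and (not y)
            fp += pred and (not y)
            fn += (not pred) and y
        return mcc(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))

    best = params.copy()
    best_mcc = val_mcc(params)
    history = [best_mcc]

    shapes = {
        "embedding": params.embedding.shape,
        "W1": params.W1.shape,
        "W2": params.W2.shape,
        "w_out": params.w_out.shape,
        "b_out": (),
    }
    adam = _Adam(shapes, lr=config.lr)
    values = {
        "embedding": params.embedding,
        "W1": params.W1,
        "W2": params.W2,
        "w_out": params.w_out,
        "b_out": np.zeros(()),
    }
    values["b_out"][...] = params.b_out
    d = config.d

    for _epoch in range(config.epochs):
        for i in rng.permutation(train_idx):
            gta, gtb = tensors[i]
            ca, cb, z = _pair_forward(gta, gtb, params)
            p_hat = _sigmoid(z)
            dz = p_hat - ys[i]  # d(BCE)/dz
            grads = {
                "embedding": np.zeros_like(params.embedding),
                "W1": np.zeros_like(params.W1),
                "W2": np.zeros_like(params.W2),
                "w_out": dz * np.concatenate([ca[-1], cb[-1]]),
                "b_out": np.asarray(dz),
            }
            _backward_graph(gta, params, ca, dz * params.w_out[:d], grads)
            _backward_graph(gtb, params, cb, dz * params.w_out[d:], grads)
            adam.step(values, grads)
            params.b_out = float(values["b_out"])
        epoch_mcc = val_mcc(params)
        history.append(epoch_mcc)
        if epoch_mcc > best_mcc:
            best_mcc = epoch_mcc
            best = params.copy()

    report = {
        "best_val_mcc": best_mcc,
        "history": history,
        "n_train": len(train_idx),
        "n_val": len(val_idx),
    }
    return best, report


def save_params(params: GcnParams, path) -> None:
    np.savez(
        path,
        embedding=params.embedding,
        W1=params.W1,
        W2=params.W2,
        w_out=params.w_out,
        b_out=np.asarray(params.b_out),
    )


def load_params(path) -> GcnParams:
    data = np.load(path)
    return GcnParams(
        embedding=data["embedding"],
        W1=data["W1"],
        W2=data["W2"],
        w_out=data["w_out"],
        b_out=float(data["b_out"]),
    )
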