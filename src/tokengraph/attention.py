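"""Attention extraction and reduction to a single token-token matrix.

A provider yields a raw tensor of shape (layers, heads, tokens, tokens) for
one chunk. Each (layer, head) slice is row-softmaxed into probabilities and
the slices are arithmetically averaged, giving one row-stochastic matrix
whose entry a_ij is the attention-derived strength from token i to token j.
Providers that already emit probabilities can skip the softmax with
``renormalize=False``.

The in-package :class:`MockAttentionProvider` is a deterministic stand-in
for a pre-trained genomic language model: scores are computed with a
splitmix64 hash of (seed, layer, head, token_id_i, token_id_j), so the same
inputs always give bit-identical tensors and repeated tokens produce
structured, non-uniform graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionTensor",
    "AttentionMatrix",
    "MockAttentionProvider",
    "raw_attention",
    "normalize_rows",
    "aggregate",
    "mock_attention",
]

ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class AttentionTensor:
    """Raw per-layer-per-head scores, shape (L, H, m, m)."""

    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 4:
            raise ValueError(f"attention tensor must be 4-D, got shape {v.shape}")
        if min(v.shape) < 1:
            raise ValueError(f"all tensor dimensions must be positive: {v.shape}")
        if v.shape[2] != v.shape[3]:
            raise ValueError(f"trailing dimensions must be equal: {v.shape}")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_heads(self) -> int:
        return self.values.shape[1]

    @property
    def token_count(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class AttentionMatrix:
    """Normalized, layer/head-averaged scores; each row sums to 1."""

    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"attention matrix must be square, got {v.shape}")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("attention matrix entries must lie in [0, 1]")
        if np.max(np.abs(v.sum(axis=1) - 1.0)) > ROW_SUM_TOL:
            raise ValueError("attention matrix rows must sum to 1")

    @property
    def token_count(self) -> int:
        return self.values.shape[0]


def normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety.

    out_ij = exp(in_ij) / sum_k exp(in_ik). Shift-invariant per row, so the
    stabilisation does not change the result.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("attention scores must be finite")
    shifted = matrix - matrix.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=-1, keepdims=True)


def aggregate(tensor: AttentionTensor, renormalize: bool = True) -> AttentionMatrix:
    """Average row-stochastic slices over all layers and heads.

    Each (layer, head) slice is softmax-normalized (unless ``renormalize``
    is False, for providers that already emit probabilities), then all L*H
    slices are averaged with equal weight. A mean of row-stochastic
    matrices is row-stochastic, so the output rows sum to 1.
    """
    values = tensor.values
    if renormalize:
        values = normalize_rows(values)
    mean = values.mean(axis=(0, 1))
    # guard against providers that claim probabilities but are not
    mean = np.clip(mean, 0.0, 1.0)
    return AttentionMatrix(values=mean)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer; uint64 in, well-mixed uint64 out."""
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def mock_attention(
    token_ids: list[int], seed: int, L: int = 2, H: int = 2
) -> AttentionTensor:
    """Deterministic pseudo-attention for offline pipelines and tests.

    Entry (l, h, i, j) is a uniform [0, 1) score derived by hashing
    (seed, l, h, token_ids[i], token_ids[j]) with splitmix64: bit-identical
    across runs and platforms, and dependent on token identity so repeated
    tokens yield repeated scores.
    """
    if len(token_ids) == 0:
        raise ValueError("token list must be non-empty")
    if L < 1 or H < 1:
        raise ValueError("L and H must be >= 1")
    ids = np.asarray(token_ids, dtype=np.uint64)
    m = ids.shape[0]
    row = _splitmix64(ids * np.uint64(0xC2B2AE3D27D4EB4F))
    col = _splitmix64(ids * np.uint64(0x165667B19E3779F9))
    pair = row[:, None] ^ col[None, :]  # (m, m), token-identity dependent
    layers = np.arange(L, dtype=np.uint64)
    heads = np.arange(H, dtype=np.uint64)
    slice_key = _splitmix64(
        np.uint64(seed)
        ^ (layers[:, None] * np.uint64(0x9E3779B97F4A7C15))
        ^ (heads[None, :] * np.uint64(0xD6E8FEB86659FD93))
    )
    mixed = _splitmix64(slice_key[:, :, None, None] ^ pair[None, None, :, :])
    values = mixed.astype(np.float64) * (2.0**-64)
    return AttentionTensor(values=values.reshape(L, H, m, m))


class MockAttentionProvider:
    """Offline attention provider with the plugin contract (ids -> tensor)."""

    def __init__(self, seed: int = 0, L: int = 2, H: int = 2, max_tokens: int = 512):
        self.seed = seed
        self.L = L
        self.H = H
        self.max_tokens = max_tokens
        self.name = f"mock(seed={seed},L={L},H={H})"
        self.emits_probabilities = False

    def attention(self, token_ids: list[int]) -> AttentionTensor:
        return mock_attention(token_ids, seed=self.seed, L=self.L, H=self.H)


class HubAttentionProvider:
    """Attention from a pre-trained transformer model (optional dependency).

    Returns the model's per-layer per-head attention for the given token
    ids, with any special tokens excluded by the caller before this point.
    Real attention is already softmaxed, so ``emits_probabilities`` is True
    and aggregation should be run with ``renormalize=False`` unless the
    literal renormalizing pipeline is wanted. Not exercised by the default
    test suite.
    """

    def __init__(self, model_name: str, max_tokens: int = 512):
        import torch  # optional dependency
        from transformers import AutoModel

        self._torch = torch
        self._model = AutoModel.from_pretrained(
            model_name, trust_remote_code=True, output_attentions=True
        )
        self._model.eval()
        self.max_tokens = max_tokens
        self.name = model_name
        self.emits_probabilities = True

    def attention(self, token_ids: list[int]) -> AttentionTensor:
        torch = self._torch
        with torch.no_grad():
            ids = torch.tensor([list(token_ids)], dtype=torch.long)
            out = self._model(input_ids=ids)
        stacked = torch.cat([a for a in out.attentions], dim=0)  # (L, H, m, m)
        return AttentionTensor(values=stacked.numpy().astype(np.float64))


def raw_attention(provider, token_ids: list[int]) -> AttentionTensor:
    """Fetch the (L, H, m, m) attention tensor for one chunk's token ids."""
    if len(token_ids) == 0:
        raise ValueError("token list must be non-empty")
    max_tokens = getattr(provider, "max_tokens", None)
    if max_tokens is not None and len(token_ids) > max_tokens:
        raise ValueError(
            f"{len(token_ids)} tokens exceed provider capacity {max_tokens}"
        )
    tensor = provider.attention(token_ids)
    if tensor.token_count != len(token_ids):
        raise ValueError("provider returned a tensor misaligned with token order")
    return tensor
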