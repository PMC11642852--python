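"""Tokenizer adapters and genome-wide offset translation.

A tokenizer adapter turns a cleaned {A,C,G,T} string into tokens with
chunk-local offset mappings; :func:`globalize_offsets` then lifts those
offsets to genome-wide coordinates through the chunk's coordinate map, so a
token knows exactly which stretch of the reference it came from even when
invalid characters were removed inside its span.

Two deterministic offline adapters ship in-package: non-overlapping k-mer
tokenization (the Nucleotide Transformer style) and a toy byte-pair-encoding
tokenizer with a fixed merge table (the DNABERT-2 style, miniaturized). Any
pre-trained tokenizer that supports offset mappings can be plugged in via
:func:`load_hub_tokenizer` when the optional ``transformers`` dependency is
installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .sequence_io import CleanedChunk

__all__ = [
    "TokenizerAdapter",
    "TokenNode",
    "KmerTokenizer",
    "ToyBpeTokenizer",
    "load_hub_tokenizer",
    "make_tokenizer",
    "tokenize_chunk",
    "globalize_offsets",
]


@runtime_checkable
class TokenizerAdapter(Protocol):
    """Minimal contract a tokenizer must satisfy.

    ``tokenize_with_offsets`` must return tokens whose (start, end) offsets
    are sorted, non-overlapping half-open intervals into the input string,
    excluding any special tokens.
    """

    name: str
    vocab_size: int
    n_special_tokens: int
    mode: str

    def tokenize_with_offsets(self, sequence: str) -> list[tuple[int, str, int, int]]:
        """Return ``(token_id, token_string, local_start, local_end)`` tuples."""
        ...


@dataclass(frozen=True)
class TokenNode:
    """A graph node: one token anchored to a genomic interval.

    ``end - start`` can exceed ``len(token_string)`` when cleaning removed
    characters inside the token's span; the interval endpoints are always
    genome-true.
    """

    token_id: int
    token_string: str
    reference: str
    start: int
    end: int
    node_index: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("token interval must be non-empty (start < end)")


class KmerTokenizer:
    """Non-overlapping k-mer tokenizer over the {A,C,G,T} alphabet.

    Token ids are the base-4 rank of the k-mer (A=0, C=1, G=2, T=3), so the
    vocabulary is the 4**k possible k-mers. A trailing remainder shorter
    than k is dropped.
    """

    _BASE = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(self, k: int, n_special_tokens: int = 0):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.name = f"kmer:{k}"
        self.vocab_size = 4**k
        self.n_special_tokens = n_special_tokens
        self.mode = "kmer"

    def token_id(self, kmer: str) -> int:
        value = 0
        for char in kmer:
            value = value * 4 + self._BASE[char]
        return value

    def tokenize_with_offsets(self, sequence: str) -> list[tuple[int, str, int, int]]:
        k = self.k
        out = []
        for start in range(0, len(sequence) - k + 1, k):
            kmer = sequence[start : start + k]
            out.append((self.token_id(kmer), kmer, start, start + k))
        return out


class ToyBpeTokenizer:
    """Byte-pair-encoding tokenizer with a small fixed merge table.

    Greedy BPE: starting from single bases, merge the highest-priority
    adjacent pair repeatedly until no merge applies. The merge table is
    fixed so tokenization is deterministic and self-contained; it produces
    variable-length tokens the way a trained DNA BPE vocabulary does.
    """

    _MERGES: list[tuple[str, str]] = [
        ("A", "C"), ("G", "T"), ("T", "A"), ("C", "G"),
        ("AC", "GT"), ("TA", "CG"), ("G", "A"), ("C", "T"),
        ("GA", "CT"), ("ACGT", "ACGT"),
    ]

    def __init__(self, n_special_tokens: int = 0):
        self.name = "toy-bpe"
        vocab = ["A", "C", "G", "T"]
        for left, right in self._MERGES:
            vocab.append(left + right)
        self._vocab_index = {tok: i for i, tok in enumerate(vocab)}
        self._rank = {pair: r for r, pair in enumerate(self._MERGES)}
        self.vocab_size = len(vocab)
        self.n_special_tokens = n_special_tokens
        self.mode = "bpe"

    def tokenize_with_offsets(self, sequence: str) -> list[tuple[int, str, int, int]]:
        if not sequence:
            return []
        pieces = list(sequence)
        spans = [(i, i + 1) for i in range(len(sequence))]
        while True:
            best_rank, best_at = None, None
            for i in range(len(pieces) - 1):
                rank = self._rank.get((pieces[i], pieces[i + 1]))
                if rank is not None and (best_rank is None or rank < best_rank):
                    best_rank, best_at = rank, i
            if best_at is None:
                break
            i = best_at
            pieces[i : i + 2] = [pieces[i] + pieces[i + 1]]
            spans[i : i + 2] = [(spans[i][0], spans[i + 1][1])]
        return [
            (self._vocab_index[piece], piece, start, end)
            for piece, (start, end) in zip(pieces, spans)
        ]


class HubTokenizer:
    """Adapter around a Hugging Face fast tokenizer with offset mappings.

    Network/weights-dependent; not exercised by the default test suite.
    """

    def __init__(self, model_name: str):
        from transformers import AutoTokenizer  # optional dependency

        self._tok = AutoTokenizer.from_pretrained(model_name, trust_remote_code=True)
        self.name = model_name
        self.vocab_size = self._tok.vocab_size
        self.n_special_tokens = self._tok.num_special_tokens_to_add()
        self.mode = "bpe"

    def tokenize_with_offsets(self, sequence: str) -> list[tuple[int, str, int, int]]:
        enc = self._tok(sequence, return_offsets_mapping=True, add_special_tokens=False)
        out = []
        for token_id, (start, end) in zip(enc["input_ids"], enc["offset_mapping"]):
            if end > start:  # special tokens map to empty offsets
                out.append((token_id, sequence[start:end], start, end))
        return out


def load_hub_tokenizer(model_name: str) -> HubTokenizer:
    try:
        return HubTokenizer(model_name)
    except ImportError as exc:
        raise ImportError(
            "loading a hub tokenizer requires the optional 'transformers' "
            "dependency (pip install tokengraph[hub])"
        ) from exc


def make_tokenizer(spec: str) -> TokenizerAdapter:
    """Build a tokenizer from a CLI-style spec string.

    ``kmer:K`` and ``toy-bpe`` are offline built-ins; any other string is
    treated as a hub model name.
    """
    if spec.startswith("kmer:"):
        return KmerTokenizer(int(spec.split(":", 1)[1]))
    if spec in ("toy-bpe", "bpe"):
        return ToyBpeTokenizer()
    return load_hub_tokenizer(spec)


def tokenize_chunk(
    chunk: CleanedChunk, tokenizer: TokenizerAdapter
) -> list[tuple[int, str, int, int]]:
    """Tokenize a cleaned chunk, returning chunk-local offset mappings.

    Offsets index into ``chunk.cleaned_sequence``; special tokens are never
    included. An empty cleaned chunk yields an empty token list.
    """
    if not chunk.cleaned_sequence:
        return []
    tokens = tokenizer.tokenize_with_offsets(chunk.cleaned_sequence)
    for token_id, token_string, start, end in tokens:
        if chunk.cleaned_sequence[start:end] != token_string:
            raise ValueError(
                f"tokenizer {tokenizer.name!r} returned inconsistent offsets for "
                f"token {token_string!r} at [{start}, {end})"
            )
    return tokens


def globalize_offsets(
    tokens: list[tuple[int, str, int, int]],
    chunk: CleanedChunk,
    node_index_start: int = 0,
) -> list[TokenNode]:
    """Translate chunk-local token offsets to genome-wide coordinates.

    ``start`` is the genomic coordinate of the token's first base and
    ``end`` one past its last base, both read through the chunk's coordinate
    map so that characters removed by cleaning are counted. ``node_index``
    numbering continues across chunks of one reference via
    ``node_index_start``.
    """
    n = len(chunk.coord_map)
    nodes = []
    for offset, (token_id, token_string, local_start, local_end) in enumerate(tokens):
        if not (0 <= local_start < local_end <= n):
            raise ValueError(
                f"token offsets [{local_start}, {local_end}) out of range for "
                f"cleaned chunk of length {n}"
            )
        nodes.append(
            TokenNode(
                token_id=token_id,
                token_string=token_string,
                reference=chunk.reference,
                start=int(chunk.coord_map[local_start]),
                end=int(chunk.coord_map[local_end - 1]) + 1,
                node_index=node_index_start + offset,
            )
        )
    return nodes
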