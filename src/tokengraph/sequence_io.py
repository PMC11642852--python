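"""Random-access FASTA handling, chunking and nucleotide cleaning.

Large genomes are never loaded whole: references are enumerated from the
``.fai`` index and segments are fetched on demand through ``pysam``. A
reference is processed as a stream of fixed-size chunks sized to a language
model's token budget; each chunk is cleaned to the {A,C,G,T} alphabet while
preserving a map from cleaned indices back to original genomic coordinates,
because removed characters still occupy genomic positions.

Coordinates are 0-based, half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

__all__ = [
    "GenomeSource",
    "SequenceChunk",
    "CleanedChunk",
    "open_genome",
    "compute_chunk_length",
    "iter_chunks",
    "clean_chunk",
    "fetch_segment",
]

# byte values of the four valid nucleotides (uppercase)
_VALID_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSource:
    """An indexed FASTA file with named references of known length."""

    path: str
    references: list[tuple[str, int]]
    _handle: pysam.FastaFile | None = field(default=None, repr=False)

    @property
    def reference_names(self) -> list[str]:
        return [name for name, _ in self.references]

    def length_of(self, reference: str) -> int:
        for name, length in self.references:
            if name == reference:
                return length
        raise KeyError(f"unknown reference {reference!r}")

    def close(self) -> None:
        if self._handle is not None:
            self._handle.close()
            self._handle = None

    def __enter__(self) -> "GenomeSource":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


@dataclass(frozen=True)
class SequenceChunk:
    """A raw (uncleaned) slice of one reference."""

    reference: str
    start: int
    raw_sequence: str

    @property
    def length(self) -> int:
        return len(self.raw_sequence)


@dataclass(frozen=True)
class CleanedChunk:
    """A chunk reduced to {A,C,G,T}, with per-base original coordinates.

    ``coord_map[k]`` is the 0-based genomic coordinate of the k-th retained
    character; characters removed by cleaning are skipped in the map but
    still counted, so coordinates stay genome-true.
    """

    reference: str
    start: int
    cleaned_sequence: str
    coord_map: np.ndarray  # int64, strictly increasing

    def __post_init__(self):
        if len(self.coord_map) != len(self.cleaned_sequence):
            raise ValueError("coord_map length must equal cleaned_sequence length")


def open_genome(path: str | os.PathLike) -> GenomeSource:
    """Open a FASTA file for random access, building a ``.fai`` if absent.

    Returns a :class:`GenomeSource` listing every reference with its length.
    The sequence data itself is not loaded. An empty file yields an empty
    reference list; duplicate record names are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    # A FASTA with no records is legal but indexers reject it; short-circuit.
    with open(path, "rb") as fh:
        head = fh.read(1)
    if head == b"":
        return GenomeSource(path=path, references=[])
    # the faidx indexer silently drops duplicate records, so enforce name
    # uniqueness with a streaming header scan
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].strip() else ""
                if name in seen:
                    raise ValueError(f"duplicate reference name in FASTA: {name!r}")
                seen.add(name)
    try:
        handle = pysam.FastaFile(path)
    except Exception as exc:  # pysam raises OSError/ValueError on bad input
        raise ValueError(f"malformed or unindexable FASTA {path!r}: {exc}") from exc
    names = list(handle.references)
    refs = [(name, handle.get_reference_length(name)) for name in names]
    return GenomeSource(path=path, references=refs, _handle=handle)


def compute_chunk_length(model_max_tokens: int, n_special_tokens: int) -> int:
    """Nucleotides per chunk for a model with the given token budget.

    Every token covers at least one nucleotide, so a chunk of
    ``model_max_tokens - n_special_tokens`` bases can never exceed the
    model's input limit regardless of tokenizer.
    """
    if n_special_tokens < 0:
        raise ValueError("n_special_tokens must be >= 0")
    if model_max_tokens <= n_special_tokens:
        raise ValueError(
            f"model_max_tokens ({model_max_tokens}) must exceed "
            f"n_special_tokens ({n_special_tokens})"
        )
    return model_max_tokens - n_special_tokens


def iter_chunks(genome: GenomeSource, reference: str, chunk_length: int):
    """Yield consecutive :class:`SequenceChunk` tiles covering a reference.

    Produces ``ceil(L / chunk_length)`` chunks; all have ``chunk_length``
    bases except possibly the last, and their concatenation reproduces the
    reference exactly.
    """
    if chunk_length < 1:
        raise ValueError("chunk_length must be >= 1")
    length = genome.length_of(reference)
    for start in range(0, length, chunk_length):
        end = min(start + chunk_length, length)
        yield SequenceChunk(
            reference=reference,
            start=start,
            raw_sequence=fetch_segment(genome, reference, start, end),
        )


def clean_chunk(chunk: SequenceChunk) -> CleanedChunk:
    """Uppercase a chunk and drop every character outside {A,C,G,T}.

    Removed characters still occupy genomic coordinates, so the returned
    ``coord_map`` records, for each retained base, its position in the
    original reference.
    """
    raw = np.frombuffer(chunk.raw_sequence.upper().encode("ascii"), dtype=np.uint8)
    keep = np.isin(raw, _VALID_BYTES)
    coord_map = chunk.start + np.flatnonzero(keep).astype(np.int64)
    cleaned = raw[keep].tobytes().decode("ascii")
    return CleanedChunk(
        reference=chunk.reference,
        start=chunk.start,
        cleaned_sequence=cleaned,
        coord_map=coord_map,
    )


def fetch_segment(genome: GenomeSource, reference: str, start: int, end: int) -> str:
    """Return the raw subsequence ``[start, end)`` of a reference."""
    length = genome.length_of(reference)
    if not (0 <= start <= end <= length):
        raise IndexError(
            f"segment [{start}, {end}) out of range for reference "
            f"{reference!r} of length {length}"
        )
    if start == end:
        return ""
    if genome._handle is None:
        genome._handle = pysam.FastaFile(genome.path)
    return genome._handle.fetch(reference, start, end)
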