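"""Deterministic generators for every input the pipeline consumes.

Everything here is a pure function of its spec (including the seed): reruns
are byte-identical, so fixtures never need to be stored. Randomness comes
from ``numpy.random.default_rng(seed)`` (PCG64) drawn in a fixed order —
the scheme is part of the interface and stable across releases.

Two generators are provided: a multi-record FASTA emulating a reference
genome (with soft-masked lowercase and invalid/ambiguous characters at
configurable rates, plus a per-position truth table for coordinate tests),
and a labeled sequence-pair dataset for the interaction classifier whose
class signal is a plantable motif co-occurrence: positives carry motif_a in
the first sequence AND motif_b in the second, negatives at most one of the
two.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .classify import LabeledPair, write_pairs_tsv

__all__ = [
    "SynthGenomeSpec",
    "SynthEpiSpec",
    "synth_genome",
    "synth_epi_dataset",
    "make_epi_pairs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# N plus the IUPAC ambiguity codes
_INVALID = np.frombuffer(b"NRYSWKMBDHV", dtype=np.uint8)
_FASTA_WIDTH = 60


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Recipe for a synthetic multi-record FASTA."""

    lengths: tuple[int, ...] = (1000,)
    invalid_char_rate: float = 0.0
    lowercase_rate: float = 0.0
    seed: int = 0
    name_prefix: str = "chr_t"

    def __post_init__(self):
        if any(length <= 0 for length in self.lengths):
            raise ValueError("reference lengths must be positive")
        if not (0.0 <= self.invalid_char_rate < 1.0):
            raise ValueError("invalid_char_rate must be in [0, 1)")
        if not (0.0 <= self.lowercase_rate < 1.0):
            raise ValueError("lowercase_rate must be in [0, 1)")

    @property
    def n_references(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class SynthEpiSpec:
    """Recipe for a labeled enhancer-promoter-style pair dataset.

    Sequence length defaults to 5,000 nt, the scale of the interaction
    benchmark this emulates; tests use shorter sequences for speed.
    """

    n_pairs: int = 200
    seq_length: int = 5000
    motif_a: str = "ACGACGACGACG"
    motif_b: str = "TGCTGCTGCTGC"
    copies: int = 8
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for motif in (self.motif_a, self.motif_b):
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"motif must be non-empty over ACGT: {motif!r}")
            if len(motif) > self.seq_length:
                raise ValueError("motif longer than seq_length")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


def _render_reference(spec: SynthGenomeSpec, rng: np.random.Generator, length: int) -> bytes:
    seq = _BASES[rng.integers(0, 4, size=length)]
    if spec.invalid_char_rate > 0:
        mask = rng.random(length) < spec.invalid_char_rate
        seq[mask] = _INVALID[rng.integers(0, len(_INVALID), size=int(mask.sum()))]
    if spec.lowercase_rate > 0:
        mask = rng.random(length) < spec.lowercase_rate
        seq[mask] += 32  # ASCII lowercase
    return seq.tobytes()


def synth_genome(spec: SynthGenomeSpec, path: str | os.PathLike) -> list[tuple[str, str]]:
    """Write a synthetic FASTA plus a per-position truth TSV sidecar.

    The sidecar ``<path>.truth.tsv`` lists (reference, position,
    original_char) for every base, so coordinate-preservation can be
    checked against independent ground truth. Returns the (name, sequence)
    records as written.
    """
    path = os.fspath(path)
    rng = np.random.default_rng(spec.seed)
    records = []
    for ref_index, length in enumerate(spec.lengths, start=1):
        name = f"{spec.name_prefix}{ref_index}"
        records.append((name, _render_reference(spec, rng, length).decode("ascii")))
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")
    with open(path + ".truth.tsv", "w") as fh:
        fh.write("reference\tposition\toriginal_char\n")
        for name, seq in records:
            for pos, char in enumerate(seq):
                fh.write(f"{name}\t{pos}\t{char}\n")
    return records


def _plant(seq: np.ndarray, motif: str, rng: np.random.Generator) -> None:
    start = int(rng.integers(0, len(seq) - len(motif) + 1))
    seq[start : start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_epi_pairs(spec: SynthEpiSpec) -> list[LabeledPair]:
    """Generate labeled pairs with a motif co-occurrence class signal.

    Positive pairs carry ``copies`` plants of motif_a at random positions
    of seq_a and of motif_b in seq_b. Negative pairs carry at most one of
    the two motifs (one of: motif_a only, motif_b only, neither — chosen
    uniformly), so the label is the co-occurrence, not mere motif
    presence. The default motifs are short tandem repeats: their k-mer
    signature is invariant to tokenization frame, the way clustered
    binding sites are robust to where a tokenizer cuts. The label sequence
    is a deterministic seed-derived shuffle.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_pairs * spec.positive_fraction))
    labels = np.zeros(spec.n_pairs, dtype=np.int64)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    pairs = []
    for label in labels:
        seq_a = _random_seq(rng, spec.seq_length)
        seq_b = _random_seq(rng, spec.seq_length)
        if label == 1:
            for _ in range(spec.copies):
                _plant(seq_a, spec.motif_a, rng)
            for _ in range(spec.copies):
                _plant(seq_b, spec.motif_b, rng)
        else:
            mode = int(rng.integers(0, 3))
            if mode == 0:
                for _ in range(spec.copies):
                    _plant(seq_a, spec.motif_a, rng)
            elif mode == 1:
                for _ in range(spec.copies):
                    _plant(seq_b, spec.motif_b, rng)
        pairs.append(
            LabeledPair(
                seq_a=seq_a.tobytes().decode("ascii"),
                seq_b=seq_b.tobytes().decode("ascii"),
                label=int(label),
            )
        )
    return pairs


def synth_epi_dataset(spec: SynthEpiSpec, path: str | os.PathLike) -> list[LabeledPair]:
    """Write the pair dataset as TSV (seq_a, seq_b, label); returns the pairs."""
    pairs = make_epi_pairs(spec)
    write_pairs_tsv(pairs, os.fspath(path))
    return pairs
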