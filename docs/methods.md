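# Methods

## Pipeline model

`tokengraph` converts a genomic sequence into a weighted undirected graph
in five stages.

**Chunking.** A reference of length *L* is tiled into
⌈*L*/*c*⌉ consecutive chunks of *c* = `model_max_tokens − n_special_tokens`
nucleotides (the last chunk may be shorter). Because every token covers at
least one nucleotide, this guarantees any tokenizer's output fits the
model's input budget, at the cost of some slack for multi-character BPE
tokens. References are read through an indexed FASTA (pysam), so no full
genome is ever held in memory; coordinates are 0-based half-open
throughout, matching the indexed-FASTA/BED convention.

**Cleaning.** Chunks are uppercased, then every character outside
{A, C, G, T} is removed. Removed characters still occupy genomic
coordinates: cleaning produces a strictly increasing `coord_map` from
cleaned index to original coordinate, and all downstream positions are
read through it. N and the IUPAC ambiguity codes are treated uniformly
(all removed); soft-masked lowercase bases are uppercased and retained,
since case marks repeats, not invalidity.

**Tokenization.** A tokenizer adapter returns tokens with offset mappings
into the cleaned chunk; special tokens are excluded, since a class or
separator marker occupies no genomic position and cannot be a node. Token
offsets are lifted to genome-wide intervals through `coord_map`: a token
whose span contains removed characters gets an interval wider than its
string, keeping the endpoints genome-true. Built-in offline adapters: a
non-overlapping k-mer tokenizer (ids are the base-4 rank, vocabulary 4^k;
a trailing remainder shorter than k is dropped) and a toy BPE with a fixed
merge table. Hub tokenizers with offset-mapping support plug in through
the optional `transformers` extra; they are network-dependent and not part
of the test suite.

**Attention aggregation.** A provider maps a chunk's token ids to an
(L, H, m, m) score tensor. Each (layer, head) slice is row-softmaxed
(max-subtracted for overflow safety) and the L·H slices are averaged with
equal weight; a mean of row-stochastic matrices is row-stochastic, so each
output row sums to 1 within 1e−6. Softmax is applied per row because the
aggregate entry a_ij is read as the attention-derived probability from
token i to token j. Providers that already emit probabilities (real
transformer attention is softmaxed) can skip renormalization with
`renormalize=False` / `--no-renormalize`; the renormalizing default is the
pipeline's literal definition. Attention never crosses chunk boundaries —
the model only ever sees one chunk.

**Graph construction and filtering.** Only the upper triangle is
consulted: for i < j an edge with weight a_ij is created iff a_ij ≥ θ
(inclusive); a_ji is discarded, not averaged in. Chunk graphs of one
reference are unioned (node numbering continues across chunks, so the
union is disjoint), then the degree filter removes every node whose
degree is below `min_degree` in a single pass — survivors may end up
with fewer neighbors than the threshold afterwards. The single pass is
the default because the two filters (θ on edges, degree on nodes) are
deliberately orthogonal; `kcore=True` iterates the pass to the classical
k-core fixed point for users who want guaranteed post-filter degrees.
Since no cross-chunk edges exist, filtering after the union equals
filtering each chunk graph (asserted as a test). Degree-0 nodes are kept
by construction and only removed when `min_degree ≥ 1`.

## Mock attention provider

The offline stand-in for a pre-trained gLM hashes
(seed, layer, head, token_id_i, token_id_j) with the splitmix64 finalizer
and maps the 64-bit result to a uniform [0, 1) score. It is bit-identical
across runs and platforms, vectorized in uint64, and depends on token
identity only — repeated tokens produce repeated score patterns, so graphs
have reproducible structure rather than i.i.d. noise. It does not emulate
locality or biological attention patterns; it exists so that every
downstream contract (shape, determinism, normalization, thresholding,
serialization, training) is testable without model weights.

## Serving

The exploration backend is a WSGI JSON API (stdlib `wsgiref`): `/graph`
serves the node-link payload with optional server-side `?theta=`
re-filtering (equivalent to rebuilding at that θ before degree filtering:
edges only shrink, nodes unchanged), `/node/<i>/context?flank=N` returns
the genomic window around a node (default flank 50 nt, clamped to the
reference) with the graph neighbors intersecting it, and
`/search?reference=R&position=P` resolves a position to the covering
node. Front-end rendering is out of scope.

## Pair classifier

Each sequence of a labeled pair runs through the full pipeline as its own
single-reference genome. The classifier is a fixed small architecture:
token-id embedding (d = 32), two graph convolutions
H′ = ReLU(D̃^{−1/2}(A+I)D̃^{−1/2} H W) over the attention-weighted
adjacency with unit self-loops, mean pooling, and an affine + sigmoid
readout on the concatenated (first, second) embeddings — not symmetric in
the pair order, matching the (enhancer, promoter) framing. Weighted (not
binarized) adjacency is used because the attention weight is the
pipeline's core signal. Training minimizes binary cross-entropy with
per-sample Adam steps (lr 1e−3, 50 epochs by default), a seed-derived
25% validation split, and returns the parameters of the best
validation-MCC epoch (epoch 0 = the initialization, so zero epochs is a
no-op). All randomness — split, init, shuffling — derives from one
integer seed; repeated runs are bit-reproducible. MCC uses the standard
zero-denominator convention (return 0).

The network is plain NumPy with hand-written gradients; the normalized
adjacency is stored sparse (CSR), since attention graphs are
block-diagonal per chunk and long sequences would be wasteful dense —
a 5,000-nt pair peaks around 130 MB instead of gigabytes. With ~100
nodes per 300-nt graph, training 200 pairs for 50 epochs takes a few
seconds per seed on one CPU; problem
sizes in the tests (200 pairs × 300 nt) were chosen to exercise the full
pipeline at that comfortable scale while keeping the 5,000-nt default of
the data generator at the interaction benchmark's sequence length.

## Synthetic data

**Genomes.** `synth_genome` writes multi-record FASTA with configurable
per-reference lengths, invalid-character rate (N plus IUPAC ambiguity
codes) and soft-mask (lowercase) rate, plus a per-position truth TSV for
coordinate tests. All draws come from `numpy.random.default_rng(seed)`
(PCG64) in a fixed order, so outputs are byte-identical across reruns;
the drawing scheme is part of the interface. The generator does not model
GC content, repeats or chromosome-scale structure — passing tests show
coordinate and pipeline correctness, not biological realism.

**Interaction pairs.** `make_epi_pairs` emits labeled pairs whose class
signal is motif co-occurrence: positives carry `copies` plants of motif_a
in seq_a AND motif_b in seq_b; negatives carry at most one side's motif
(a-only / b-only / neither, uniform), so the label is the co-occurrence,
not motif presence. Defaults: tandem-repeat motifs (`ACG`×4, `TGC`×4) and
copies = 8. Both defaults come from a margin analysis rather than
biological modeling: a tandem repeat's k-mer signature is invariant to
tokenization frame (any phase of the plant yields tokens from the same
three-element set, as clustered binding sites are robust to where a
tokenizer cuts), and at 8 copies in 300 nt the signature-count
distributions of background and planted sequences are disjoint in their
extreme tails (measured background max ≈ 13 vs planted min ≈ 17 per
3,000/2,000 draws), making the dataset separable by construction. A
single short plant demonstrably is not separable at this scale (a
logistic-regression oracle on k-mer counts stays near chance), which
would make end-to-end learning tests meaningless. Pair-level AND over
noisy per-sequence signals is what makes the task non-trivial for the
linear pair readout: the GCN's per-node ReLUs acting on the
complete-graph average provide the per-sequence squashing that the
readout then combines.

## Numerical choices

- Softmax: row-max subtraction; shift-invariance holds to 1e−9.
- Row-sum conservation after aggregation: asserted at 1e−6.
- Edge threshold: inclusive (≥ θ); ties are exercised in tests by drawing
  θ from the matrix entries themselves.
- Serialization: floats are written with `repr` (TSV) / native JSON /
  GraphML typed attributes, so round-trips are exact, not approximate.
- Empty inputs: empty FASTA → empty reference list; all-invalid chunk →
  empty cleaned chunk → no tokens (not an error); empty chunk list →
  empty reference graph; empty graph serializes and round-trips.
- Degenerate MCC tables (any zero marginal) return 0.

## Known limitations

- The mock provider's attention is structured noise; graph topology under
  it validates mechanics, not biology. Conclusions about real regulatory
  structure require a real gLM through the hub adapters.
- The hub adapters (tokenizer and attention) are import-guarded and
  untested here; they require network access and model weights.
- The toy BPE merge table is fixed and tiny; it exercises variable-length
  offsets, not a trained vocabulary.
- Benchmark-scale interaction results on public cell-line datasets are
  out of scope: they need external data and pre-trained model weights.
- Cross-reference (interchromosomal) edges are not built; a merged FASTA
  record is the supported workaround.
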