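"""Train the GCN pair classifier on the synthetic interaction dataset.

Generates 200 labeled sequence pairs whose positive class is a planted
motif co-occurrence, converts every sequence to a token graph, trains the
two-layer GCN with a seed-fixed run, and reports the validation Matthews
Correlation Coefficient.
"""

from tokengraph import SynthEpiSpec, TrainConfig, make_epi_pairs, train

pairs = make_epi_pairs(SynthEpiSpec(n_pairs=200, seq_length=300, seed=11))
n_pos = sum(p.label for p in pairs)
print(f"dataset: {len(pairs)} pairs ({n_pos} positive), {len(pairs[0].seq_a)} nt each")

params, report = train(pairs, TrainConfig(epochs=50, theta=0.0), seed=1)
print(f"train/validation split: {report['n_train']}/{report['n_val']}")
print(f"best validation MCC: {report['best_val_mcc']:.3f}")
print(f"validation MCC by epoch (first 10): "
      f"{[round(x, 2) for x in report['history'][:10]]}")
# MCC is in [-1, 1]: 1 is perfect agreement, 0 is chance. The planted
# co-occurrence signal is separable by construction, so a trained model
# should approach 1 on held-out pairs.
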