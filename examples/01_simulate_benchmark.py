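"""Simulate a two-species spike-in benchmark and write it to disk.

Builds the default dataset — 1000 human + 200 E. coli-like proteins over
four spike-in conditions of 23 samples each — and prints its headline
structure: matrix shape, overall missingness, and the share of human-only
samples (the quarter of the design where spike proteins are truly absent).
"""

import tempfile
from pathlib import Path

import spikebench as sb

config = sb.SimConfig(seed=1)
dataset, truth = sb.simulate_benchmark(config)

print(f"proteins x samples: {dataset.n_proteins} x {dataset.n_samples}")
print(f"overall missingness: {dataset.values.isna().mean().mean():.1%}")
print(f"human-only sample share: {(dataset.condition == 'humanOnly').mean():.0%}")
spikes = truth.species == "ecoli"
print(f"spike proteins: {int(spikes.sum())}, true log2FC (1:25 -> 1:12): {config.spike_delta}")

outdir = Path(tempfile.mkdtemp())
sb.write_intensity_matrix(dataset, outdir / "matrix.tsv")
sb.write_annotation(dataset, outdir / "annotation.tsv")
sb.write_ground_truth(truth, outdir / "truth.tsv")
print(f"wrote matrix/annotation/truth TSVs to {outdir}")
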