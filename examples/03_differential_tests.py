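"""Run the seven differential-abundance tests on one bootstrap dataset.

Draws 10 samples per condition (with replacement) from the 1:25 and 1:12
spike-in groups and reports, per test, how many spike proteins reach
p < 0.05 and how many human proteins are falsely called.
"""

import spikebench as sb

dataset, truth = sb.simulate_benchmark(sb.SimConfig(seed=1))
entry = sb.enumerate_design(
    sb.BootstrapDesign(min_size=10, max_size=10, replicates=1, base_seed=3)
)[0]
bootstrap = sb.draw_bootstrap(dataset, entry)
spike = truth.species.eq("ecoli")

print(f"bootstrap matrix: {bootstrap.matrix.shape[0]} proteins x {bootstrap.matrix.shape[1]} samples")
for method in sb.METHODS:
    outcome = sb.run_test(bootstrap.matrix, bootstrap.groups, bootstrap.pair, method, seed=11)
    p = outcome.effective_p()
    hits = int((p[spike.reindex(p.index).fillna(False)] < 0.05).sum())
    false = int((p[~spike.reindex(p.index).fillna(True)] < 0.05).sum())
    print(f"{method:10s}: {hits:3d} / {int(spike.sum())} spike proteins called, {false:3d} human false calls")
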