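"""Score one analysis outcome against the known ground truth.

Computes the scaled partial AUC (FPR <= 10%, ceiling 100), the sensitivity
at alpha = 0.05 and the RMSE of the estimated versus true log2 fold-changes.
"""

import spikebench as sb

dataset, truth = sb.simulate_benchmark(sb.SimConfig(seed=1))
entry = sb.enumerate_design(
    sb.BootstrapDesign(min_size=10, max_size=10, replicates=1, base_seed=3)
)[0]
bootstrap = sb.draw_bootstrap(dataset, entry)
outcome = sb.run_test(bootstrap.matrix, bootstrap.groups, bootstrap.pair, "limma")

result = sb.evaluate_outcome(outcome, truth, set(dataset.proteins))
print(f"scaled pAUC (FPR <= 10%): {result.pauc:.1f} / 100")
print(f"sensitivity at alpha=0.05: {result.sensitivity:.2f}")
print(f"RMSE of log2FC estimates:  {result.rmse:.3f}")
print(f"TP/FP/TN/FN at alpha=0.05: {result.tp}/{result.fp}/{result.tn}/{result.fn}")
print(f"max reachable TPR: {result.max_tpr:.2f}")
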