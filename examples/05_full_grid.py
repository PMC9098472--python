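"""A small factorial benchmark: sparsity x normalization x test over bootstraps.

Runs a reduced grid on one simulated workflow and summarizes the median
scaled pAUC per statistical test and per sparsity-reduction level; the
best-scoring option per reference list is flagged.
"""

import spikebench as sb

dataset, truth = sb.simulate_benchmark(sb.SimConfig(n_human=400, n_spike=80, seed=1))
spec = sb.GridSpec(
    workflows={"sim": dataset},
    truth=truth,
    design=sb.BootstrapDesign(min_size=5, max_size=5, replicates=5, base_seed=2),
    sparsity_levels=("NoSR", "SR66", "SR90"),
    normalizations=("unnormalized", "median"),
    tests=("t_equal", "limma", "sam"),
    references=("workflow",),
)
workflow_level, cases = sb.count_combinations(spec)
print(f"{workflow_level} option combinations, {cases} analysis cases")

rows = sb.run_grid(spec)
print(f"{len(rows)} result rows")
summary = sb.summarize(rows, by=["reference", "test"])
print(summary[["test", "pauc_median", "rmse_median", "best_pauc"]].to_string(index=False))
by_sr = sb.summarize(rows, by=["reference", "sparsity"])
print(by_sr[["sparsity", "pauc_median"]].to_string(index=False))
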