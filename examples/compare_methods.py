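"""Benchmark the fishing strategy against its comparators on replicated
simulations (a desk-scale version of the published comparison).

Runs 20 replicates of the independent-causal-SNP condition and prints
replicate-averaged TDR / FDR / MCC per method. The single-blanket mode
('dasso') shows the power loss of full conditioning; trend+Bonferroni
shows what plain multiple testing achieves.
"""

from mbfish import BenchmarkConfig, ScenarioSpec, run_benchmark

cfg = BenchmarkConfig(
    scenario=ScenarioSpec(scenario_id=1, scheme_id=2, population_size=20_000),
    methods=("mbrfs", "bonferroni", "bh", "dasso"),
    n_replicates=20,
    seed=42,
)
reports = run_benchmark(cfg)

print(f"{'method':12s} {'TDR':>6s} {'FDR':>6s} {'MCC':>6s}   ({cfg.n_replicates} replicates)")
for method, rep in reports.items():
    print(f"{method:12s} {rep.tdr_overall:6.3f} {rep.fdr:6.3f} {rep.mcc:6.3f}")
print("\nthe repeated-fishing selector should recover clearly more of the "
      "weak-effect causal SNPs (higher TDR) than Bonferroni at a modest "
      "FDR cost, and the single-blanket mode should trail both.")
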