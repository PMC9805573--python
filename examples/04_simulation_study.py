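"""A miniature FDR/power study: repeated offline vs online procedures.

Ten batches of 1,000 genes, 20 replicate runs, pi = 0.1.  The key
quantity is the empirical global FDR: the mean over runs of the final
cumulative FDP pooled across all batches.  Repeated offline BH targets
each batch separately and lets the global rate drift above alpha; the
online procedures keep it controlled.  (Scale n_reps/batches/genes up for
smoother estimates — the package default study is 20 x 2,000 x 100.)
"""

from batchfdr import SimulationConfig, run_simulation_study

config = SimulationConfig(n_batches=10, genes_per_batch=1000, pi_de=0.1, master_seed=3)
summary = run_simulation_study(
    config,
    methods=["offline_bh", "online_bh", "online_stbh", "online_prds"],
    pi_grid=[0.1],
    n_reps=20,
    alpha=0.05,
    engine="welch",
)
cols = ["method", "fdr", "fdr_se", "power_standard", "power_as_printed"]
print(summary.table[cols].to_string(index=False, float_format="%.4f"))
print("\nfdr = mean final cumulative FDP over runs; nominal level alpha = 0.05.")
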