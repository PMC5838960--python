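"""Reduced monitoring protocols: banked baseline and no replication.

After a first full round, a lab can (a) bank the pure-tissue profile and
run only the six mixture samples in later rounds, or (b) run all five
samples once without replication.  This example runs the same synthetic
dataset through all three modes and compares the metrics rows.
"""

from mixqc import PipelineConfig, metrics_to_table, run_pipeline
from mixqc.simulate import SimulationConfig, simulate_dataset

sim = simulate_dataset(SimulationConfig(n_mirna=800, depth=300_000, seed=5))
config = PipelineConfig(n_boot=200, seed=5)

full = run_pipeline(sim.table, sim.design, config, round_id="round3")

# bank the round-3 pure profile, then analyse mixtures alone
banked = full.artifacts["profile"]
mix_ids = [e.sample_id for e in sim.table.manifest.entries if e.kind == "mix"]
baseline = run_pipeline(sim.table.subset_samples(mix_ids), sim.design, config,
                        mode="baseline", baseline_profile=banked,
                        round_id="round4")

single = run_pipeline(sim.table, sim.design, config, mode="single_replicate",
                      round_id="round3")

print(metrics_to_table([full, baseline, single]).to_string(index=False))
print("\nBaseline mode (6 samples) reproduces the full-protocol metrics when"
      "\nthe banked profile matches the current process (tiny differences come"
      "\nfrom filtering/normalizing over 6 rather than 15 samples).  Without"
      "\nreplication"
      "\nthe ROC is ranked by |log2 ratio| instead of paired-t p-values and"
      "\ndiscrimination is typically weaker.")
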