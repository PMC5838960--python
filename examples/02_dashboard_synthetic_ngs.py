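"""Full dashboard analysis of a synthetic sequencing dataset.

Simulates a 15-sample reference set (3 replicates of each pure tissue
and mixture) with multinomial sequencing noise, runs the complete
pipeline and prints the summary metrics row, then renders the six-panel
dashboard figure.
"""

from pathlib import Path

from mixqc import PipelineConfig, metrics_to_table, render_dashboard, run_pipeline
from mixqc.simulate import SimulationConfig, simulate_dataset

sim = simulate_dataset(SimulationConfig(n_mirna=1000, depth=2_000_000, seed=42))
print(f"simulated table: {sim.table.values.shape[0]} miRNA x "
      f"{sim.table.values.shape[1]} samples (NGS counts)")

result = run_pipeline(sim.table, sim.design, PipelineConfig(n_boot=300, seed=42),
                      round_id="demo")
print("\nsummary metrics (one dashboard row):")
print(metrics_to_table([result]).to_string(index=False))

print("\nInterpretation: counts per selectivity class show how many designed"
      "\ntrue positives/negatives the platform detected; lower/upper limit"
      "\nbound the signal range where 95% of deviations stay within half a"
      "\nfold change; AUC measures how well ranking separates designed"
      "\ntrue positives from 1-to-1 true negatives; median/IQR of the"
      "\ndeviation are the bias and precision; proportion_sum is the total"
      "\ntarget-plot segment length from deconvolving the mixing fractions.")

out = Path("example_output")
paths = render_dashboard(result, out / "dashboard", formats=("png",))
print(f"\ndashboard figure written to {paths[0]}")
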