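"""Recovering the mixing fractions from the measured mixtures.

Fits the linear mixing model in reverse: given the pure-tissue profile
and the measured mixture signals, constrained least squares on the
probability simplex estimates each tissue's fraction in Mix1 and Mix2.
Bootstrap resampling of miRNAs gives 95% confidence ellipses.
"""

import numpy as np

from mixqc import estimate_proportions, proportion_uncertainty, pure_profile
from mixqc.ingest import detect_filter, normalize_median_total
from mixqc.simulate import SimulationConfig, simulate_dataset

sim = simulate_dataset(SimulationConfig(n_mirna=1000, depth=2_000_000, seed=8))
linear = normalize_median_total(detect_filter(sim.table))
profile = pure_profile(linear)

est = estimate_proportions(profile, linear, sim.design)
print("designed fractions (components x mixtures):")
print(np.round(sim.design.phi, 3))
print("\nestimated fractions:")
print(est.phi_hat.round(4))
print("\nper-component target-plot segment lengths:")
print(est.segment_length.round(5))
print(f"segment length sum: {est.length_sum:.5f}")

unc = proportion_uncertainty(profile, linear, sim.design, n_boot=300, seed=8)
for comp, ell in unc.ellipses.items():
    sds = np.sqrt(np.diag(ell.cov))
    print(f"{comp}: bootstrap sd (Mix1, Mix2) = ({sds[0]:.4f}, {sds[1]:.4f})")
print("\nSegment lengths near zero mean the lab's measurements reproduce the"
      "\npipetted proportions; consistent displacement indicates a tissue-"
      "\nintrinsic miRNA-fraction bias rather than random error.")
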