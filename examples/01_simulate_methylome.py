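"""Generate a synthetic array-style methylome with known ground truth.

The simulator lays out CpG islands (dense probes) separated by open sea
(sparse probes), walks a persistent 3-state Markov chain along each
chromosome (unmethylated / middle / methylated strata) and draws
beta-values from a truncated normal around each stratum mean.
"""

import numpy as np

from methylstates import SimulationConfig, simulate

truth = simulate(SimulationConfig(seed=1))
df = truth.profile.records

print(f"simulated {len(df)} CpGs on {df['chrom'].nunique()} chromosomes")
for s, label in enumerate(("UMS", "MMS", "FMS")):
    betas = df["beta"].to_numpy()[truth.true_site_state == s]
    print(
        f"  stratum {label}: {len(betas):5d} sites, "
        f"beta = {betas.mean():.3f} +- {betas.std():.3f}"
    )
n_islands = sum(len(v) for v in truth.islands.intervals.values())
print(f"  {n_islands} CpG islands; {len(truth.true_regions)} planted state runs")
print(
    "  planted run length (CpGs): median "
    f"{int(np.median(truth.true_regions['n_cpg']))}, "
    f"max {int(truth.true_regions['n_cpg'].max())}"
)
# The stratum means land on the configured 0.05/0.5/0.95 targets and the
# run-length numbers show the spatial persistence the HMM will exploit.
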