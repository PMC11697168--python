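"""A desk-scale factorial sweep over branch probabilities.

The full study crosses 10 probability levels per node with 3 loop
positions and 10 replicates (300,000 runs); here we run a 2-level slice
at a reduced horizon and cluster the per-combination efficiencies into
high / medium / low groups, as one would for the full table.
"""

from tunneltraffic import SimConfig, factorial_design, run_sweep
from tunneltraffic.analysis import group_sorted_efficiencies

design = factorial_design(
    levels=[0.2, 1.0], deltas=(2,), reps=2, base_seed=7
)
print(f"design: {len(design)} runs "
      f"(2 levels^4 probabilities x 1 loop position x 2 replicates)")

base = SimConfig(n0=50, T=1500, window=(1350, 1500))
table = run_sweep(design, base)

grouped = group_sorted_efficiencies(table, k=3, seed=0)
print("\ncombinations sorted by mean E (group 1 = high, 3 = low):")
print(
    grouped[["P1", "P2", "P3", "P4", "mean_E", "group"]]
    .head(8)
    .to_string(index=False)
)
sizes = grouped.groupby("group").size()
print(f"\ngroup sizes: {dict(sizes)}")
# Each row averages the replicate runs of one (P1..P4, delta) setting;
# the groups mirror the high/medium/low efficiency bands of the study.
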