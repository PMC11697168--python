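"""Global sensitivity of transport efficiency to the branch probabilities.

Draws a Latin Hypercube sample of (P1..P4), runs the simulator for each
loop position, and computes partial rank correlation coefficients (PRCC):
the Pearson correlation between rank-regression residuals, measuring each
probability's monotone influence on E with the others' effects removed.
"""

from tunneltraffic import SimConfig, run_sweep
from tunneltraffic.analysis import prcc_by_delta
from tunneltraffic.sweep import lhs_sweep_design

design = lhs_sweep_design(25, deltas=(1, 2, 3), reps=1, base_seed=3)
print(f"running {len(design)} simulations (25 LHS draws x 3 loop positions)")

base = SimConfig(T=1500, window=(1350, 1500))
table = run_sweep(design, base)

coeffs = prcc_by_delta(table.runs)
print("\nPRCC of each branch probability against E, by loop position:")
print(
    coeffs.pivot(index="variable", columns="delta", values="prcc")
    .round(3)
    .to_string()
)
# Negative values mean raising that branch probability lowers the
# delivery rate; magnitudes near zero mean the node barely matters.
# At this sample size coefficients carry sampling noise of roughly +-0.2.
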