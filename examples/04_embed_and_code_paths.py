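"""Embedding probability combinations and coding them as H/M/L paths.

Takes the members of one efficiency group from a synthetic sweep table,
embeds their (P1..P4) vectors in 2-D with t-SNE, and codes each
probability as High / Medium / Low — the compact path notation used to
read off which branching strategies share an efficiency band.
"""

from tunneltraffic import make_fixture, tsne
from tunneltraffic.analysis import (
    categorize_hml,
    group_sorted_efficiencies,
    probability_histograms,
)

fx = make_fixture("signal-sweep", seed=5, n_rows=120)
table = fx.table.rename(columns={"E": "mean_E"})

grouped = group_sorted_efficiencies(table, k=3, seed=0)
top = grouped[grouped["group"] == 1]
print(f"group 1 (high E): {len(top)} combinations")

hist = probability_histograms(top)
print("\nP3 histogram over [0,1] (high-E group):")
print(hist["P3"].round(2).to_string())

emb = tsne(top[["P1", "P2", "P3", "P4"]].to_numpy(), seed=0, iterations=300)
print(f"\nt-SNE final KL divergence: {emb.kl:.3f}")

codes = [
    "".join(categorize_hml(v) for v in row)
    for row in top[["P1", "P2", "P3", "P4"]].to_numpy()[:5]
]
print("first five H/M/L path codes (P1 P2 P3 P4):", codes)
# In the planted fixture high E requires low P3 and P4, so the high-E
# histogram piles onto the low bins and the codes end in L more often.
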