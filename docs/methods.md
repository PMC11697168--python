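# Methods

## Model

The tunnel system is an undirected lattice graph.  Main-tunnel cells are
indexed 0 (nest) … `main_length−1` (food site); loop cells continue the
index range along the arc from junction *a* to junction *c*.  Branching
nodes *a*, *b*, *c* sit on the main tunnel at fractions (0.1, 0.2, 0.3),
(0.4, 0.5, 0.6) or (0.7, 0.8, 0.9) of its length for loop positions
δ = 1, 2, 3 (near nest / centred / near food) — (50, 100, 150),
(200, 250, 300), (350, 400, 450) cells at the default length 500.  Node
*d* is the loop cell at index `loop_length // 2`; loop cells below that
index form segment 1 (*a*-side), the rest segment 2, so both segments
hold exactly `loop_length / 2` cells.  Since the loop path *a*→…→*c* has
`loop_length + 1` edges (odd), the *a*–*d* arc is one edge longer than
*d*–*c*; the asymmetry is one cell out of 100 at default size.  Every
edge costs one timestep except the separation crossing *b*–*d*, which
costs zero — it stands for a passage short and wide enough to transit
instantly.

Each of N₀ identical termites carries at most one food particle, heads
either toward the food site or toward the nest, and walks one unit-cost
edge per step.  Per timestep the phases are fixed: decrement jam timers →
move free termites → trophallaxis encounters → jam detection → endpoint
pickup/deposit.  The fixed order plus a single seeded generator makes
runs bit-reproducible.

**Branch choice.**  At a node with probability P the termite takes the
switching branch (main↔loop) with probability P, otherwise it continues
along its current tunnel toward its goal; it never takes a branch that
moves it away from its goal.  Consequently only food-bound termites can
enter the loop at *a* (toward *d*), only nest-bound ones at *c*; the
*b*↔*d* crossing serves both directions, and a termite that crosses it
continues with its unit move on the far side in the same step (at most
one free crossing per termite per step).  This reproduces the canonical
high-efficiency routes *a*→*d*→*b*→*c* (outbound) and *c*→*d*→*b*→*a*
(homebound).

**Trophallaxis.**  After the move phase, a carrier and an empty termite
on the same cell with opposite headings transfer the particle with
probability `transfer_prob` (default 0.5); on transfer both reverse
heading, otherwise they pass without interacting.  Multiple co-located
candidates are paired greedily in seeded random order, one encounter per
termite per step.  No food is ever lost; as a result a particle arriving
at the nest is deposited by whichever termite carried it last, one
particle per arrival.

**Traffic jams.**  A jam forms on a cell when at least `jam_size`
(default 4) free termites occupy it with heading vectors (+1 toward
food, −1 toward nest) summing to zero over some group of `jam_size` —
equivalently, at least `jam_size/2` free termites heading each way.  All
free termites on the cell are immobilized for `jam_duration` steps.
Reading the zero-sum over a quartet rather than over all occupants
matters: with the all-occupants reading, jams become vanishingly rare
exactly in the crowded conditions where congestion should dominate.
Jammed termites neither move nor take part in encounters or further jam
triggers; they still pick up or deposit if immobilized on an endpoint
cell.  Whether jammed termites should also block passage is unresolved
in the underlying behavioural account; here they do not, since termites
are observed to squeeze past each other in tunnels.

**Endpoints.**  An empty termite reaching the food cell picks up one
particle (supply unlimited) and turns around; a carrier reaching the
nest deposits exactly one particle and turns around.  Any termite on an
endpoint cell faces back inward afterwards.

## Efficiency statistic

`E(τ) = s · Σ_{t≤τ} food(t) / (τ · N₀)` with τ counted from the first
timestep, so E is exactly zero until the first delivery — at least 499
unit moves after pickup, hence E(τ) = 0 for τ < 500 on the default
network.  The scalar E of a run is the mean of E(τ) over an inclusive
late window, `(0.9·T, T)` by default: (4500, 5000) at the standard
horizon T = 5000.  Jam-frequency maps count jam events per cell and
normalize by the busiest cell, so 1.0 marks the worst hotspot.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `main_length`, `loop_length` | 500, 200 cells | standard geometry |
| `delta` | 2 | loop centred on the main tunnel |
| P₁…P₄ | 0.1, 0.1, 0.4, 0.4 | baseline branch probabilities |
| `n0` | 400 | colony size |
| `T` | 5000 steps | horizon |
| `s` | 10,000 | efficiency scaling |
| `transfer_prob` | 0.5 | trophallaxis success probability |
| `jam_size` | 4 (even) | balanced group that triggers a jam |
| `jam_duration` | 60 steps | immobilization per jam |

Colony size and jam duration are free parameters of the model; the study
conditions they encode are a congestion-operative regime, chosen once as
follows.  At N₀ = 100 the colony is so sparse (0.14 termites per cell)
that jams are negligible (~10–25 events per 2,000 steps) and the loop
acts purely as a detour — congestion, the phenomenon of interest, never
engages.  N₀ = 400 (0.57 per cell) produces hundreds of jam events per
run and a clear congestion signal while keeping a full-horizon run near
4 s on one core.  `jam_duration = 60` is commensurate with the 50-cell
inter-node spacing, so a jam outlives the local traffic wave that caused
it.  Deeper congestion is reachable only with colony sizes that make
sweep-scale experiments impractical, because immobilized termites stop
triggering new jams and the jam load saturates.

## Analysis stack

*Factorial design*: Cartesian product of probability levels (default
{0.1,…,1.0}), loop positions and replicates — 300,000 rows at full
scale.  Per-row seeds derive from the base seed by a counter-based
generator at design time, so execution order and parallelism cannot
change results, and an on-disk journal makes sweeps resumable.

*LHS*: stratified samples of [0,1]⁴ (one draw per equal stratum per
dimension) via scipy's `qmc.LatinHypercube`.

*k-means*: Lloyd iterations with random restarts (default 10), best
within-cluster SSE kept; efficiency tables are clustered in 1-D on E and
groups relabelled 1…k by descending centroid.  Verified against
exhaustive partition search at toy sizes.

*t-SNE*: written out in full — per-point Gaussian bandwidths found by
bisection (tolerance 1e−5) to match a target perplexity (default 30, or
n/4 for small n); conditional affinities symmetrized and normalized as
p_ij = (p_{j|i} + p_{i|j}) / 2n (the joint-distribution form; the
unnormalized average is unstable under gradient descent); Student-t
low-dimensional affinities; gradient descent with momentum 0.5→0.8,
early exaggeration ×4 for 100 iterations.  The analytic gradient is
tested against central finite differences.  Embeddings are read
qualitatively; no quantitative claim rests on them.

*PRCC*: all columns rank-transformed (average ranks on ties); each
rank-input and the rank-output are regressed (least squares, intercept)
on the remaining rank-inputs and the Pearson correlation of the residual
pair is reported.  Degenerate inputs (constant or collinear columns)
raise errors naming the offending columns.  Checked against a
normal-equations re-implementation (1e−10) and pingouin's partial
Spearman correlation.

## What the synthetic fixtures emulate

`mini-tunnel` scales the geometry down (20-cell main, 8-cell loop) and
exercises every structural invariant.  `null-sweep` and `signal-sweep`
are synthetic sweep tables — noise-only E, and E = 1 − 0.4P₃ − 0.4P₄
plus noise — giving sensitivity analyses a known null and a planted
ground truth.  They validate the statistical machinery, not the
simulator; passing them says nothing about real termite behaviour, nor
do simulator tests: the model omits pheromones, tunnel curvature, wall
irregularity, agent heterogeneity and off-centre separation tunnels.

## Reproduction scope and known limitations

At desk scale the package reproduces: the zero-efficiency transient and
the 500-step first-delivery bound; the design cardinalities; food and
population conservation; and, in the congestion-operative default
regime, the centred-loop ordering in which full separation-tunnel use
(P₃,P₄) = (1.0,1.0) outperforms (0.6,0.6).  That ordering reverses in
sparse colonies, where the loop is a pure detour.

Absolute E values are not reproducible: they depend on colony size and
jam duration, which the underlying study leaves unstated, and the deeply
congested regime implied by E ≈ 0.5 at s = 10,000 lies beyond tractable
colony sizes here (E ≈ 1.5 at N₀ = 1,200 with 1,000-step jams).

The global sensitivity signs are only partially reproduced.  PRCC(P₃)
is negative at every loop position, but in this geometry the *d*→*b*
crossing always shortens the remaining route (it rejoins the main tunnel
midway between the junctions), so PRCC(P₄) comes out positive except for
the near-nest loop, and the P₃ magnitude is largest — not smallest — for
the centred loop.  A uniformly negative P₄ with the weakest magnitudes
at δ = 2 evidently requires behavioural or geometric details beyond
those specified for this model; the corresponding end-to-end check is
left failing rather than adjusted.
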