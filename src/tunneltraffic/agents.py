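"""Discrete-time agent dynamics for food transport through the tunnel.

Each simulated termite occupies one grid cell, heads either toward the food
site or toward the nest, and may carry at most one food particle.  Per
timestep the phases are, in fixed order:

1. decrement jam timers;
2. move every free termite along one unit-cost edge (a zero-cost crossing
   of the separation tunnel happens within the same step, at most once);
3. resolve trophallaxis encounters: a carrier meeting an empty termite
   head-on transfers its particle with probability ``transfer_prob`` and
   both reverse;
4. detect traffic jams: when at least ``jam_size`` free termites occupy
   one cell and their heading vectors (+1 toward food, -1 toward nest)
   sum to zero, all of them are immobilized for ``jam_duration`` steps;
5. endpoints: an empty termite at the food site picks up a particle and
   turns around (food is unlimited); a carrier at the nest deposits
   exactly one particle and turns around.

Branch choice at the four nodes: with probability ``P`` of the node the
termite takes the switching branch (main<->loop, including the free b<->d
crossing), otherwise it continues along its current tunnel toward its
goal.  A switch that would move the termite away from its goal is never
taken — at node ``a`` only food-bound termites may enter the loop, at
``c`` only nest-bound ones; ``b`` and ``d`` serve both directions.

The engine stores the population in flat numpy arrays and advances all
agents simultaneously, which keeps full-scale runs (hundreds of agents,
thousands of steps) fast while remaining exactly reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .network import (
    BranchProbabilities,
    ConfigurationError,
    TunnelNetwork,
    build_network,
)

__all__ = [
    "TOWARD_FOOD",
    "TOWARD_NEST",
    "Termite",
    "SimConfig",
    "SimState",
    "SimResult",
    "JamEvent",
    "init_state",
    "choose_next_cell",
    "resolve_encounters",
    "detect_and_apply_jams",
    "handle_endpoints",
    "step",
    "run",
]

TOWARD_FOOD = 1
TOWARD_NEST = -1


@dataclass
class Termite:
    """Single-agent view of the population state."""

    id: int
    cell: int
    heading: int  # +1 toward food, -1 toward nest
    carrying: bool
    jam_timer: int = 0
    teleported_this_step: bool = False


@dataclass(frozen=True)
class JamEvent:
    t: int
    cell: int


@dataclass
class SimConfig:
    """Full parameterization of one simulation run.

    ``window`` is the inclusive timestep range over which the steady-state
    efficiency E is averaged; by default the last tenth of the horizon,
    which for the standard T = 5000 gives 4500..5000.
    """

    delta: int = 2
    main_length: int = 500
    loop_length: int = 200
    probs: BranchProbabilities = field(default_factory=BranchProbabilities)
    n0: int = 400
    T: int = 5000
    s: float = 10_000.0
    transfer_prob: float = 0.5
    jam_size: int = 4
    jam_duration: int = 60
    seed: Optional[int] = None
    window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ConfigurationError(f"n0 must be >= 1, got {self.n0}")
        if self.T < 1:
            raise ConfigurationError(f"T must be >= 1, got {self.T}")
        if not 0.0 <= self.transfer_prob <= 1.0:
            raise ConfigurationError(
                f"transfer_prob={self.transfer_prob} outside [0, 1]"
            )
        if self.jam_size < 2 or self.jam_size % 2:
            # heading vectors can only cancel in equal numbers
            raise ConfigurationError(
                f"jam_size must be an even count >= 2, got {self.jam_size}"
            )
        if self.jam_duration < 0:
            raise ConfigurationError("jam_duration must be >= 0")
        if self.s <= 0:
            raise ConfigurationError("scaling factor s must be > 0")

    def effective_window(self) -> tuple[int, int]:
        if self.window is not None:
            return self.window
        return (max(1, int(round(0.9 * self.T))), self.T)

    def build_network(self) -> TunnelNetwork:
        return build_network(self.delta, self.main_length, self.loop_length)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


class _MoveTables:
    """Per-network lookup tables for the movement rule.

    ``cont[h]`` maps a cell to the next cell when continuing along the
    current tunnel toward the goal ``h`` (endpoint cells map to
    themselves).  ``switch[h]`` maps node cells to the landing cell of the
    switching branch (-1 where no goal-consistent switch exists); for b and
    d the landing cell already includes the free crossing plus the unit
    move taken on the far side.
    """

    def __init__(self, net: TunnelNetwork):
        n = net.n_cells
        a, b, c, d = (net.node_cells[k] for k in "abcd")
        loop0 = net.main_length
        last = loop0 + net.loop_length - 1

        cont_f = np.empty(n, dtype=np.int64)
        cont_n = np.empty(n, dtype=np.int64)
        # main tunnel: +1 toward food, -1 toward nest; endpoints hold still
        for cell in range(net.main_length):
            cont_f[cell] = min(cell + 1, net.food_cell)
            cont_n[cell] = max(cell - 1, net.nest_cell)
        # loop runs a -> loop0 .. last -> c in the toward-food direction
        for cell in range(loop0, last + 1):
            cont_f[cell] = cell + 1 if cell < last else c
            cont_n[cell] = cell - 1 if cell > loop0 else a

        switch_f = np.full(n, -1, dtype=np.int64)
        switch_n = np.full(n, -1, dtype=np.int64)
        switch_f[a] = loop0  # food-bound at a: enter the loop arc a->d
        switch_n[c] = last  # nest-bound at c: enter the loop arc c->d
        # b<->d crossing is free; the unit move continues on the far side
        switch_f[b] = cont_f[d]
        switch_n[b] = cont_n[d]
        switch_f[d] = cont_f[b]
        switch_n[d] = cont_n[b]

        self.cont = {TOWARD_FOOD: cont_f, TOWARD_NEST: cont_n}
        self.switch = {TOWARD_FOOD: switch_f, TOWARD_NEST: switch_n}
        self.node_cells = (a, b, c, d)

    def switch_probs(
        self, probs: BranchProbabilities
    ) -> dict[int, np.ndarray]:
        """Per-cell switching probability for each heading."""
        a, b, c, d = self.node_cells
        n = len(self.cont[TOWARD_FOOD])
        pf = np.zeros(n)
        pn = np.zeros(n)
        pf[a] = probs.p1
        pf[b] = pn[b] = probs.p2
        pn[c] = probs.p3
        pf[d] = pn[d] = probs.p4
        return {TOWARD_FOOD: pf, TOWARD_NEST: pn}


@dataclass
class SimState:
    """Vectorized population state plus running audit counters."""

    network: TunnelNetwork
    config: SimConfig
    pos: np.ndarray  # cell index per termite
    heading: np.ndarray  # +1 / -1
    carrying: np.ndarray  # bool
    jam_timer: np.ndarray  # int
    t: int = 0
    picked_total: int = 0
    delivered_total: int = 0
    jam_events: list[JamEvent] = field(default_factory=list)
    tables: _MoveTables = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tables is None:
            self.tables = _MoveTables(self.network)

    @property
    def n(self) -> int:
        return len(self.pos)

    def termite(self, i: int) -> Termite:
        return Termite(
            id=i,
            cell=int(self.pos[i]),
            heading=int(self.heading[i]),
            carrying=bool(self.carrying[i]),
            jam_timer=int(self.jam_timer[i]),
        )

    @property
    def carried(self) -> int:
        return int(self.carrying.sum())


def init_state(
    config: SimConfig, network: TunnelNetwork, rng: np.random.Generator
) -> SimState:
    """Place N0 empty termites uniformly on the main tunnel, random headings."""
    n = config.n0
    pos = rng.integers(0, network.main_length, size=n)
    heading = rng.choice(np.array([TOWARD_FOOD, TOWARD_NEST], dtype=np.int64), size=n)
    return SimState(
        network=network,
        config=config,
        pos=pos.astype(np.int64),
        heading=heading,
        carrying=np.zeros(n, dtype=bool),
        jam_timer=np.zeros(n, dtype=np.int64),
    )


def choose_next_cell(
    termite: Termite,
    network: TunnelNetwork,
    probs: BranchProbabilities,
    rng: np.random.Generator,
    tables: Optional[_MoveTables] = None,
) -> int:
    """Next cell for a single free termite under the branch-choice rule.

    At a node the switching branch is taken with the node's probability
    (for b and d the returned cell lies beyond the free crossing, and the
    termite's ``teleported_this_step`` latch is set); otherwise the termite
    continues along its current tunnel toward its goal.
    """
    if termite.jam_timer > 0:
        raise ValueError("jammed termites do not move")
    if tables is None:
        tables = _MoveTables(network)
    h = termite.heading
    cell = termite.cell
    sw = tables.switch[h][cell]
    if sw >= 0 and not termite.teleported_this_step:
        p = tables.switch_probs(probs)[h][cell]
        if rng.random() < p:
            if cell in (network.node_cells["b"], network.node_cells["d"]):
                termite.teleported_this_step = True
            return int(sw)
    return int(tables.cont[h][cell])


def _move_free(state: SimState, rng: np.random.Generator) -> None:
    cfg = state.config
    tables = state.tables
    free = state.jam_timer == 0
    h = state.heading
    pos = state.pos
    fwd = np.where(
        h == TOWARD_FOOD,
        tables.cont[TOWARD_FOOD][pos],
        tables.cont[TOWARD_NEST][pos],
    )
    sp = tables.switch_probs(cfg.probs)
    p_switch = np.where(h == TOWARD_FOOD, sp[TOWARD_FOOD][pos], sp[TOWARD_NEST][pos])
    sw = np.where(
        h == TOWARD_FOOD,
        tables.switch[TOWARD_FOOD][pos],
        tables.switch[TOWARD_NEST][pos],
    )
    u = rng.random(state.n)
    take = (u < p_switch) & (sw >= 0)
    nxt = np.where(take, sw, fwd)
    state.pos = np.where(free, nxt, pos)


def resolve_encounters(state: SimState, rng: np.random.Generator) -> int:
    """Trophallaxis between co-located carrier/empty pairs with opposite headings.

    Pairs are formed greedily in a seeded random order; each termite takes
    part in at most one encounter per step.  With probability
    ``transfer_prob`` the particle changes hands and both termites reverse;
    otherwise they pass each other untouched.  Returns the number of
    transfers.  Jammed termites are immobilized and do not interact.
    """
    free_idx = np.flatnonzero(state.jam_timer == 0)
    if free_idx.size < 2:
        return 0
    counts = np.bincount(state.pos[free_idx])
    if counts.max() < 2:
        return 0
    order = free_idx[rng.permutation(free_idx.size)]
    buckets: dict[int, list[int]] = {}
    for i in order:
        c = int(state.pos[i])
        if counts[c] >= 2:
            buckets.setdefault(c, []).append(int(i))
    transfers = 0
    for cell in sorted(buckets):
        group = buckets[cell]
        if len(group) < 2:
            continue
        unmatched: list[int] = []
        for i in group:
            partner = -1
            for k, j in enumerate(unmatched):
                if (
                    state.carrying[i] != state.carrying[j]
                    and state.heading[i] == -state.heading[j]
                ):
                    partner = k
                    break
            if partner < 0:
                unmatched.append(i)
                continue
            j = unmatched.pop(partner)
            if rng.random() < state.config.transfer_prob:
                state.carrying[i], state.carrying[j] = (
                    state.carrying[j],
                    state.carrying[i],
                )
                state.heading[i] = -state.heading[i]
                state.heading[j] = -state.heading[j]
                transfers += 1
    return transfers


def detect_and_apply_jams(state: SimState) -> list[JamEvent]:
    """Immobilize cells where ``jam_size`` free termites meet head-on balanced.

    A jam forms on a cell when some group of ``jam_size`` free termites
    there has heading vectors summing to zero, i.e. the cell holds at
    least ``jam_size / 2`` free termites heading each way.  Every free
    termite on the cell is immobilized for ``jam_duration`` steps.
    """
    free = state.jam_timer == 0
    if free.sum() < state.config.jam_size:
        return []
    n_cells = state.network.n_cells
    toward_food = free & (state.heading == TOWARD_FOOD)
    toward_nest = free & (state.heading == TOWARD_NEST)
    n_f = np.bincount(state.pos[toward_food], minlength=n_cells)
    n_n = np.bincount(state.pos[toward_nest], minlength=n_cells)
    half = state.config.jam_size // 2
    jam_cells = np.flatnonzero((np.minimum(n_f, n_n) >= half))
    events = []
    for cell in jam_cells:
        mask = free & (state.pos == cell)
        state.jam_timer[mask] = state.config.jam_duration
        ev = JamEvent(state.t, int(cell))
        events.append(ev)
        state.jam_events.append(ev)
    return events


def handle_endpoints(state: SimState) -> int:
    """Pickup at the food site, deposit at the nest; returns deliveries."""
    at_food = state.pos == state.network.food_cell
    picked = at_food & ~state.carrying
    state.carrying[picked] = True
    state.picked_total += int(picked.sum())
    state.heading[at_food] = TOWARD_NEST

    at_nest = state.pos == state.network.nest_cell
    deposited = at_nest & state.carrying
    deliveries = int(deposited.sum())
    state.carrying[deposited] = False
    state.delivered_total += deliveries
    state.heading[at_nest] = TOWARD_FOOD
    return deliveries


def step(
    state: SimState, rng: np.random.Generator
) -> tuple[SimState, int, list[JamEvent]]:
    """Advance one timestep; returns (state, deliveries, new jam events)."""
    state.t += 1
    np.maximum(state.jam_timer - 1, 0, out=state.jam_timer)
    _move_free(state, rng)
    resolve_encounters(state, rng)
    events = detect_and_apply_jams(state)
    food_t = handle_endpoints(state)
    return state, food_t, events


@dataclass
class SimResult:
    """Per-step observables and summary statistics of one run."""

    config: SimConfig
    seed: Optional[int]
    food_per_step: np.ndarray  # deliveries food(t), t = 1..T
    picked_per_step: np.ndarray
    carried_after_step: np.ndarray
    E_series: np.ndarray  # E(tau), tau = 1..T
    E: float  # steady-state mean of E(tau) over the window
    jam_events: list[JamEvent]

    @property
    def total_delivered(self) -> int:
        return int(self.food_per_step.sum())

    @property
    def first_delivery_step(self) -> Optional[int]:
        nz = np.flatnonzero(self.food_per_step)
        return int(nz[0]) + 1 if nz.size else None

    def jam_count_per_step(self) -> np.ndarray:
        out = np.zeros(len(self.food_per_step), dtype=np.int64)
        for ev in self.jam_events:
            out[ev.t - 1] += 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": np.arange(1, len(self.food_per_step) + 1),
                "food_t": self.food_per_step,
                "E_tau": self.E_series,
                "jam_count": self.jam_count_per_step(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        cfg = self.config
        return {
            "seed": self.seed,
            "delta": cfg.delta,
            "probs": list(cfg.probs.as_tuple()),
            "n0": cfg.n0,
            "T": cfg.T,
            "E": self.E,
            "total_delivered": self.total_delivered,
            "first_delivery_step": self.first_delivery_step,
            "n_jam_events": len(self.jam_events),
            "jam_events": [[ev.t, ev.cell] for ev in self.jam_events],
        }


def run(config: SimConfig) -> SimResult:
    """Execute a full simulation and compute the efficiency statistic."""
    from . import metrics

    network = config.build_network()
    rng = np.random.default_rng(config.seed)
    state = init_state(config, network, rng)
    T = config.T
    food = np.zeros(T, dtype=np.int64)
    picked = np.zeros(T, dtype=np.int64)
    carried = np.zeros(T, dtype=np.int64)
    for t in range(T):
        _, food_t, _ = step(state, rng)
        food[t] = food_t
        picked[t] = state.picked_total
        carried[t] = state.carried
    series = metrics.efficiency_series(food, config.n0, config.s)
    lo, hi = config.effective_window()
    E = metrics.steady_state_E(series, window=(lo, hi))
    return SimResult(
        config=config,
        seed=config.seed,
        food_per_step=food,
        picked_per_step=picked,
        carried_after_step=carried,
        E_series=series.values,
        E=E,
        jam_events=state.jam_events,
    )
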