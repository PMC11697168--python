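"""Agent dynamics: movement, branching, trophallaxis, jams, endpoints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tunneltraffic as tt
from tunneltraffic.agents import (
    TOWARD_FOOD,
    TOWARD_NEST,
    SimState,
    Termite,
    choose_next_cell,
    detect_and_apply_jams,
    handle_endpoints,
    init_state,
    resolve_encounters,
    run,
    step,
)
from tunneltraffic.network import BranchProbabilities, ConfigurationError
from .conftest import mini_config


def make_state(net, cfg, termites):
    """Build a SimState with explicitly placed termites."""
    n = len(termites)
    return SimState(
        network=net,
        config=cfg.with_(n0=n),
        pos=np.array([t[0] for t in termites], dtype=np.int64),
        heading=np.array([t[1] for t in termites], dtype=np.int64),
        carrying=np.array([t[2] for t in termites], dtype=bool),
        jam_timer=np.zeros(n, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def test_init_no_carriers_and_population_constant(rng):
    cfg = mini_config(n0=25)
    net = cfg.build_network()
    state = init_state(cfg, net, rng)
    assert state.n == 25
    assert state.carried == 0
    assert np.all(state.jam_timer == 0)
    assert np.all((state.pos >= 0) & (state.pos < net.main_length))
    for _ in range(50):
        step(state, rng)
        assert state.n == 25


def test_init_heading_split_is_binomial():
    cfg = mini_config(n0=40)
    net = cfg.build_network()
    toward_food = 0
    draws = 0
    for seed in range(200):
        state = init_state(cfg, net, np.random.default_rng(seed))
        toward_food += int((state.heading == TOWARD_FOOD).sum())
        draws += state.n
    frac = toward_food / draws
    # 8000 Bernoulli(0.5) draws: 5 sigma ~ 0.028
    assert abs(frac - 0.5) < 0.03


def test_init_rejects_empty_colony():
    with pytest.raises(ConfigurationError):
        mini_config(n0=0)


# ---------------------------------------------------------------------------
# branch choice
# ---------------------------------------------------------------------------


def test_zero_probabilities_walk_the_main_tunnel(mini_net, rng):
    probs = BranchProbabilities(0, 0, 0, 0)
    cell = mini_net.nest_cell
    for _ in range(mini_net.main_length - 1):
        t = Termite(0, cell, TOWARD_FOOD, False)
        cell = choose_next_cell(t, mini_net, probs, rng)
    assert cell == mini_net.food_cell


def test_forced_branch_at_a_enters_loop(mini_net, rng):
    probs = BranchProbabilities(1.0, 0, 0, 0)
    t = Termite(0, mini_net.node_cells["a"], TOWARD_FOOD, False)
    nxt = choose_next_cell(t, mini_net, probs, rng)
    assert mini_net.tunnel_class(nxt) == "loop1"


def test_nest_bound_never_reverses_into_loop_at_a(mini_net, rng):
    probs = BranchProbabilities(1.0, 0, 0, 0)
    t = Termite(0, mini_net.node_cells["a"], TOWARD_NEST, False)
    nxt = choose_next_cell(t, mini_net, probs, rng)
    assert mini_net.tunnel_class(nxt) == "main"
    assert nxt == mini_net.node_cells["a"] - 1


def test_switch_at_b_crosses_for_free_and_advances(mini_net, rng):
    probs = BranchProbabilities(0, 1.0, 0, 0)
    b, d = mini_net.node_cells["b"], mini_net.node_cells["d"]
    t = Termite(0, b, TOWARD_FOOD, False)
    nxt = choose_next_cell(t, mini_net, probs, rng)
    # lands one unit-move beyond d, on the c-side loop arc
    assert nxt == d + 1
    assert t.teleported_this_step


def test_branch_frequency_matches_probability(mini_net):
    # 10,000 arrivals at b with P2 = 0.3: binomial CI
    probs = BranchProbabilities(0, 0.3, 0, 0)
    rng = np.random.default_rng(7)
    b = mini_net.node_cells["b"]
    took = 0
    n = 10_000
    for _ in range(n):
        t = Termite(0, b, TOWARD_FOOD, False)
        if choose_next_cell(t, mini_net, probs, rng) != b + 1:
            took += 1
    assert took / n == pytest.approx(0.3, abs=0.015)


# ---------------------------------------------------------------------------
# trophallaxis encounters
# ---------------------------------------------------------------------------


def test_like_pairs_do_not_interact(mini_net, rng):
    cfg = mini_config(transfer_prob=1.0)
    # carrying+carrying and empty+empty pairs: nothing happens
    state = make_state(
        mini_net,
        cfg,
        [(5, TOWARD_FOOD, True), (5, TOWARD_NEST, True),
         (7, TOWARD_FOOD, False), (7, TOWARD_NEST, False)],
    )
    resolve_encounters(state, rng)
    assert list(state.carrying) == [True, True, False, False]
    assert list(state.heading) == [TOWARD_FOOD, TOWARD_NEST, TOWARD_FOOD, TOWARD_NEST]


def test_forced_transfer_swaps_load_and_reverses_both(mini_net, rng):
    cfg = mini_config(transfer_prob=1.0)
    state = make_state(
        mini_net, cfg, [(5, TOWARD_NEST, True), (5, TOWARD_FOOD, False)]
    )
    n = resolve_encounters(state, rng)
    assert n == 1
    assert list(state.carrying) == [False, True]
    assert list(state.heading) == [TOWARD_FOOD, TOWARD_NEST]


def test_same_heading_carrier_empty_pair_does_not_transfer(mini_net, rng):
    cfg = mini_config(transfer_prob=1.0)
    state = make_state(
        mini_net, cfg, [(5, TOWARD_NEST, True), (5, TOWARD_NEST, False)]
    )
    assert resolve_encounters(state, rng) == 0


def test_transfer_rate_is_binomial(mini_net):
    cfg = mini_config(transfer_prob=0.5)
    rng = np.random.default_rng(11)
    transfers = 0
    n = 10_000
    for _ in range(n):
        state = make_state(
            mini_net, cfg, [(5, TOWARD_NEST, True), (5, TOWARD_FOOD, False)]
        )
        transfers += resolve_encounters(state, rng)
    assert transfers / n == pytest.approx(0.5, abs=0.015)


def test_each_termite_at_most_one_encounter_per_step(mini_net, rng):
    cfg = mini_config(transfer_prob=1.0)
    # one carrier amid three eligible empties: exactly one transfer
    state = make_state(
        mini_net,
        cfg,
        [(5, TOWARD_NEST, True)]
        + [(5, TOWARD_FOOD, False) for _ in range(3)],
    )
    assert resolve_encounters(state, rng) == 1
    assert state.carrying.sum() == 1


# ---------------------------------------------------------------------------
# traffic jams
# ---------------------------------------------------------------------------


def test_balanced_four_jam(mini_net):
    cfg = mini_config(jam_duration=5)
    state = make_state(
        mini_net,
        cfg,
        [(6, TOWARD_FOOD, False), (6, TOWARD_FOOD, False),
         (6, TOWARD_NEST, False), (6, TOWARD_NEST, False)],
    )
    events = detect_and_apply_jams(state)
    assert len(events) == 1 and events[0].cell == 6
    assert np.all(state.jam_timer == 5)


def test_unbalanced_or_small_groups_do_not_jam(mini_net):
    cfg = mini_config()
    all_same = make_state(
        mini_net, cfg, [(6, TOWARD_FOOD, False)] * 4
    )
    assert detect_and_apply_jams(all_same) == []
    three = make_state(
        mini_net,
        cfg,
        [(6, TOWARD_FOOD, False), (6, TOWARD_NEST, False),
         (6, TOWARD_FOOD, False)],
    )
    assert detect_and_apply_jams(three) == []


def test_five_with_balanced_subset_jam(mini_net):
    # 3 one way + 2 the other: four of them meet head-on balanced
    cfg = mini_config(jam_duration=4)
    state = make_state(
        mini_net,
        cfg,
        [(6, TOWARD_FOOD, False)] * 3 + [(6, TOWARD_NEST, False)] * 2,
    )
    events = detect_and_apply_jams(state)
    assert len(events) == 1
    assert np.all(state.jam_timer == 4)


def test_jammed_termites_do_not_move(mini_net, rng):
    cfg = mini_config(jam_duration=3, probs=BranchProbabilities(0, 0, 0, 0))
    state = make_state(
        mini_net,
        cfg,
        [(6, TOWARD_FOOD, False), (6, TOWARD_FOOD, False),
         (6, TOWARD_NEST, False), (6, TOWARD_NEST, False)],
    )
    detect_and_apply_jams(state)
    pos0 = state.pos.copy()
    step(state, rng)
    step(state, rng)
    assert np.array_equal(state.pos, pos0)
    step(state, rng)  # timers expire, termites move again
    assert not np.array_equal(state.pos, pos0)


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------


def test_pickup_and_deposit(mini_net):
    cfg = mini_config()
    state = make_state(
        mini_net,
        cfg,
        [(mini_net.food_cell, TOWARD_FOOD, False),
         (mini_net.nest_cell, TOWARD_NEST, True),
         (mini_net.nest_cell, TOWARD_NEST, False)],
    )
    deliveries = handle_endpoints(state)
    assert deliveries == 1
    assert list(state.carrying) == [True, False, False]
    # everyone at an endpoint faces back inward
    assert state.heading[0] == TOWARD_NEST
    assert state.heading[1] == TOWARD_FOOD
    assert state.heading[2] == TOWARD_FOOD


def test_single_agent_round_trip_rate():
    # obstacle-free main path of L cells: one particle per 2(L-1) steps
    L = 12
    cfg = mini_config(
        main_length=L,
        loop_length=4,
        probs=BranchProbabilities(0, 0, 0, 0),
        n0=1,
        T=8 * (L - 1),
        window=(1, 8 * (L - 1)),
        seed=3,
    )
    res = run(cfg)
    first = res.first_delivery_step
    # starting somewhere on the path: first trip <= full round trip
    assert first <= 2 * (L - 1) + 1
    deliveries = np.flatnonzero(res.food_per_step) + 1
    assert np.all(np.diff(deliveries) == 2 * (L - 1))


def test_single_agent_from_nest_delivers_at_exact_round_trip(mini_net):
    cfg = mini_config(probs=BranchProbabilities(0, 0, 0, 0), n0=1, T=60)
    net = cfg.build_network()
    state = make_state(net, cfg, [(net.nest_cell, TOWARD_FOOD, False)])
    rng = np.random.default_rng(0)
    deliveries = []
    for t in range(60):
        _, food_t, _ = step(state, rng)
        deliveries.append(food_t)
    first = np.flatnonzero(deliveries)[0] + 1
    assert first == 2 * (net.main_length - 1)


# ---------------------------------------------------------------------------
# full runs: determinism, conservation, empty system
# ---------------------------------------------------------------------------


def test_no_termites_short_circuit(mini_net, rng):
    cfg = mini_config(n0=1)
    state = make_state(mini_net, cfg, [(5, TOWARD_FOOD, False)])
    state.pos = state.pos[:0]
    state.heading = state.heading[:0]
    state.carrying = state.carrying[:0]
    state.jam_timer = state.jam_timer[:0]
    _, food_t, events = step(state, rng)
    assert food_t == 0 and events == []


def test_seed_determinism():
    cfg = mini_config(n0=15, T=300, seed=77)
    a, b = run(cfg), run(cfg)
    assert np.array_equal(a.food_per_step, b.food_per_step)
    assert np.array_equal(a.E_series, b.E_series)
    assert a.jam_events == b.jam_events
    c = run(cfg.with_(seed=78))
    assert not np.array_equal(a.food_per_step, c.food_per_step)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    n0=st.integers(2, 30),
    seed=st.integers(0, 2**31 - 1),
    p=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    delta=st.sampled_from([1, 2, 3]),
)
def test_food_conservation_property(n0, seed, p, delta):
    """No food is lost: picked up = delivered + in transit, at every step."""
    cfg = mini_config(
        delta=delta,
        n0=n0,
        seed=seed,
        T=150,
        window=(100, 150),
        probs=BranchProbabilities(*p),
    )
    res = run(cfg)
    delivered = np.cumsum(res.food_per_step)
    assert np.all(res.picked_per_step == delivered + res.carried_after_step)
    assert np.all(np.diff(delivered) >= 0)


def test_first_delivery_bound_on_default_network():
    cfg = tt.SimConfig(T=600, seed=5)
    res = run(cfg)
    if res.first_delivery_step is not None:
        assert res.first_delivery_step >= 500
    assert np.all(res.E_series[:499] == 0.0)
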