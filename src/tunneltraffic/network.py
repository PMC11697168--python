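"""Tunnel geometry: a straight main tunnel with an attached 2-segment loop.

The network is a lattice graph of unit grid cells.  The main tunnel is a
simple path from the nest to the food site.  A loop tunnel branches off the
main tunnel at two nodes (``a`` near the nest side, ``c`` near the food
side) and is divided into two segments by a short, wide "separation tunnel"
that connects the main tunnel's middle node ``b`` to the loop's middle node
``d``.  Because the separation tunnel is short and wide, crossing it costs
zero timesteps; every other edge costs one timestep.

The loop position is a categorical parameter ``delta``: 1 places the loop
near the nest, 2 at the centre of the main tunnel, 3 near the food site.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

__all__ = [
    "BranchProbabilities",
    "BranchNode",
    "TunnelNetwork",
    "build_network",
    "neighbors",
    "shortest_path_length",
    "ConfigurationError",
    "GeometryError",
    "UnknownCellError",
]


class ConfigurationError(ValueError):
    """Invalid model configuration (parameter out of its allowed range)."""


class GeometryError(ValueError):
    """Node layout does not fit inside the requested tunnel lengths."""


class UnknownCellError(KeyError):
    """A cell index that does not exist in the network."""


# Fractional main-tunnel positions of nodes (a, b, c) per loop position.
_NODE_FRACTIONS = {
    1: (0.1, 0.2, 0.3),
    2: (0.4, 0.5, 0.6),
    3: (0.7, 0.8, 0.9),
}


@dataclass(frozen=True)
class BranchProbabilities:
    """Branch-selection probabilities P1..P4 at nodes a, b, c, d."""

    p1: float = 0.1
    p2: float = 0.1
    p3: float = 0.4
    p4: float = 0.4

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)

    def for_node(self, label: str) -> float:
        return self.as_tuple()["abcd".index(label)]


@dataclass(frozen=True)
class BranchNode:
    """A branching node: its label, host cell and incident edges.

    ``incident_edges`` lists (neighbor cell, tunnel class of the neighbor,
    traversal cost in timesteps).
    """

    label: str
    cell: int
    incident_edges: tuple[tuple[int, str, int], ...]


@dataclass
class TunnelNetwork:
    """The full lattice: main path, loop path, node positions, adjacency.

    Cells are 0-based integers: ``0 .. main_length-1`` along the main
    tunnel (0 = nest, ``main_length-1`` = food), then
    ``main_length .. main_length+loop_length-1`` along the loop from the
    ``a`` side to the ``c`` side.  Node ``d`` is the loop cell at the
    loop's midpoint; loop cells before it form segment 1, the rest
    segment 2.
    """

    main_length: int
    loop_length: int
    delta: int
    nest_cell: int
    food_cell: int
    node_cells: dict[str, int]  # label -> cell
    adjacency: dict[int, list[tuple[int, int]]]  # cell -> [(nbr, cost)]
    nodes: dict[str, BranchNode] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.main_length + self.loop_length

    @property
    def d_index(self) -> int:
        """Loop-array index of node d."""
        return self.loop_length // 2

    def main_cells(self) -> range:
        return range(self.main_length)

    def loop_cells(self) -> range:
        return range(self.main_length, self.main_length + self.loop_length)

    def tunnel_class(self, cell: int) -> str:
        """'main', 'loop1' (a-side segment) or 'loop2' (c-side segment)."""
        if cell not in self.adjacency:
            raise UnknownCellError(cell)
        if cell < self.main_length:
            return "main"
        return "loop1" if cell - self.main_length < self.d_index else "loop2"

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        edges = sorted(
            (min(u, v), max(u, v), c)
            for u, nbrs in self.adjacency.items()
            for v, c in nbrs
        )
        payload = {
            "main_length": self.main_length,
            "loop_length": self.loop_length,
            "delta": self.delta,
            "nest_cell": self.nest_cell,
            "food_cell": self.food_cell,
            "node_cells": self.node_cells,
            "cells": list(range(self.n_cells)),
            "edges": sorted(set(edges)),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TunnelNetwork":
        data = json.loads(text)
        net = build_network(
            data["delta"], data["main_length"], data["loop_length"]
        )
        expect = {tuple(e) for e in data["edges"]}
        have = {
            (min(u, v), max(u, v), c)
            for u, nbrs in net.adjacency.items()
            for v, c in nbrs
        }
        if expect != have:
            raise GeometryError("serialized edge list does not match geometry")
        return net


def _edge(adj: dict[int, list[tuple[int, int]]], u: int, v: int, cost: int) -> None:
    adj[u].append((v, cost))
    adj[v].append((u, cost))


def build_network(
    delta: int, main_length: int = 500, loop_length: int = 200
) -> TunnelNetwork:
    """Construct the simplified looped tunnel for a given loop position.

    Parameters
    ----------
    delta
        Loop position: 1 near the nest, 2 centred, 3 near the food site.
    main_length
        Number of grid cells in the straight main tunnel (nest to food).
    loop_length
        Number of grid cells in the loop tunnel; must be even so the
        separation tunnel splits it into two equal segments.
    """
    if delta not in (1, 2, 3):
        raise ConfigurationError(f"delta must be 1, 2 or 3, got {delta!r}")
    if main_length < 4:
        raise ConfigurationError(f"main_length must be >= 4, got {main_length}")
    if loop_length < 2 or loop_length % 2:
        raise ConfigurationError(
            f"loop_length must be even and >= 2, got {loop_length}"
        )

    a_cell, b_cell, c_cell = (
        round(f * main_length) for f in _NODE_FRACTIONS[delta]
    )
    if not (0 < a_cell < b_cell < c_cell < main_length - 1):
        raise GeometryError(
            f"nodes (a,b,c)=({a_cell},{b_cell},{c_cell}) do not fit strictly "
            f"inside a main tunnel of {main_length} cells"
        )

    loop0 = main_length  # first loop cell (adjacent to a)
    d_cell = loop0 + loop_length // 2
    last_loop = loop0 + loop_length - 1

    adj: dict[int, list[tuple[int, int]]] = {
        c: [] for c in range(main_length + loop_length)
    }
    for u in range(main_length - 1):
        _edge(adj, u, u + 1, 1)
    _edge(adj, a_cell, loop0, 1)
    for u in range(loop0, last_loop):
        _edge(adj, u, u + 1, 1)
    _edge(adj, last_loop, c_cell, 1)
    _edge(adj, b_cell, d_cell, 0)  # the separation tunnel: free crossing

    node_cells = {"a": a_cell, "b": b_cell, "c": c_cell, "d": d_cell}
    net = TunnelNetwork(
        main_length=main_length,
        loop_length=loop_length,
        delta=delta,
        nest_cell=0,
        food_cell=main_length - 1,
        node_cells=node_cells,
        adjacency={c: sorted(nbrs) for c, nbrs in adj.items()},
    )
    net.nodes = {
        label: BranchNode(
            label,
            cell,
            tuple(
                (nbr, net.tunnel_class(nbr), cost)
                for nbr, cost in net.adjacency[cell]
            ),
        )
        for label, cell in node_cells.items()
    }
    return net


def neighbors(network: TunnelNetwork, cell: int) -> list[tuple[int, int]]:
    """Adjacent cells of ``cell`` with traversal costs."""
    try:
        return list(network.adjacency[cell])
    except KeyError:
        raise UnknownCellError(cell) from None


def shortest_path_length(network: TunnelNetwork, src: int, dst: int) -> int:
    """Minimum traversal cost between two cells (the b-d edge counts 0)."""
    if src not in network.adjacency:
        raise UnknownCellError(src)
    if dst not in network.adjacency:
        raise UnknownCellError(dst)
    dist = {src: 0}
    heap = [(0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if u == dst:
            return d
        if d > dist.get(u, float("inf")):
            continue
        for v, cost in network.adjacency[u]:
            nd = d + cost
            if nd < dist.get(v, float("inf")):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    raise RuntimeError(f"cells {src} and {dst} are disconnected")  # unreachable
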