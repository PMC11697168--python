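"""Deterministic miniature inputs for tests, examples and debugging.

Fixtures are generated from a seed at call time, never stored on disk:

* ``mini-tunnel`` — a 20-cell main tunnel with an 8-cell loop, honoring
  every geometric invariant of the full network;
* ``null-sweep`` — a synthetic sweep table whose E values are pure noise,
  independent of the branch probabilities (sensitivity analyses should
  find nothing);
* ``signal-sweep`` — a synthetic sweep table with E = 1 - 0.4 P3 - 0.4 P4
  plus small noise, a planted ground truth that PRCC must recover with
  strongly negative coefficients for P3 and P4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .network import ConfigurationError, TunnelNetwork, build_network

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("mini-tunnel", "null-sweep", "signal-sweep")


@dataclass
class Fixture:
    name: str
    seed: int
    network: Optional[TunnelNetwork] = None
    table: Optional[pd.DataFrame] = None


def _sweep_frame(rng: np.random.Generator, n_rows: int) -> pd.DataFrame:
    P = rng.random((n_rows, 4))
    return pd.DataFrame(P, columns=["P1", "P2", "P3", "P4"]).assign(
        delta=rng.integers(1, 4, size=n_rows)
    )


def make_fixture(name: str, seed: int = 0, n_rows: int = 200) -> Fixture:
    """Build a named fixture deterministically from a seed."""
    rng = np.random.default_rng(seed)
    if name == "mini-tunnel":
        return Fixture(name, seed, network=build_network(1, 20, 8))
    if name == "null-sweep":
        df = _sweep_frame(rng, n_rows)
        df["E"] = 0.5 + 0.05 * rng.standard_normal(n_rows)
        return Fixture(name, seed, table=df)
    if name == "signal-sweep":
        df = _sweep_frame(rng, n_rows)
        df["E"] = (
            1.0
            - 0.4 * df["P3"]
            - 0.4 * df["P4"]
            + 0.01 * rng.standard_normal(n_rows)
        )
        return Fixture(name, seed, table=df)
    raise ConfigurationError(
        f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
    )
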