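"""Transport-efficiency statistic and spatial jam-frequency maps.

The efficiency at time tau is the scaled cumulative delivery rate per
termite,

    E(tau) = s * sum_{t=1}^{tau} food(t) / (tau * N0),

where ``food(t)`` is the number of particles deposited at the nest at
timestep ``t``, ``N0`` the colony size and ``s`` a scaling factor
(default 10,000) that keeps the numbers readable.  The scalar efficiency
``E`` of a run is the average of E(tau) over a late, converged window of
the horizon (timesteps 4,500..5,000 for the standard T = 5,000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ConfigurationError, TunnelNetwork

__all__ = [
    "EfficiencySeries",
    "JamFrequencyMap",
    "efficiency_series",
    "steady_state_E",
    "jam_frequency_map",
]


@dataclass
class EfficiencySeries:
    """E(tau) for tau = 1..T (``values[k]`` is E(k+1))."""

    values: np.ndarray
    s: float
    n0: int

    def __len__(self) -> int:
        return len(self.values)

    def cumulative_deliveries(self) -> np.ndarray:
        tau = np.arange(1, len(self.values) + 1)
        return np.rint(self.values * tau * self.n0 / self.s).astype(np.int64)


def efficiency_series(food_per_step, n0: int, s: float = 10_000.0) -> EfficiencySeries:
    """Scaled cumulative delivery rate E(tau) for every tau."""
    if n0 < 1:
        raise ConfigurationError(f"n0 must be >= 1, got {n0}")
    if s <= 0:
        raise ConfigurationError(f"s must be > 0, got {s}")
    food = np.asarray(food_per_step, dtype=float)
    tau = np.arange(1, len(food) + 1, dtype=float)
    values = s * np.cumsum(food) / (tau * n0)
    return EfficiencySeries(values=values, s=float(s), n0=int(n0))


def steady_state_E(
    series: EfficiencySeries, window: tuple[int, int] = (4500, 5000)
) -> float:
    """Mean of E(tau) over the inclusive timestep window."""
    lo, hi = window
    if not (1 <= lo <= hi <= len(series)):
        raise ValueError(
            f"window {window} outside series of length {len(series)}"
        )
    return float(series.values[lo - 1 : hi].mean())


@dataclass
class JamFrequencyMap:
    """Per-cell jam counts and max-normalized frequencies in [0, 1]."""

    counts: np.ndarray  # indexed by cell id
    normalized: np.ndarray
    network: TunnelNetwork

    def to_frame(self) -> pd.DataFrame:
        cells = np.arange(self.network.n_cells)
        return pd.DataFrame(
            {
                "cell_id": cells,
                "tunnel_class": [self.network.tunnel_class(int(c)) for c in cells],
                "count": self.counts,
                "normalized": self.normalized,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def jam_frequency_map(jam_events, network: TunnelNetwork) -> JamFrequencyMap:
    """Tally jam events per cell; normalize by the busiest cell's count."""
    counts = np.zeros(network.n_cells, dtype=np.int64)
    for ev in jam_events:
        cell = ev.cell if hasattr(ev, "cell") else ev[1]
        if not 0 <= cell < network.n_cells:
            raise ValueError(f"jam event references unknown cell {cell}")
        counts[cell] += 1
    peak = counts.max()
    normalized = counts / peak if peak > 0 else counts.astype(float)
    return JamFrequencyMap(counts=counts, normalized=normalized, network=network)
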