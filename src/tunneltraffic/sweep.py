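"""Experiment designs and batch execution.

Two designs are supported: the full factorial grid over branch
probabilities and loop positions (10 levels per probability x 3 loop
positions x 10 replicates = 300,000 runs at full scale) and Latin
Hypercube samples of the probability hypercube for sensitivity analysis.
``run_sweep`` executes a design row by row with per-row seeds attached at
design time, so results are independent of execution order and resumable
through an on-disk journal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import agents
from .network import BranchProbabilities, ConfigurationError

__all__ = [
    "SweepDesign",
    "SweepTable",
    "default_levels",
    "factorial_design",
    "lhs_design",
    "lhs_sweep_design",
    "run_sweep",
]

_PROB_COLS = ["P1", "P2", "P3", "P4"]
_COMBO_COLS = _PROB_COLS + ["delta"]


def _row_seed(base_seed: int, n_rows: int) -> np.ndarray:
    """Deterministic per-row seeds; prefix-stable in the row index."""
    state = np.random.SeedSequence(base_seed).generate_state(n_rows, np.uint64)
    return (state % np.uint64(2**31)).astype(np.int64)


def default_levels(n: int = 10) -> np.ndarray:
    """The n-level probability grid {1/n, 2/n, ..., 1.0}."""
    return np.arange(1, n + 1) / n


@dataclass
class SweepDesign:
    """Enumerated runs: one row per (P1..P4, delta, replicate)."""

    table: pd.DataFrame  # columns: row, P1..P4, delta, replicate, seed
    provenance: str  # "factorial" | "lhs"

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SweepTable:
    """Executed sweep: per-run results and per-combination means."""

    runs: pd.DataFrame  # design columns + E, total_delivered, n_jams, error

    @property
    def summary(self) -> pd.DataFrame:
        ok = self.runs[self.runs["error"].isna()]
        g = ok.groupby(_COMBO_COLS, as_index=False)
        out = g.agg(
            mean_E=("E", "mean"),
            n_reps=("E", "size"),
            total_jams=("n_jams", "sum"),
        )
        return out

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepTable":
        return cls(runs=pd.read_csv(path))


def factorial_design(
    levels=None,
    deltas=(1, 2, 3),
    reps: int = 10,
    base_seed: int = 0,
) -> SweepDesign:
    """Cartesian product of probability levels, loop positions and replicates."""
    if levels is None:
        levels = default_levels()
    levels = np.asarray(list(levels), dtype=float)
    if levels.size == 0:
        raise ConfigurationError("levels must be non-empty")
    if np.any((levels < 0) | (levels > 1)):
        raise ConfigurationError("probability levels must lie in [0, 1]")
    rows = list(
        itertools.product(levels, levels, levels, levels, deltas, range(reps))
    )
    table = pd.DataFrame(rows, columns=_PROB_COLS + ["delta", "replicate"])
    table.insert(0, "row", np.arange(len(table)))
    table["seed"] = _row_seed(base_seed, len(table))
    return SweepDesign(table=table, provenance="factorial")


def lhs_design(
    n_samples: int, dims: int = 4, rng=None
) -> np.ndarray:
    """Latin Hypercube sample of the unit hypercube.

    Each dimension is split into ``n_samples`` equal strata with exactly
    one draw per stratum, uniformly placed within it.
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    sampler = qmc.LatinHypercube(d=dims, seed=rng)
    return sampler.random(n_samples)


def lhs_sweep_design(
    n_samples: int,
    deltas=(1, 2, 3),
    reps: int = 1,
    base_seed: int = 0,
) -> SweepDesign:
    """LHS probability draws crossed with loop positions and replicates."""
    pts = lhs_design(n_samples, 4, rng=np.random.default_rng(base_seed))
    rows = []
    for (p1, p2, p3, p4), delta, rep in itertools.product(
        pts, deltas, range(reps)
    ):
        rows.append((p1, p2, p3, p4, delta, rep))
    table = pd.DataFrame(rows, columns=_PROB_COLS + ["delta", "replicate"])
    table.insert(0, "row", np.arange(len(table)))
    table["seed"] = _row_seed(base_seed, len(table))
    return SweepDesign(table=table, provenance="lhs")


def _run_one(row, base_config: agents.SimConfig) -> dict:
    cfg = base_config.with_(
        delta=int(row.delta),
        probs=BranchProbabilities(row.P1, row.P2, row.P3, row.P4),
        seed=int(row.seed),
    )
    res = agents.run(cfg)
    return {
        "E": res.E,
        "total_delivered": res.total_delivered,
        "n_jams": len(res.jam_events),
        "error": np.nan,
    }


def run_sweep(
    design: SweepDesign,
    base_config: Optional[agents.SimConfig] = None,
    journal: Optional[str] = None,
    progress: bool = False,
) -> SweepTable:
    """Execute every design row; optionally journal results for resume.

    Per-row failures are recorded in the ``error`` column instead of
    aborting the sweep.  With a ``journal`` path, finished rows are
    appended to a CSV as they complete and skipped on re-entry.
    """
    if base_config is None:
        base_config = agents.SimConfig()
    done: dict[int, dict] = {}
    jpath = Path(journal) if journal else None
    if jpath is not None and jpath.exists():
        prev = pd.read_csv(jpath)
        for rec in prev.to_dict("records"):
            done[int(rec["row"])] = rec
    jfile = None
    if jpath is not None:
        write_header = not jpath.exists() or jpath.stat().st_size == 0
        jfile = open(jpath, "a", buffering=1)
        if write_header:
            jfile.write("row,E,total_delivered,n_jams,error\n")
    results = []
    try:
        iterator = design.table.itertuples(index=False)
        if progress:
            from tqdm import tqdm

            iterator = tqdm(iterator, total=len(design))
        for row in iterator:
            rid = int(row.row)
            if rid in done:
                rec = done[rid]
                out = {
                    "E": rec["E"],
                    "total_delivered": rec["total_delivered"],
                    "n_jams": rec["n_jams"],
                    "error": rec.get("error", np.nan),
                }
            else:
                try:
                    out = _run_one(row, base_config)
                except Exception as exc:  # recorded, not fatal
                    out = {
                        "E": np.nan,
                        "total_delivered": 0,
                        "n_jams": 0,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                if jfile is not None:
                    err = "" if out["error"] is np.nan else out["error"]
                    jfile.write(
                        f"{rid},{out['E']},{out['total_delivered']},"
                        f"{out['n_jams']},{err}\n"
                    )
            results.append(out)
    finally:
        if jfile is not None:
            jfile.close()
    runs = design.table.copy()
    res_df = pd.DataFrame(results)
    for col in res_df.columns:
        runs[col] = res_df[col].to_numpy()
    runs["error"] = runs["error"].astype(object).where(pd.notna(runs["error"]), np.nan)
    return SweepTable(runs=runs)
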