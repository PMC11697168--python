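"""Configuration files and run manifests.

Configurations are flat YAML (or JSON, which YAML subsumes) mappings of
``SimConfig`` fields with the branch probabilities as ``p1``..``p4``.
Unknown keys are rejected so typos fail loudly.  Every CLI run writes a
``RunManifest`` recording the exact inputs, seeds, software version and a
checksum of each produced artifact, so any output can be traced back and
reproduced.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .agents import SimConfig
from .network import BranchProbabilities, ConfigurationError

__all__ = ["load_config", "save_config", "config_to_dict", "RunManifest"]

_PROB_KEYS = ("p1", "p2", "p3", "p4")
_SCALAR_KEYS = (
    "delta",
    "main_length",
    "loop_length",
    "n0",
    "T",
    "s",
    "transfer_prob",
    "jam_size",
    "jam_duration",
    "seed",
    "window",
)


def config_to_dict(cfg: SimConfig) -> dict:
    out = {k: getattr(cfg, k) for k in _SCALAR_KEYS}
    if out["window"] is not None:
        out["window"] = list(out["window"])
    out.update({k: getattr(cfg.probs, k) for k in _PROB_KEYS})
    return out


def _config_from_dict(data: dict) -> SimConfig:
    unknown = sorted(set(data) - set(_SCALAR_KEYS) - set(_PROB_KEYS))
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    probs = BranchProbabilities(
        **{k: data[k] for k in _PROB_KEYS if k in data}
    )
    kw = {k: data[k] for k in _SCALAR_KEYS if k in data}
    if kw.get("window") is not None:
        kw["window"] = tuple(kw["window"])
    return SimConfig(probs=probs, **kw)


def load_config(path) -> SimConfig:
    """Read a YAML/JSON run configuration, applying model defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    return _config_from_dict(data)


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every CLI artifact."""

    command: str
    parameters: dict
    seed: object = None
    version: str = __version__
    created: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat(timespec="seconds")
    )
    outputs: list = dataclasses.field(default_factory=list)

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs.append({"path": str(p), "sha256": _sha256(p)})

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, default=str)
        )
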