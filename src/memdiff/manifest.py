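"""Seeded-run manifests and structured experiment configuration.

Every CLI run writes, beside its CSV outputs, a JSON manifest holding the
subcommand, the full parameter set, the seed, the tool version and the
output paths.  Replaying a manifest re-runs the same computation and must
reproduce every stochastic output bit-for-bit; silent seeding is forbidden
throughout the package, so the manifest is a complete record of the run.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__

logger = logging.getLogger("memdiff")

_BLOCK_KEYS: dict[str, set[str]] = {
    "walk": {"p", "steps", "mode", "n_walks", "origin"},
    "diffusion": {"D", "t", "ic", "ic_params", "grid_min", "grid_max", "grid_points"},
    "sde": {"F", "gamma", "D", "x0", "T", "steps", "paths", "method", "forces"},
    "converge": {"F", "gamma", "D", "x0", "T", "levels", "paths"},
    "pde": {"sigmas", "grid", "tau_end", "checkpoints"},
}


@dataclass(frozen=True)
class RunManifest:
    """Complete record of one seeded run."""

    subcommand: str
    parameters: dict[str, Any]
    seed: int
    outputs: list[str]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass(frozen=True)
class ExperimentConfig:
    """Named parameter blocks for the walk/diffusion/sde/pde scenarios.

    Unknown block names and unknown keys inside a block are rejected up
    front, so a typo fails loudly instead of silently using a default.
    """

    blocks: dict[str, dict[str, Any]]
    seed: int = 0
    output_dir: str = "memdiff-out"

    def __post_init__(self) -> None:
        for name, block in self.blocks.items():
            if name not in _BLOCK_KEYS:
                raise ValueError(
                    f"unknown config block {name!r}; known: {sorted(_BLOCK_KEYS)}"
                )
            if not isinstance(block, dict):
                raise ValueError(f"config block {name!r} must be a mapping")
            unknown = set(block) - _BLOCK_KEYS[name]
            if unknown:
                raise ValueError(
                    f"unknown keys {sorted(unknown)} in config block {name!r}"
                )

    def require(self, name: str) -> dict[str, Any]:
        if name not in self.blocks:
            raise ValueError(f"config is missing the {name!r} block")
        return dict(self.blocks[name])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
        seed = int(raw.pop("seed", 0))
        output_dir = str(raw.pop("output_dir", "memdiff-out"))
        return cls(blocks=raw, seed=seed, output_dir=output_dir)


def log_seed(operation: str, seed: int) -> None:
    """Record the seed of a stochastic operation; never seed silently."""
    logger.info("%s: seed=%d", operation, seed)
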