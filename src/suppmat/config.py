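"""Validated run configuration (YAML file + CLI overrides)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class Config:
    encoder: str = "hashing"
    dim: int = 768
    k: int | None = None
    k_grid: list[int] | None = None
    seed: int = 0
    tau: float = 0.30
    neighbor_n: int = 1000
    archive_depth: int = 3
    archive_ceiling_bytes: int = 1 << 30
    gap_b: int = 20

    def validate(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0,1]")
        if self.neighbor_n < 1 or self.archive_depth < 1:
            raise ValueError("neighbor_n and archive_depth must be >= 1")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> Config:
    """Load YAML config; unknown keys are rejected."""
    if path is None:
        cfg = Config()
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(Config)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
        cfg = Config(**raw)
    cfg.validate()
    return cfg
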