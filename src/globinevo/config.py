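"""Run configuration and seed management.

Every stochastic operation in the package takes an explicit seed; RunConfig
derives per-stage seeds from the master seed so that a whole run is a pure
function of (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml


def derive_seed(master: int, name: str) -> int:
    """Stable per-stage child seed (< 2**31) from a master seed and a tag."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            paths=dict(raw.get("paths", {})),
            params=dict(raw.get("params", {})),
        )
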