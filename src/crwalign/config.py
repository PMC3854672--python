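"""Run configuration: the tunable parameters of both alignment engines.

Defaults follow the published operating point of the method: blocks of
15-20 highly conserved columns (we use 16), a conservation cutoff of 0.80,
a heuristic composition weight of 0.8 (so the maximum block score is
1 + 0.8 = 1.8), a strict-stage score fraction of 0.9 (threshold 1.62) and a
single 20% relaxation (threshold 1.296), 3-10 sequences per statistics
taxon (we use 5), and a taxonomy leaf level of six for the superficial
taxon-selection pass.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import ConfigurationError


@dataclass(frozen=True)
class Config:
    block_size: int = 16  # conserved columns per block
    conservation_cutoff: float = 0.80  # strict: conserved iff C_i > cutoff
    composition_weight: float = 0.8
    score_fraction: float = 0.9  # strict stage: SC >= fraction * max_score
    relaxation_factor: float = 0.8  # one geometric relaxation of the threshold
    min_sequences: int = 5  # per-taxon statistics threshold
    leaf_level: int = 6  # taxonomy depth scanned by the superficial pass
    max_insertions_strict: int = 2  # extra residues between adjacent conserved cols
    max_insertions_relaxed: int = 30
    max_exceptions: int = 0  # structure-search exception budget
    extra_relaxations: int = 0  # additional geometric relaxations (off by default)

    @property
    def max_score(self) -> float:
        """Highest attainable block score (1 + composition weight)."""
        return 1.0 + self.composition_weight

    @property
    def strict_threshold(self) -> float:
        return self.max_score * self.score_fraction

    @property
    def relaxed_threshold(self) -> float:
        return self.strict_threshold * self.relaxation_factor

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Defaults, then file values, then explicit overrides (flags win)."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(Config)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return Config(**values)
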