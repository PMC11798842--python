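"""Run configuration with a master seed and named child seed streams.

Every stochastic stage pulls its seed from the master seed plus a stable
stream name, so a whole experiment reproduces from one integer and any
single stage can be re-seeded independently. Derived seeds stay below
2**31.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(master: int, stream: str) -> int:
    """Deterministic child seed for a named stream (stable across runs)."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML unchanged."""

    # landscape
    n_rows: int = 30
    n_cols: int = 30
    n_surrogate_species: int = 200
    n_target_species: int = 200
    range_size_distribution: tuple = ("lognormal", 1.0, 1.0)
    contiguity: bool = True
    overlap: float = 0.6
    # abiotic layer
    abiotic_correlation: float = 0.0
    missing_fraction: float = 0.12
    # surrogacy runs
    algorithms: tuple = ("ABF", "CAZ")
    n_runs: int = 5
    n_random: int = 100
    # scenario flags
    pe_as_extinct: bool = False
    area_rule: str = "rectangle"
    dynamic_q: bool = True
    pair_optimal: bool = False
    # seeding
    master_seed: int = 0
    # paths
    out_dir: str = "results"

    def seed(self, stream: str) -> int:
        return derive_seed(self.master_seed, stream)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["range_size_distribution"] = list(self.range_size_distribution)
        d["algorithms"] = list(self.algorithms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["range_size_distribution"] = tuple(d["range_size_distribution"])
        d["algorithms"] = tuple(d["algorithms"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
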