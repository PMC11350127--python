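"""Run configuration: one flat, serialisable record of every knob."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    All significance levels are open-interval probabilities; CIM settings
    are in cM.  The record round-trips through YAML unchanged, and its hash
    stamps every output file of a run.
    """

    seed: int = 0
    n_chrom: int = 5
    csl_reps: int = 12
    n_rils: int = 100
    ril_reps: int = 3
    grid_rows: int = 12
    grid_cols: int = 60
    n_blocks: int = 3
    trait: str = "stem_length"
    block_sd: float = 2.0
    surface_amplitude: float = 1.0
    alpha3: float = 5e-5
    alpha2: float = 5e-5
    alpha_bg: float = 1e-3
    alpha_gw: float = 0.05
    cim_step_cm: float = 5.0
    cim_window_cm: float = 50.0
    cim_min_sep_cm: float = 30.0
    run_spatial: bool = True
    run_epistasis: bool = True
    run_linkage: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha3", "alpha2", "alpha_bg", "alpha_gw"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("cim_step_cm", "cim_window_cm", "cim_min_sep_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
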