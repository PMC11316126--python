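"""Run configuration shared by the pipeline and the CLI."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    contact_cutoff: float = 5.0  # A; heavy-atom contact defining a zipper
    min_contacts: int = 5  # contact pairs required per interface
    expansion_radius: float = 30.0  # A; symmetry-expansion sphere
    hbond_cutoff: float = 3.5  # A; backbone N...O sheet criterion
    sasa_points: int = 960  # sphere points per atom
    params_path: str | None = None  # solvation parameter TSV; None = packaged
    divisor_convention: str = "central"  # "central" | "total"
    include_solvent_in_energy: bool = False
    solvent_attach_distance: float = 4.0  # A
    fibril_axis_override: str | None = None  # "a" | "b" | "c"
    keep_alt: str = "A"
    output_format: str = "tsv"  # "tsv" | "json"

    def __post_init__(self):
        for name in ("contact_cutoff", "expansion_radius", "hbond_cutoff",
                     "solvent_attach_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_contacts < 1 or self.sasa_points < 100:
            raise ValueError("min_contacts >= 1 and sasa_points >= 100 required")
        if self.divisor_convention not in ("central", "total"):
            raise ValueError("divisor_convention must be 'central' or 'total'")
        if self.output_format not in ("tsv", "json"):
            raise ValueError("output_format must be 'tsv' or 'json'")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a TOML config file; keyword overrides win."""
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)
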