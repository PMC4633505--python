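"""Analysis configuration: every threshold of the pipeline in one place.

Distance criteria, the population cut, the TSE band, and the mechanism
cutoffs default to the values the analyses are defined with; binning and
stride defaults are package choices.  ``provenance`` marks which is which
for ``--show-config``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class Config:
    hydrophobic_cutoff: float = 6.5     # Å
    electrostatic_cutoff: float = 11.0  # Å
    hbond_cutoff: float = 3.5           # Å
    native_cutoff: float = 7.5          # Å
    population_cut: float = 0.30        # stable-contact fraction (strict >)
    native_stability: float = 0.5       # folded-frame fraction for native set
    site_cutoff: float = 12.0           # Å, binding-site region
    global_cutoff: float = 40.0         # Å, whole molecule
    tse_band: tuple[float, float] = (0.4, 0.6)
    bins: int = 50
    shell_width: float = 2.0            # Å
    delta_bin_width: float = 0.5        # Å
    seed: int = 0
    stride: int = 1
    output_dir: str = "."

    PROVENANCE = {
        "hydrophobic_cutoff": "paper", "electrostatic_cutoff": "paper",
        "hbond_cutoff": "paper", "native_cutoff": "paper",
        "population_cut": "paper", "site_cutoff": "paper",
        "global_cutoff": "paper", "tse_band": "paper",
        "native_stability": "chosen", "bins": "chosen",
        "shell_width": "chosen", "delta_bin_width": "chosen",
        "seed": "chosen", "stride": "chosen", "output_dir": "chosen",
    }

    def validate(self) -> "Config":
        for name in ("hydrophobic_cutoff", "electrostatic_cutoff",
                     "hbond_cutoff", "native_cutoff", "site_cutoff",
                     "global_cutoff", "shell_width", "delta_bin_width"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"{name} must be a positive distance, got {v!r}")
        if not (0 <= self.population_cut <= 1):
            raise ConfigError(f"population_cut outside [0,1]: {self.population_cut}")
        if not (0 < self.native_stability <= 1):
            raise ConfigError(f"native_stability outside (0,1]: {self.native_stability}")
        lo, hi = self.tse_band
        if not (0 < lo <= hi < 1):
            raise ConfigError(f"tse_band must lie inside (0,1): {self.tse_band}")
        if self.stride < 1 or int(self.stride) != self.stride:
            raise ConfigError(f"stride must be a positive integer: {self.stride}")
        if self.bins < 2:
            raise ConfigError(f"bins must be >= 2: {self.bins}")
        return self

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "Config":
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            unknown = set(data) - set(cls.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "tse_band" in data:
            data["tse_band"] = tuple(data["tse_band"])
        return cls(**data).validate()

    def show(self) -> str:
        lines = []
        for k, v in asdict(self).items():
            tag = self.PROVENANCE.get(k, "chosen")
            lines.append(f"{k:22s} = {v!r:20}  [{tag}]")
        return "\n".join(lines)
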