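"""YAML run-configuration loading.

A configuration file has up to four blocks, all optional (reference
defaults fill the gaps)::

    geometry:
      n_subvolumes: 15
      subvolume_height: 100.0e-6   # m
      cross_section: 3000.0e-12    # m^2 (tissue; ECS share is alpha * A_c)
      volume_fraction: 0.2
      tortuosity: 1.6
    ions:                          # concentrations in mol/m^3 (== mM)
      - {name: K, valence: 1, diffusion_constant: 1.96e-9, baseline_concentration: 3.0}
      - ...
    constants:
      temperature: 300.0           # K
    solver:
      dt: 1.0e-4                   # s
      include_diffusion: true
      duration: 5.0                # s
      record_stride: 10
      seed: 0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core import (
    Configuration,
    Geometry,
    IonSet,
    IonSpecies,
    PhysicalConstants,
    default_configuration,
)
from .solver import SolverOptions

__all__ = ["load_config", "RunSettings"]


class RunSettings:
    """Configuration plus solver options plus the generator seed."""

    def __init__(
        self,
        configuration: Configuration,
        options: SolverOptions,
        seed: int = 0,
    ):
        self.configuration = configuration
        self.options = options
        self.seed = seed


def load_config(path: str | Path | None) -> RunSettings:
    """Load a YAML run configuration; missing blocks fall back to defaults."""
    raw = {}
    if path is not None:
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root of {path} must be a mapping")

    default = default_configuration()
    geometry = (
        Geometry(**raw["geometry"]) if "geometry" in raw else default.geometry
    )
    if "ions" in raw:
        ions = IonSet([IonSpecies(**entry) for entry in raw["ions"]])
    else:
        ions = default.ions
    constants = (
        PhysicalConstants(**raw["constants"])
        if "constants" in raw
        else default.constants
    )
    solver = dict(raw.get("solver", {}))
    seed = int(solver.pop("seed", 0))
    options = SolverOptions(**solver) if solver else SolverOptions()
    return RunSettings(Configuration(ions, geometry, constants), options, seed)
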