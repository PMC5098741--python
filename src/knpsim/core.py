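"""Domain types and physical constants shared by the whole package.

The simulated system is a vertical column of neural tissue subdivided into
``N`` box-shaped subvolumes of height ``l_c`` and tissue cross-section
``A_c``.  Only a fraction ``alpha`` of the tissue volume is extracellular
space (ECS), and diffusion through it is hindered by the tortuosity
``lambda`` so that the effective diffusion constant of an ion is
``D / lambda**2``.  The two edge subvolumes act as reservoirs: their ion
concentrations are clamped to baseline values for all time.

All quantities are strict SI internally (m, s, V, A, mol/m^3, S/m).  Since
1 mM == 1 mol/m^3, concentrations can be read directly as millimolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "IonSpecies",
    "IonSet",
    "Geometry",
    "PhysicalConstants",
    "ECSState",
    "Configuration",
    "default_configuration",
    "electroneutral_anion_concentration",
    "charge_density",
    "baseline_state",
]

#: Faraday's constant, C/mol.
FARADAY = 96485.0
#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species with its valence, mobility and resting level.

    Parameters
    ----------
    name
        Short label, e.g. ``"K"`` or ``"X"``.
    valence
        Signed integer charge number ``z`` (nonzero).
    diffusion_constant
        Free-solution diffusion coefficient ``D`` in m^2/s.  Tortuosity is
        *not* folded in here; every transport formula applies the factor
        ``1/lambda**2`` explicitly.
    baseline_concentration
        Resting ECS concentration ``c0`` in mol/m^3 (= mM).
    """

    name: str
    valence: int
    diffusion_constant: float
    baseline_concentration: float

    def __post_init__(self) -> None:
        if int(self.valence) != self.valence or self.valence == 0:
            raise ValueError(f"valence of {self.name!r} must be a nonzero integer")
        if not self.diffusion_constant > 0:
            raise ValueError(f"diffusion constant of {self.name!r} must be > 0")
        if self.baseline_concentration < 0:
            raise ValueError(f"baseline concentration of {self.name!r} must be >= 0")


class IonSet:
    """An ordered collection of :class:`IonSpecies` with unique names.

    Provides array views (``valences``, ``diffusion_constants``,
    ``baseline_concentrations``) used throughout the numerics.
    """

    def __init__(self, species: Sequence[IonSpecies]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("ion names must be unique")
        self._species = tuple(species)
        self.names: tuple[str, ...] = tuple(names)
        self.valences = np.array([s.valence for s in species], dtype=float)
        self.diffusion_constants = np.array(
            [s.diffusion_constant for s in species], dtype=float
        )
        self.baseline_concentrations = np.array(
            [s.baseline_concentration for s in species], dtype=float
        )

    def __len__(self) -> int:
        return len(self._species)

    def __iter__(self) -> Iterator[IonSpecies]:
        return iter(self._species)

    def __getitem__(self, name: str) -> IonSpecies:
        for s in self._species:
            if s.name == name:
                return s
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def without(self, name: str) -> "IonSet":
        """A new set with species ``name`` removed."""
        return IonSet([s for s in self._species if s.name != name])

    def concentrations_from(self, mapping: Mapping[str, float]) -> np.ndarray:
        """Per-ion concentration vector from a name->value mapping.

        Species absent from the mapping default to their baseline.
        """
        unknown = set(mapping) - set(self.names)
        if unknown:
            raise KeyError(f"unknown ion name(s): {sorted(unknown)}")
        return np.array(
            [mapping.get(s.name, s.baseline_concentration) for s in self._species]
        )

    def __repr__(self) -> str:
        return f"IonSet({', '.join(self.names)})"


@dataclass(frozen=True)
class Geometry:
    """The discretized 1D porous-medium column.

    ``cross_section`` is the *tissue* cross-section; the ECS cross-section
    available to transport is ``volume_fraction * cross_section``.
    """

    n_subvolumes: int = 15
    subvolume_height: float = 100e-6
    cross_section: float = 3000e-12
    volume_fraction: float = 0.2
    tortuosity: float = 1.6

    def __post_init__(self) -> None:
        if self.n_subvolumes < 3:
            raise ValueError("need at least 3 subvolumes (two reservoirs + interior)")
        if self.subvolume_height <= 0 or self.cross_section <= 0:
            raise ValueError("subvolume height and cross-section must be > 0")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume fraction must be in (0, 1]")
        if self.tortuosity < 1:
            raise ValueError("tortuosity must be >= 1")

    @property
    def ecs_cross_section(self) -> float:
        """ECS cross-section alpha*A_c (m^2)."""
        return self.volume_fraction * self.cross_section

    @property
    def ecs_subvolume_volume(self) -> float:
        """ECS volume of one subvolume, alpha*A_c*l_c (m^3)."""
        return self.ecs_cross_section * self.subvolume_height

    @property
    def n_interfaces(self) -> int:
        return self.n_subvolumes - 1


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday/gas constants plus the (configurable) absolute temperature."""

    faraday: float = FARADAY
    gas_constant: float = GAS_CONSTANT
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def psi(self) -> float:
        """Thermal voltage RT/F (V); always derived, never stored."""
        return self.gas_constant * self.temperature / self.faraday


@dataclass
class ECSState:
    """Concentrations and potential of the whole column at one instant.

    ``concentrations`` has shape ``(n_ions, n_subvolumes)``; ``potential``
    has shape ``(n_subvolumes,)`` or is ``None`` before the first Kirchhoff
    solve.  ``potential[0] == 0`` whenever it has been solved (reference
    subvolume).
    """

    concentrations: np.ndarray
    potential: np.ndarray | None = None
    time: float = 0.0

    def copy(self) -> "ECSState":
        return ECSState(
            self.concentrations.copy(),
            None if self.potential is None else self.potential.copy(),
            self.time,
        )


class Configuration(NamedTuple):
    """Bundle of ion set, geometry and constants defining one model setup."""

    ions: IonSet
    geometry: Geometry
    constants: PhysicalConstants


def default_configuration(temperature: float = 300.0) -> Configuration:
    """The reference configuration of the 15-subvolume cortical column.

    K+, Na+, Ca2+ and an unspecified anion X- (standing in for Cl-) at
    cerebrospinal-fluid baseline levels; the X- baseline is chosen so the
    bulk is exactly electroneutral.  Column of 15 boxes, 100 um high, tissue
    cross-section 3000 um^2, ECS volume fraction 0.2 (ECS cross-section
    600 um^2), tortuosity 1.6.
    """
    ions = IonSet(
        [
            IonSpecies("K", 1, 1.96e-9, 3.0),
            IonSpecies("Na", 1, 1.33e-9, 150.0),
            IonSpecies("Ca", 2, 0.71e-9, 1.4),
            IonSpecies("X", -1, 2.03e-9, 155.8),
        ]
    )
    return Configuration(ions, Geometry(), PhysicalConstants(temperature=temperature))


def electroneutral_anion_concentration(ions: IonSet) -> float:
    """Concentration of a monovalent anion that neutralizes ``ions``.

    Given a set with net positive baseline charge, returns the
    concentration ``c`` such that adding one species with valence -1 at
    concentration ``c`` makes ``sum(z_k * c_k) == 0``.

    Raises
    ------
    ValueError
        If the remaining set has no net positive charge to neutralize.
    """
    net = float(np.dot(ions.valences, ions.baseline_concentrations))
    if net <= 0:
        raise ValueError(
            "remaining ions carry no net positive charge; a monovalent anion "
            f"cannot neutralize a net charge of {net} mol/m^3"
        )
    return net


def charge_density(state: ECSState, ions: IonSet) -> np.ndarray:
    """Per-subvolume charge density rho_n = F * sum_k z_k c_n^k (C/m^3)."""
    conc = np.asarray(state.concentrations, dtype=float)
    if conc.shape[0] != len(ions):
        raise ValueError(
            f"state has {conc.shape[0]} ion rows but the ion set has {len(ions)}"
        )
    return FARADAY * (ions.valences[:, None] * conc).sum(axis=0)


def baseline_state(ions: IonSet, geometry: Geometry, time: float = 0.0) -> ECSState:
    """Uniform state with every subvolume at baseline concentrations."""
    conc = np.tile(
        ions.baseline_concentrations[:, None], (1, geometry.n_subvolumes)
    )
    return ECSState(concentrations=conc, potential=None, time=time)
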