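"""Transmembrane source time series: import, validation and synthesis.

The KNP solver consumes, per ECS subvolume, the time series of transmembrane
ionic fluxes ``J^kM_n(t)`` (mol/s, positive into the ECS) and the capacitive
membrane current ``I^cap_n(t)`` (A).  In the hybrid workflow these come from
a compartmental neuron simulator: per-segment channel current densities are
multiplied by segment membrane area, grouped by carrier ion, divided by
``z_k F`` and binned by the depth of the segment midpoint
(:func:`map_segment_currents`).

Since no neuron simulator is bundled, :func:`generate_population_sources`
synthesizes a statistically similar population drive: a handful of neurons
firing Poisson action-potential trains, each AP depositing a biphasic
Na+-influx / K+-efflux pulse pair into the soma subvolume, with slow anion
and Ca2+ background fluxes over the dendritic depth span and a distributed
capacitive return current that closes each neuron's current loop exactly, so
the depth-summed total transmembrane current is identically zero at every
sample — the property the Kirchhoff potential solve relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .core import FARADAY, Geometry, IonSet
from .solver import SourceSample

__all__ = [
    "SourceSeries",
    "SegmentCurrentTable",
    "PopulationParams",
    "ValidationReport",
    "map_segment_currents",
    "generate_population_sources",
    "validate_sources",
    "write_source_series",
    "read_source_series",
]


@dataclass
class SourceSeries:
    """Uniformly sampled per-subvolume transmembrane sources.

    ``ion_fluxes`` has shape ``(M, K, N)`` (mol/s), ``capacitive_current``
    ``(M, N)`` (A), on the uniform grid ``times`` (s).
    """

    times: np.ndarray
    ion_fluxes: np.ndarray
    capacitive_current: np.ndarray
    ion_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) < 1:
            raise ValueError("need at least one sample")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
                raise ValueError("times must form a uniform, increasing grid")

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.inf

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def sample(self, i: int) -> SourceSample:
        return SourceSample(self.ion_fluxes[i], self.capacitive_current[i])

    def total_current(self, ions: IonSet, faraday: float = FARADAY) -> np.ndarray:
        """Depth-summed total transmembrane current per sample (A)."""
        ionic = faraday * (
            ions.valences[None, :, None] * self.ion_fluxes
        ).sum(axis=(1, 2))
        return ionic + self.capacitive_current.sum(axis=1)


@dataclass
class SegmentCurrentTable:
    """Per-segment membrane current densities with a channel->ion mapping.

    Columns: ``segment_id``, ``subvolume`` (1-based, interior only),
    ``area`` (m^2), ``channel`` key, ``density`` (A/m^2, positive outward).
    ``channel_ion_map`` sends each channel key to an ion name of the working
    ion set, or to ``"cap"`` for capacitive current densities.
    """

    segment_id: np.ndarray
    subvolume: np.ndarray
    area: np.ndarray
    channel: np.ndarray
    density: np.ndarray
    channel_ion_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.area, dtype=float) <= 0):
            raise ValueError("segment areas must be > 0")


@dataclass
class PopulationParams:
    """Knobs of the synthetic population-source generator.

    Defaults emulate the reference scenario: 10 pyramidal-like neurons
    firing ~5 APs/s each, somata in subvolume 3, per-AP Na+/K+ pulse
    amplitudes of -30/+30 nA, dendrites spanning subvolumes 3..14.
    """

    n_neurons: int = 10
    firing_rate: float = 5.0          # APs per second per neuron
    soma_subvolume: int = 3           # 1-based
    na_peak: float = -30e-9           # A, per-AP Na+ pulse peak (inward)
    k_peak: float = 30e-9             # A, per-AP K+ pulse peak (outward)
    na_width: float = 0.5e-3          # s, alpha-kernel time constant
    k_width: float = 1.0e-3           # s
    k_offset: float = 0.5e-3          # s, delay of the K+ pulse after the Na+ pulse
    dendrite_span: tuple[int, int] = (3, 14)  # 1-based inclusive
    x_background: float = 0.5e-9      # A, slow X- current scale per neuron
    ca_background: float = 0.05e-9    # A, slow Ca2+ current scale per neuron
    background_tau: float = 50e-3     # s, correlation time of background drive
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("na_peak", "k_peak", "x_background", "ca_background"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _alpha_kernel(dt: float, tau: float, n_tau: float = 8.0) -> np.ndarray:
    """Unit-peak alpha function (t/tau)*exp(1 - t/tau) sampled at dt."""
    t = np.arange(0.0, n_tau * tau, dt)
    return (t / tau) * np.exp(1.0 - t / tau)


def map_segment_currents(
    table: SegmentCurrentTable, geometry: Geometry, ions: IonSet
) -> SourceSample:
    """Collapse a per-segment current table into per-subvolume sources.

    Each segment's current (density x area) is assigned to the subvolume of
    its midpoint and converted to an ion flux via ``J = i A / (z_k F)`` —
    the valence in the denominator halves Ca2+ currents and flips the sign
    for the anion.  Channels mapped to ``"cap"`` are summed as capacitive
    current.
    """
    jm = np.zeros((len(ions), geometry.n_subvolumes))
    icap = np.zeros(geometry.n_subvolumes)
    sub = np.asarray(table.subvolume, dtype=int)
    if np.any((sub < 2) | (sub > geometry.n_subvolumes - 1)):
        bad = sub[(sub < 2) | (sub > geometry.n_subvolumes - 1)]
        raise ValueError(
            f"segment subvolume index {bad[0]} outside interior range "
            f"2..{geometry.n_subvolumes - 1}"
        )
    currents = np.asarray(table.density, dtype=float) * np.asarray(
        table.area, dtype=float
    )
    for chan, n, cur in zip(table.channel, sub, currents):
        try:
            target = table.channel_ion_map[str(chan)]
        except KeyError:
            raise KeyError(f"channel {chan!r} has no ion mapping") from None
        if target == "cap":
            icap[n - 1] += cur
        else:
            k = ions.index(target)
            jm[k, n - 1] += cur / (ions.valences[k] * FARADAY)
    return SourceSample(jm, icap)


def generate_population_sources(
    params: PopulationParams,
    duration: float,
    sample_dt: float = 1e-4,
    geometry: Geometry | None = None,
    ions: IonSet | None = None,
) -> SourceSeries:
    """Seeded synthetic population drive (see module docstring).

    Deterministic given ``params.seed``.  The depth-summed total current
    (ionic + capacitive) is zero by construction at every sample.
    """
    if duration <= 0 or sample_dt <= 0:
        raise ValueError("duration and sample_dt must be > 0")
    from .core import default_configuration

    if geometry is None or ions is None:
        default = default_configuration()
        geometry = geometry or default.geometry
        ions = ions or default.ions

    n = geometry.n_subvolumes
    soma = params.soma_subvolume
    lo, hi = params.dendrite_span
    if not (2 <= soma <= n - 1) or not (2 <= lo <= hi <= n - 1):
        raise ValueError("soma and dendrite subvolumes must be interior")

    m = int(round(duration / sample_dt)) + 1
    times = np.arange(m) * sample_dt
    k_ions = len(ions)
    jm = np.zeros((m, k_ions, n))
    icap = np.zeros((m, n))

    i_k, i_na = ions.index("K"), ions.index("Na")
    i_ca, i_x = ions.index("Ca"), ions.index("X")
    z = ions.valences

    na_kernel = _alpha_kernel(sample_dt, params.na_width)
    k_kernel = _alpha_kernel(sample_dt, params.k_width)
    k_shift = int(round(params.k_offset / sample_dt))
    span = np.arange(lo - 1, hi)          # 0-based dendritic subvolumes
    w_span = np.full(len(span), 1.0 / len(span))

    rng = np.random.default_rng(params.seed)
    i_na_soma = np.zeros(m)
    i_k_soma = np.zeros(m)
    i_x_dend = np.zeros(m)
    i_ca_dend = np.zeros(m)

    decay = np.exp(-sample_dt / params.background_tau)
    for _ in range(params.n_neurons):
        spikes = np.zeros(m)
        n_ap = rng.poisson(params.firing_rate * duration)
        if n_ap > 0 and params.firing_rate > 0:
            idx = np.floor(rng.uniform(0, duration, size=n_ap) / sample_dt)
            np.add.at(spikes, idx.astype(int), 1.0)
        i_na_soma += params.na_peak * np.convolve(spikes, na_kernel)[:m]
        kk = params.k_peak * np.convolve(spikes, k_kernel)[:m]
        if k_shift:
            kk = np.concatenate([np.zeros(k_shift), kk[: m - k_shift]])
        i_k_soma += kk

        # slow, low-pass filtered background drives (one AR(1) track each)
        for amp, acc in ((params.x_background, i_x_dend),
                         (params.ca_background, i_ca_dend)):
            white = rng.standard_normal(m) * np.sqrt(1 - decay**2)
            white[0] += decay * rng.standard_normal()
            track = lfilter([1.0], [1.0, -decay], white)
            acc += amp * track

    jm[:, i_na, soma - 1] = i_na_soma / (z[i_na] * FARADAY)
    jm[:, i_k, soma - 1] = i_k_soma / (z[i_k] * FARADAY)
    jm[:, i_x, span] = (i_x_dend / (z[i_x] * FARADAY))[:, None] * w_span
    jm[:, i_ca, span] = (i_ca_dend / (z[i_ca] * FARADAY))[:, None] * w_span

    # capacitive return: close the population current loop exactly
    total_ionic = FARADAY * (z[None, :, None] * jm).sum(axis=(1, 2))
    icap[:, span] = -total_ionic[:, None] * w_span
    return SourceSeries(times, jm, icap, ions.names)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_sources` (reports, never raises)."""

    passed: bool
    worst_depth_sum: float      # A, worst |depth-summed total current|
    worst_edge_value: float     # worst |source| in an edge subvolume
    all_finite: bool
    messages: list[str] = field(default_factory=list)


def validate_sources(
    series: SourceSeries,
    ions: IonSet,
    tolerance: float = 1e-12,
) -> ValidationReport:
    """Check the invariants the solver relies on.

    Edge subvolumes must carry no sources, every sample must be finite, and
    the depth-summed total transmembrane current (ionic + capacitive) must
    vanish within ``tolerance`` (A) at every sample.
    """
    messages: list[str] = []
    finite = bool(
        np.all(np.isfinite(series.ion_fluxes))
        and np.all(np.isfinite(series.capacitive_current))
    )
    if not finite:
        messages.append("non-finite source values present")

    edge = max(
        np.abs(series.ion_fluxes[:, :, [0, -1]]).max(initial=0.0) * FARADAY,
        np.abs(series.capacitive_current[:, [0, -1]]).max(initial=0.0),
    )
    if edge > tolerance:
        messages.append(
            f"edge subvolumes carry sources (worst {edge:.3e} A-equivalent)"
        )

    depth = series.total_current(ions)
    worst_idx = int(np.argmax(np.abs(depth))) if len(depth) else 0
    worst = float(np.abs(depth).max(initial=0.0))
    if worst > tolerance:
        messages.append(
            f"depth-summed total current is {depth[worst_idx]:.3e} A at "
            f"t={series.times[worst_idx]:.6g} s (tolerance {tolerance:.1e} A)"
        )
    return ValidationReport(
        passed=finite and edge <= tolerance and worst <= tolerance,
        worst_depth_sum=worst,
        worst_edge_value=float(edge),
        all_finite=finite,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Text I/O: long format `time  subvolume  species  value`, species "cap" for
# the capacitive current.  This is also the import path for currents exported
# from an external neuron simulator.


def write_source_series(series: SourceSeries, path: str | Path) -> None:
    path = Path(path)
    m, k, n = series.ion_fluxes.shape
    with path.open("w") as fh:
        fh.write("# time_s\tsubvolume\tspecies\tvalue\n")
        fh.write("# species value units: ion -> mol/s, cap -> A\n")
        for i, t in enumerate(series.times):
            for ki, name in enumerate(series.ion_names):
                for ni in range(n):
                    val = series.ion_fluxes[i, ki, ni]
                    if val != 0.0:
                        fh.write(f"{t:.9g}\t{ni + 1}\t{name}\t{val:.17g}\n")
            for ni in range(n):
                val = series.capacitive_current[i, ni]
                if val != 0.0:
                    fh.write(f"{t:.9g}\t{ni + 1}\tcap\t{val:.17g}\n")


def read_source_series(
    path: str | Path, ions: IonSet, geometry: Geometry
) -> SourceSeries:
    """Read a long-format source file (see :func:`write_source_series`).

    The time grid is reconstructed from the distinct time stamps and must
    be uniform; omitted (time, subvolume, species) entries are zero.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t_s, sub_s, species, val_s = line.split("\t")
            rows.append((float(t_s), int(sub_s), species, float(val_s)))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    times = np.unique([r[0] for r in rows])
    t_index = {t: i for i, t in enumerate(times)}
    m, k, n = len(times), len(ions), geometry.n_subvolumes
    jm = np.zeros((m, k, n))
    icap = np.zeros((m, n))
    for t, sub, species, val in rows:
        if not 1 <= sub <= n:
            raise ValueError(f"subvolume {sub} outside 1..{n}")
        if species == "cap":
            icap[t_index[t], sub - 1] = val
        else:
            jm[t_index[t], ions.index(species), sub - 1] = val
    return SourceSeries(times, jm, icap, ions.names)
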