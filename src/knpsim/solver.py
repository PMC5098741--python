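"""Kirchhoff-Nernst-Planck numerical core.

Per-interface Nernst-Planck fluxes (diffusive and field-driven), the
concentration-dependent electrolyte conductivity, the tridiagonal Kirchhoff
current-law system for the extracellular potential, and explicit
forward-Euler time stepping of the ECS ion concentrations.

Discretization and conventions
------------------------------
Subvolumes are indexed ``n = 1..N`` in the physics (0-based in arrays);
interface ``(n-1, n)`` separates subvolume ``n-1`` from ``n`` and positive
fluxes/currents point in the +z direction (toward larger ``n``).

For each interface, with effective diffusion constant ``D/lambda**2``,
ECS cross-section ``alpha*A_c`` and thermal voltage ``psi = RT/F``::

    J_d = -(alpha*A_c/l_c) * (D/lambda^2) * (c_n - c_{n-1})                 (mol/s)
    J_f = -(alpha*A_c/(psi*l_c)) * z * (D/lambda^2) * c_mid * (V_n-V_{n-1}) (mol/s)
    I_d = F * sum_k z_k J_d^k,  I_f = F * sum_k z_k J_f^k                   (A)
    sigma = (F/psi) * sum_k (D_k z_k^2 / lambda^2) * c_mid^k                (S/m)

with ``c_mid`` the arithmetic mean of the two neighbor concentrations.

The potential is obtained from Kirchhoff's current law: the sum of all
currents into each interior subvolume (transmembrane ionic + capacitive +
diffusive + field) is zero; subvolume 1 is the reference (``V_1 = 0``) and
no net electrical current crosses the top boundary interface
(``I_d + I_f = 0`` between ``N-1`` and ``N``).  This yields a tridiagonal
linear system solved exactly each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.linalg import solve_banded

from .core import (
    Configuration,
    ECSState,
    Geometry,
    IonSet,
    PhysicalConstants,
    baseline_state,
)

__all__ = [
    "InterfaceQuantities",
    "PotentialSystem",
    "SolverOptions",
    "SourceSample",
    "Trajectory",
    "interface_conductivity",
    "apparent_conductivity",
    "diffusive_fluxes",
    "field_fluxes",
    "diffusive_currents",
    "field_currents",
    "compute_interface_quantities",
    "assemble_potential_system",
    "solve_potential",
    "step_concentrations",
    "run_simulation",
]


class SourceSample(NamedTuple):
    """Transmembrane sources for one instant.

    ``ion_fluxes`` has shape ``(n_ions, n_subvolumes)`` in mol/s (flux of
    each ion *into* the ECS subvolume); ``capacitive_current`` has shape
    ``(n_subvolumes,)`` in A.
    """

    ion_fluxes: np.ndarray
    capacitive_current: np.ndarray

    def ionic_current(self, ions: IonSet, faraday: float = 96485.0) -> np.ndarray:
        """Net ionic transmembrane current I^M_n = F sum_k z_k J^kM_n (A)."""
        return faraday * (ions.valences[:, None] * self.ion_fluxes).sum(axis=0)

    @staticmethod
    def zeros(n_ions: int, n_subvolumes: int) -> "SourceSample":
        return SourceSample(
            np.zeros((n_ions, n_subvolumes)), np.zeros(n_subvolumes)
        )


@dataclass
class InterfaceQuantities:
    """Per-interface fluxes, currents and conductivities at one instant.

    All arrays are indexed by interface (length ``N-1``); flux arrays have
    a leading ion axis.
    """

    diffusive_flux: np.ndarray  # (K, N-1), mol/s
    field_flux: np.ndarray      # (K, N-1), mol/s
    diffusive_current: np.ndarray  # (N-1,), A
    field_current: np.ndarray      # (N-1,), A
    conductivity: np.ndarray       # (N-1,), S/m


@dataclass
class PotentialSystem:
    """The tridiagonal Kirchhoff system ``A V = b``."""

    matrix: np.ndarray  # (N, N) tridiagonal
    rhs: np.ndarray     # (N,)

    def banded(self) -> np.ndarray:
        """The (3, N) diagonal-ordered form used by banded solvers."""
        n = self.matrix.shape[0]
        ab = np.zeros((3, n))
        ab[0, 1:] = np.diagonal(self.matrix, 1)
        ab[1, :] = np.diagonal(self.matrix)
        ab[2, :-1] = np.diagonal(self.matrix, -1)
        return ab


@dataclass
class SolverOptions:
    """Time-stepping options.

    dt
        Euler step (s).  Must satisfy the explicit-diffusion stability
        bound ``max_k(D_k/lambda^2) * dt / l_c^2 < 0.5``; with the default
        geometry (l_c = 100 um) the default step of 0.1 ms has a stability
        margin of roughly 1e5.
    include_diffusion
        When ``False``, diffusive fluxes are removed from the continuity
        equation and diffusive currents from the potential equation; the
        concentration dependence of the conductivity is retained.
    duration
        Total simulated time (s).
    record_stride
        Record every ``record_stride``-th step (step 0 included).
    freeze_conductivity
        Peg sigma at its initial-state value for the whole run (used to
        isolate conductivity-drift effects when comparing runs).
    """

    dt: float = 1e-4
    include_diffusion: bool = True
    duration: float = 1.0
    record_stride: int = 10
    freeze_conductivity: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def check_stability(self, ions: IonSet, geometry: Geometry) -> None:
        d_eff = ions.diffusion_constants.max() / geometry.tortuosity**2
        number = d_eff * self.dt / geometry.subvolume_height**2
        if number >= 0.5:
            raise ValueError(
                f"dt={self.dt} violates the explicit-diffusion stability bound: "
                f"D_eff*dt/l_c^2 = {number:.3g} >= 0.5"
            )


@dataclass
class Trajectory:
    """Decimated record of a simulation run.

    ``concentrations`` has shape ``(S, K, N)``; ``potential`` ``(S, N)``;
    the per-interface arrays ``(S, N-1)`` (with ion axis for fluxes).
    """

    times: np.ndarray
    concentrations: np.ndarray
    potential: np.ndarray
    diffusive_flux: np.ndarray   # (S, K, N-1)
    field_flux: np.ndarray       # (S, K, N-1)
    diffusive_current: np.ndarray
    field_current: np.ndarray
    conductivity: np.ndarray
    ion_names: tuple[str, ...]
    worst_kirchhoff_residual: float = 0.0

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> ECSState:
        return ECSState(
            self.concentrations[i].copy(),
            self.potential[i].copy(),
            float(self.times[i]),
        )


# ---------------------------------------------------------------------------
# Interface quantities


def interface_conductivity(
    c_left: np.ndarray,
    c_right: np.ndarray,
    ions: IonSet,
    constants: PhysicalConstants,
    geometry: Geometry,
) -> np.ndarray | float:
    """Electrolyte conductivity between two neighbor subvolumes (S/m).

    ``sigma = (F/psi) * sum_k (D_k z_k^2 / lambda^2) * (c_left + c_right)/2``.
    Accepts per-ion vectors ``(K,)`` (returns a scalar) or arrays ``(K, M)``
    (returns ``(M,)``).
    """
    c_left = np.asarray(c_left, dtype=float)
    c_right = np.asarray(c_right, dtype=float)
    if np.any(c_left < 0) or np.any(c_right < 0):
        raise ValueError("concentrations must be >= 0")
    weight = ions.diffusion_constants * ions.valences**2 / geometry.tortuosity**2
    mid = 0.5 * (c_left + c_right)
    shaped = weight if mid.ndim == 1 else weight[:, None]
    sigma = (constants.faraday / constants.psi) * (shaped * mid).sum(axis=0)
    return float(sigma) if np.ndim(sigma) == 0 else sigma


def apparent_conductivity(sigma: float, geometry: Geometry) -> float:
    """Apparent tissue conductivity sigma' = alpha * sigma (S/m).

    Rescales the ECS conductivity to the whole tissue as reference volume,
    the convention used when comparing against bulk-tissue measurements.
    """
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("conductivity must be >= 0")
    return geometry.volume_fraction * sigma


def _conductivities(state, ions, constants, geometry) -> np.ndarray:
    c = state.concentrations
    return interface_conductivity(c[:, :-1], c[:, 1:], ions, constants, geometry)


def diffusive_fluxes(
    state: ECSState, ions: IonSet, geometry: Geometry
) -> np.ndarray:
    """Fickian interface fluxes J^kd (mol/s), shape ``(K, N-1)``.

    Positive values point toward larger subvolume index.
    """
    c = state.concentrations
    pref = geometry.ecs_cross_section / geometry.subvolume_height
    d_eff = ions.diffusion_constants[:, None] / geometry.tortuosity**2
    return -pref * d_eff * (c[:, 1:] - c[:, :-1])


def field_fluxes(
    state: ECSState,
    ions: IonSet,
    constants: PhysicalConstants,
    geometry: Geometry,
) -> np.ndarray:
    """Drift (field-driven) interface fluxes J^kf (mol/s), shape ``(K, N-1)``."""
    if state.potential is None:
        raise ValueError("state has no solved potential")
    c = state.concentrations
    v = state.potential
    pref = geometry.ecs_cross_section / (constants.psi * geometry.subvolume_height)
    d_eff = ions.diffusion_constants[:, None] / geometry.tortuosity**2
    cmid = 0.5 * (c[:, 1:] + c[:, :-1])
    return -pref * ions.valences[:, None] * d_eff * cmid * (v[1:] - v[:-1])


def diffusive_currents(
    state: ECSState, ions: IonSet, geometry: Geometry, faraday: float = 96485.0
) -> np.ndarray:
    """Net diffusive interface currents I^d = F sum_k z_k J^kd (A)."""
    jd = diffusive_fluxes(state, ions, geometry)
    return faraday * (ions.valences[:, None] * jd).sum(axis=0)


def field_currents(
    state: ECSState,
    ions: IonSet,
    constants: PhysicalConstants,
    geometry: Geometry,
) -> np.ndarray:
    """Net field-driven interface currents I^f = F sum_k z_k J^kf (A)."""
    jf = field_fluxes(state, ions, constants, geometry)
    return constants.faraday * (ions.valences[:, None] * jf).sum(axis=0)


def compute_interface_quantities(
    state: ECSState,
    ions: IonSet,
    constants: PhysicalConstants,
    geometry: Geometry,
    include_diffusion: bool = True,
    sigma: np.ndarray | None = None,
) -> InterfaceQuantities:
    """All per-interface quantities for one state (potential must be solved)."""
    jd = diffusive_fluxes(state, ions, geometry)
    if not include_diffusion:
        jd = np.zeros_like(jd)
    jf = field_fluxes(state, ions, constants, geometry)
    zf = constants.faraday * ions.valences[:, None]
    if sigma is None:
        sigma = _conductivities(state, ions, constants, geometry)
    return InterfaceQuantities(
        diffusive_flux=jd,
        field_flux=jf,
        diffusive_current=(zf * jd).sum(axis=0),
        field_current=(zf * jf).sum(axis=0),
        conductivity=np.asarray(sigma, dtype=float),
    )


# ---------------------------------------------------------------------------
# Potential system


def assemble_potential_system(
    state: ECSState,
    ions: IonSet,
    source_sample: SourceSample,
    options: SolverOptions,
    geometry: Geometry,
    constants: PhysicalConstants,
    sigma: np.ndarray | None = None,
) -> PotentialSystem:
    """Build the tridiagonal Kirchhoff system for the potential.

    Row 1 pins the reference ``V_1 = 0``.  Interior rows balance field
    currents against transmembrane and diffusive currents::

        sigma_{n-1,n} V_{n-1} - (sigma_{n-1,n}+sigma_{n,n+1}) V_n
            + sigma_{n,n+1} V_{n+1}
          = (l_c/(alpha A_c)) (-I^cap_n - I^M_n - I^d_{n-1,n} + I^d_{n,n+1})

    The last row imposes zero net electrical current through the top
    boundary interface (``I^d + I^f = 0`` there), i.e.
    ``sigma_{N-1,N}(V_{N-1} - V_N) = -(l_c/(alpha A_c)) I^d_{N-1,N}``.
    With diffusion off, all ``I^d`` terms are zero while the concentration
    dependence of sigma is retained.
    """
    n = geometry.n_subvolumes
    if sigma is None:
        sigma = _conductivities(state, ions, constants, geometry)
    sigma = np.asarray(sigma, dtype=float)
    if not np.any(sigma > 0):
        raise ValueError("all interface conductivities are zero: singular system")

    if options.include_diffusion:
        i_d = diffusive_currents(state, ions, geometry, constants.faraday)
    else:
        i_d = np.zeros(geometry.n_interfaces)
    i_m = source_sample.ionic_current(ions, constants.faraday)
    i_cap = np.asarray(source_sample.capacitive_current, dtype=float)

    scale = geometry.subvolume_height / geometry.ecs_cross_section
    a = np.zeros((n, n))
    b = np.zeros(n)
    a[0, 0] = 1.0
    for row in range(1, n - 1):
        a[row, row - 1] = sigma[row - 1]
        a[row, row] = -(sigma[row - 1] + sigma[row])
        a[row, row + 1] = sigma[row]
        b[row] = scale * (
            -i_cap[row] - i_m[row] - i_d[row - 1] + i_d[row]
        )
    a[n - 1, n - 2] = sigma[n - 2]
    a[n - 1, n - 1] = -sigma[n - 2]
    b[n - 1] = -scale * i_d[n - 2]
    return PotentialSystem(matrix=a, rhs=b)


def solve_potential(system: PotentialSystem) -> np.ndarray:
    """Exact solution of the tridiagonal system (direct banded elimination)."""
    try:
        v = solve_banded((1, 1), system.banded(), system.rhs)
    except np.linalg.LinAlgError as err:  # pragma: no cover - scipy raises ValueError
        raise ValueError("singular potential system") from err
    if not np.all(np.isfinite(v)):
        raise ValueError("singular potential system")
    return v


# ---------------------------------------------------------------------------
# Time stepping


def step_concentrations(
    state: ECSState,
    interfaces: InterfaceQuantities,
    source_sample: SourceSample,
    options: SolverOptions,
    geometry: Geometry,
) -> ECSState:
    """One forward-Euler update of the interior concentrations.

    Edge subvolumes are reservoirs and never change.  Raises if any updated
    concentration goes negative (a symptom of a too-large time step or
    unphysical sources) naming the offending subvolume, ion and time.
    """
    c = state.concentrations
    net = interfaces.diffusive_flux + interfaces.field_flux
    inflow = net[:, :-1] - net[:, 1:]
    vol = geometry.ecs_subvolume_volume
    new_c = c.copy()
    new_c[:, 1:-1] += options.dt * (
        source_sample.ion_fluxes[:, 1:-1] + inflow
    ) / vol
    if np.any(new_c < 0):
        k, n = np.unravel_index(np.argmin(new_c), new_c.shape)
        raise ValueError(
            f"negative concentration ({new_c[k, n]:.3e} mol/m^3) for ion index "
            f"{k} in subvolume {n + 1} at t={state.time + options.dt:.6g} s; "
            "reduce dt or check the sources"
        )
    return ECSState(new_c, state.potential, state.time + options.dt)


def _kirchhoff_residual(i_d, i_f, i_m, i_cap) -> float:
    """Worst relative interior net-current residual (correctness telemetry).

    Normalized by the largest individual current magnitude so that the
    relative tolerance is meaningful even when the components cancel (as
    they do exactly in source-free runs).
    """
    i_tot = i_d + i_f
    net = -i_cap[1:-1] - i_m[1:-1] - i_tot[:-1] + i_tot[1:]
    scale = max(
        np.abs(i_d).max(), np.abs(i_f).max(),
        np.abs(i_m).max(), np.abs(i_cap).max(), 1e-300,
    )
    return float(np.abs(net).max() / scale)


def run_simulation(
    config: Configuration,
    sources=None,
    options: SolverOptions | None = None,
    initial_state: ECSState | None = None,
) -> Trajectory:
    """Run the KNP scheme and record a decimated trajectory.

    Per step: (1) conductivities and diffusive currents from the current
    concentrations, (2) assemble and solve the Kirchhoff potential system
    with the current source sample, (3) drift fluxes from the solved
    potential, (4) forward-Euler concentration update.  The state recorded
    at each sample time carries the potential solved *at* that time, so the
    very first record already reflects the initial concentration profile.

    Parameters
    ----------
    config
        ``(ions, geometry, constants)`` bundle.
    sources
        A :class:`~knpsim.sources.SourceSeries`, or ``None`` for a
        source-free run.  Samples are applied with zero-order hold when the
        solver step is finer than the source sampling interval.
    options
        :class:`SolverOptions`; defaults used when omitted.
    initial_state
        Starting :class:`~knpsim.core.ECSState`; baseline everywhere when
        omitted.
    """
    ions, geometry, constants = config
    options = options or SolverOptions()
    options.check_stability(ions, geometry)

    k, n = len(ions), geometry.n_subvolumes
    state = (initial_state or baseline_state(ions, geometry)).copy()
    if state.concentrations.shape != (k, n):
        raise ValueError("initial state shape does not match configuration")

    n_steps = int(round(options.duration / options.dt))
    if sources is not None:
        if sources.times[-1] + 0.5 * options.dt < options.duration:
            raise ValueError("sources do not cover the requested duration")
        src_dt = sources.sample_dt
        src_last = len(sources.times) - 1

    rec_idx = np.arange(0, n_steps + 1, options.record_stride)
    s = len(rec_idx)
    rec = Trajectory(
        times=np.empty(s),
        concentrations=np.empty((s, k, n)),
        potential=np.empty((s, n)),
        diffusive_flux=np.empty((s, k, n - 1)),
        field_flux=np.empty((s, k, n - 1)),
        diffusive_current=np.empty((s, n - 1)),
        field_current=np.empty((s, n - 1)),
        conductivity=np.empty((s, n - 1)),
        ion_names=ions.names,
    )
    rec_set = {int(i): j for j, i in enumerate(rec_idx)}

    # hoisted loop constants
    f = constants.faraday
    psi = constants.psi
    z = ions.valences[:, None]
    d_eff = (ions.diffusion_constants / geometry.tortuosity**2)[:, None]
    sig_w = (f / psi) * (d_eff * z * z)
    flux_pref = geometry.ecs_cross_section / geometry.subvolume_height
    scale = geometry.subvolume_height / geometry.ecs_cross_section
    vol = geometry.ecs_subvolume_volume
    dt = options.dt
    diff_on = options.include_diffusion
    zeros_sample = SourceSample.zeros(k, n)
    # freezing sigma freezes the drift weights as a whole: both the solve
    # and the field fluxes use the initial interface concentrations, so the
    # recorded currents stay consistent with Kirchhoff's law
    frozen_sigma = frozen_cmid = None
    if options.freeze_conductivity:
        c0 = state.concentrations
        frozen_cmid = 0.5 * (c0[:, 1:] + c0[:, :-1])
        frozen_sigma = _conductivities(state, ions, constants, geometry)

    ab = np.zeros((3, n))
    worst = 0.0
    c = state.concentrations

    for step in range(n_steps + 1):
        t = step * dt
        if sources is None:
            jm = zeros_sample.ion_fluxes
            i_cap = zeros_sample.capacitive_current
            i_m = np.zeros(n)
        else:
            i_src = min(int(t / src_dt + 1e-9), src_last)
            jm = sources.ion_fluxes[i_src]
            i_cap = sources.capacitive_current[i_src]
            i_m = f * (z * jm).sum(axis=0)

        dc = c[:, 1:] - c[:, :-1]
        cmid = 0.5 * (c[:, 1:] + c[:, :-1])
        sigma = frozen_sigma if frozen_sigma is not None else (sig_w * cmid).sum(0)
        jd = -flux_pref * d_eff * dc
        i_d_full = f * (z * jd).sum(axis=0)
        i_d = i_d_full if diff_on else 0.0 * i_d_full

        # tridiagonal Kirchhoff system in banded form
        ab[0, 1] = 0.0
        ab[0, 2:] = sigma[1:]
        ab[1, 0] = 1.0
        ab[1, 1:-1] = -(sigma[:-1] + sigma[1:])
        ab[1, -1] = -sigma[-1]
        ab[2, :-1] = sigma
        b = np.zeros(n)
        b[1:-1] = scale * (-i_cap[1:-1] - i_m[1:-1] - i_d[:-1] + i_d[1:])
        b[-1] = -scale * i_d[-1]
        v = solve_banded((1, 1), ab, b)

        drift_cmid = cmid if frozen_cmid is None else frozen_cmid
        jf = -(flux_pref / psi) * z * d_eff * drift_cmid * (v[1:] - v[:-1])

        j = rec_set.get(step)
        if j is not None:
            i_f = f * (z * jf).sum(axis=0)
            rec.times[j] = t
            rec.concentrations[j] = c
            rec.potential[j] = v
            rec.diffusive_flux[j] = jd if diff_on else 0.0 * jd
            rec.field_flux[j] = jf
            rec.diffusive_current[j] = i_d
            rec.field_current[j] = i_f
            rec.conductivity[j] = sigma
            worst = max(worst, _kirchhoff_residual(i_d, i_f, i_m, i_cap))

        if step == n_steps:
            break

        net = (jd + jf) if diff_on else jf
        new_c = c.copy()
        new_c[:, 1:-1] += dt * (jm[:, 1:-1] + net[:, :-1] - net[:, 1:]) / vol
        if np.any(new_c < 0):
            ki, ni = np.unravel_index(np.argmin(new_c), new_c.shape)
            raise ValueError(
                f"negative concentration for ion {ions.names[ki]!r} in "
                f"subvolume {ni + 1} at t={t + dt:.6g} s; reduce dt or check "
                "the sources"
            )
        c = new_c

    rec.worst_kirchhoff_residual = worst
    return rec
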