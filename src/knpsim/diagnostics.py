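"""Analysis operators for simulated extracellular dynamics.

Time-averaged depth profiles, log-binned power spectral densities with
power-law fitting, liquid-junction potential calculators (Goldman-Hodgkin-
Katz and Henderson), and current-source-density (CSD) estimation both in
the classical form (which assumes purely Ohmic ECS currents) and with the
diffusive-current correction.  The CSD pair makes quantitative the classic
pitfall that, when concentration gradients exist, the classical estimator
misreads diffusive ECS currents as transmembrane current sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from .core import ECSState, Geometry, IonSet, PhysicalConstants
from .solver import Trajectory, diffusive_currents, interface_conductivity

__all__ = [
    "DepthProfile",
    "PowerSpectrum",
    "PowerLawFit",
    "time_average_profile",
    "power_spectrum",
    "fit_power_law",
    "ghk_potential",
    "henderson_potential",
    "csd_standard",
    "csd_diffusion_corrected",
]


@dataclass
class DepthProfile:
    """One value per subvolume, averaged over a time interval."""

    values: np.ndarray
    interval: tuple[float, float]
    quantity: str


@dataclass
class PowerSpectrum:
    """Log-binned one-sided power spectral density."""

    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray        # signal_unit^2 / Hz
    bin_decades: float
    raw_frequencies: np.ndarray | None = None
    raw_power: np.ndarray | None = None


@dataclass
class PowerLawFit:
    """Least-squares log-log line; ``exponent`` is the magnitude beta of 1/f^beta."""

    exponent: float
    amplitude: float
    band: tuple[float, float]
    r_squared: float


def time_average_profile(
    trajectory: Trajectory,
    quantity: str,
    intervals: Sequence[tuple[float, float]],
) -> list[DepthProfile]:
    """Arithmetic per-subvolume mean of a quantity over each interval.

    ``quantity`` is ``"potential"`` or ``"concentration:<ion>"``.  This is
    the low-pass filter used to expose slow depth structure in a record
    dominated by fast fluctuations.
    """
    if quantity == "potential":
        data = trajectory.potential
    elif quantity.startswith("concentration:"):
        ion = quantity.split(":", 1)[1]
        data = trajectory.concentrations[:, trajectory.ion_names.index(ion), :]
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    t = trajectory.times
    out = []
    for t0, t1 in intervals:
        mask = (t >= t0) & (t <= t1)
        if not mask.any():
            raise ValueError(f"interval ({t0}, {t1}) contains no samples")
        out.append(
            DepthProfile(data[mask].mean(axis=0), (float(t0), float(t1)), quantity)
        )
    return out


def power_spectrum(
    signal: np.ndarray,
    sample_dt: float,
    log_bin: float = 0.1,
    window: str = "boxcar",
) -> PowerSpectrum:
    """One-sided periodogram of the mean-subtracted signal, log-bin smoothed.

    The raw periodogram is averaged into geometric frequency bins of
    ``log_bin`` decades (one value per 0.1 log unit by default); each bin
    reports the geometric-mean frequency of its members.  Detrending is
    mean subtraction only; a taper can be requested via ``window``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) < 16:
        raise ValueError("signal must be 1D with at least 16 samples")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0")
    freqs, power = periodogram(
        signal - signal.mean(),
        fs=1.0 / sample_dt,
        window=window,
        detrend=False,
    )
    freqs, power = freqs[1:], power[1:]  # drop the (zeroed) DC bin

    logf = np.log10(freqs)
    edges = np.arange(
        np.floor(logf[0] / log_bin) * log_bin,
        logf[-1] + log_bin,
        log_bin,
    )
    idx = np.digitize(logf, edges)
    f_binned, p_binned = [], []
    for b in np.unique(idx):
        sel = idx == b
        f_binned.append(10 ** logf[sel].mean())
        p_binned.append(power[sel].mean())
    return PowerSpectrum(
        frequencies=np.array(f_binned),
        power=np.array(p_binned),
        bin_decades=log_bin,
        raw_frequencies=freqs,
        raw_power=power,
    )


def fit_power_law(
    spectrum: PowerSpectrum, band: tuple[float, float]
) -> PowerLawFit:
    """Least-squares line on (log10 f, log10 PSD) within ``band``.

    Returns the exponent as the positive magnitude beta of a 1/f^beta law
    (beta = -slope).
    """
    f_lo, f_hi = band
    mask = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
    mask &= spectrum.power > 0
    if mask.sum() < 4:
        raise ValueError(
            f"need >= 4 spectrum bins in band ({f_lo}, {f_hi}); got {mask.sum()}"
        )
    x = np.log10(spectrum.frequencies[mask])
    y = np.log10(spectrum.power[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        exponent=float(-slope),
        amplitude=float(10**intercept),
        band=(float(f_lo), float(f_hi)),
        r_squared=float(r2),
    )


def _concentration_vectors(comp, ions: IonSet) -> np.ndarray:
    if isinstance(comp, dict):
        return ions.concentrations_from(comp)
    arr = np.asarray(comp, dtype=float)
    if arr.shape != (len(ions),):
        raise ValueError("concentration vector length must match the ion set")
    return arr


def ghk_potential(
    comp_a, comp_b, ions: IonSet, constants: PhysicalConstants
) -> float:
    """Goldman-Hodgkin-Katz junction potential ``V_B - V_A`` (V).

    The textbook GHK voltage equation over the *monovalent* species of the
    ion set, with the ions' diffusion constants playing the role of
    permeabilities (a shared tortuosity factor cancels in the ratio)::

        V = psi * ln[(sum_cat D c_A + sum_an D c_B) /
                     (sum_cat D c_B + sum_an D c_A)]

    Divalent species (Ca2+ here, present at ~1 mM) are excluded, as the
    GHK voltage equation is derived for monovalent ions; use
    :func:`henderson_potential` when all valences must contribute.
    Compartments are name->concentration mappings (mol/m^3) or per-ion
    vectors; concentrations of included species must be positive.
    """
    ca = _concentration_vectors(comp_a, ions)
    cb = _concentration_vectors(comp_b, ions)
    mono = np.abs(ions.valences) == 1
    if np.any(ca[mono] <= 0) or np.any(cb[mono] <= 0):
        raise ValueError("monovalent concentrations must be > 0 on both sides")
    d = ions.diffusion_constants
    cat = mono & (ions.valences > 0)
    an = mono & (ions.valences < 0)
    num = (d[cat] * ca[cat]).sum() + (d[an] * cb[an]).sum()
    den = (d[cat] * cb[cat]).sum() + (d[an] * ca[an]).sum()
    if den == 0:
        raise ZeroDivisionError("GHK denominator is zero")
    return float(constants.psi * np.log(num / den))


def henderson_potential(
    comp_a, comp_b, ions: IonSet, constants: PhysicalConstants
) -> float:
    """Henderson liquid-junction potential ``V_B - V_A`` (V).

    Classical Henderson formula with mobilities proportional to
    ``D_k |z_k|`` (Einstein relation), valid for arbitrary valences under
    the linear-mixing assumption::

        V = psi * [sum_k z_k D_k (c_B - c_A)] / [sum_k z_k^2 D_k (c_B - c_A)]
                * ln[sum_k z_k^2 D_k c_A / sum_k z_k^2 D_k c_B]

    Reduces to the Nernst potential for a single ion and to zero for a
    symmetric binary salt.  For identical compartments returns 0.
    """
    ca = _concentration_vectors(comp_a, ions)
    cb = _concentration_vectors(comp_b, ions)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("concentrations must be >= 0")
    d, z = ions.diffusion_constants, ions.valences
    s_a = (z**2 * d * ca).sum()
    s_b = (z**2 * d * cb).sum()
    if s_a <= 0 or s_b <= 0:
        raise ZeroDivisionError("total mobility-weighted concentration is zero")
    dc = cb - ca
    w = (z**2 * d * dc).sum()
    m = (z * d * dc).sum()
    if w == 0:
        # s_a == s_b; the log factor vanishes at the same rate -> limit
        return float(-constants.psi * m / s_a)
    return float(constants.psi * (m / w) * np.log(s_a / s_b))


def csd_standard(
    v_profile: np.ndarray,
    sigma_interfaces: np.ndarray,
    geometry: Geometry,
) -> np.ndarray:
    """Classical CSD estimate ``-d/dz (sigma dV/dz)`` (A per m^3 of ECS).

    Discrete second-difference on the subvolume grid with interface
    conductivities; one-sided at the column ends (no current crosses the
    outer faces).  Assumes all ECS current is Ohmic.
    """
    v = np.asarray(v_profile, dtype=float)
    sig = np.asarray(sigma_interfaces, dtype=float)
    if len(sig) != len(v) - 1:
        raise ValueError("need one conductivity per interface (N-1 values)")
    flux = sig * (v[1:] - v[:-1])  # sigma * dV across each interface (* 1/l_c)
    div = np.empty_like(v)
    div[0] = flux[0]
    div[1:-1] = flux[1:] - flux[:-1]
    div[-1] = -flux[-1]
    return -div / geometry.subvolume_height**2


def csd_diffusion_corrected(
    v_profile: np.ndarray,
    concentration_profiles: np.ndarray,
    ions: IonSet,
    geometry: Geometry,
    constants: PhysicalConstants,
) -> np.ndarray:
    """Diffusion-corrected CSD ``-[d/dz(sigma dV/dz) - d(i_d)/dz]`` (A/m^3 ECS).

    Subtracts the divergence of the diffusive current density before sign
    inversion, so diffusive ECS currents are no longer misattributed to
    transmembrane sources.  Conductivities and diffusive currents are built
    from the supplied per-ion concentration profiles (shape ``(K, N)``).
    """
    conc = np.asarray(concentration_profiles, dtype=float)
    state = ECSState(conc, np.asarray(v_profile, dtype=float), 0.0)
    sigma = interface_conductivity(
        conc[:, :-1], conc[:, 1:], ions, constants, geometry
    )
    base = csd_standard(v_profile, sigma, geometry)
    i_d = diffusive_currents(state, ions, geometry, constants.faraday)
    div_id = np.empty_like(base)
    div_id[0] = i_d[0]
    div_id[1:-1] = i_d[1:] - i_d[:-1]
    div_id[-1] = -i_d[-1]
    return base + div_id / geometry.ecs_subvolume_volume
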