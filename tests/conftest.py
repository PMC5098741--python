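import numpy as np
import pytest

from knpsim import (
    PopulationParams,
    baseline_state,
    default_configuration,
    generate_population_sources,
)
from knpsim.sources import SourceSeries


@pytest.fixture(scope="session")
def config():
    return default_configuration()


@pytest.fixture(scope="session")
def ions(config):
    return config.ions


@pytest.fixture(scope="session")
def geometry(config):
    return config.geometry


@pytest.fixture(scope="session")
def constants(config):
    return config.constants


@pytest.fixture(scope="session")
def soma_shifts(ions):
    """Electroneutral concentration shifts of the perturbed soma subvolume,
    aligned with the default ion order (K, Na, Ca, X), in mol/m^3."""
    shifts = {"K": 6.0, "Na": -5.1, "Ca": -0.1, "X": 0.7}
    return np.array([shifts[name] for name in ions.names])


@pytest.fixture()
def decay_state(ions, geometry, soma_shifts):
    """Baseline column with only subvolume 3 perturbed."""
    state = baseline_state(ions, geometry)
    state.concentrations[:, 2] += soma_shifts
    return state


@pytest.fixture(scope="session")
def population_sources(geometry, ions):
    """Short synthetic population drive shared by solver/diagnostics tests."""
    params = PopulationParams(seed=42)
    return generate_population_sources(params, 0.2, 1e-4, geometry, ions)


def random_balanced_sources(ions, geometry, duration, dt, seed):
    """Random interior sources whose depth-summed total current is zero.

    Ion fluxes and capacitive currents are drawn independently; the
    capacitive current of one interior subvolume absorbs the imbalance.
    """
    rng = np.random.default_rng(seed)
    m = int(round(duration / dt)) + 1
    k, n = len(ions), geometry.n_subvolumes
    jm = np.zeros((m, k, n))
    icap = np.zeros((m, n))
    jm[:, :, 1:-1] = rng.normal(scale=1e-14, size=(m, k, n - 2))
    icap[:, 1:-1] = rng.normal(scale=1e-10, size=(m, n - 2))
    total = 96485.0 * (ions.valences[None, :, None] * jm).sum(axis=(1, 2))
    total += icap.sum(axis=1)
    icap[:, 1] -= total
    return SourceSeries(np.arange(m) * dt, jm, icap, ions.names)
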