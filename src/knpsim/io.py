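"""Delimited-text (and optional HDF5) writers/readers for trajectories."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .solver import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_trajectory_hdf5"]

_INTERFACE_FILES = {
    "diffusive_current": "Id.tsv",
    "field_current": "If.tsv",
    "conductivity": "sigma.tsv",
}


def _save(path: Path, header: str, columns: np.ndarray) -> None:
    np.savetxt(path, columns, delimiter="\t", header=header, comments="")


def write_trajectory(traj: Trajectory, outdir: str | Path) -> None:
    """Write one TSV per quantity with a header row naming subvolume indices.

    Files: ``V.tsv`` (V), ``c_<ion>.tsv`` (mol/m^3) per ion, ``Id.tsv`` /
    ``If.tsv`` (A) and ``sigma.tsv`` (S/m) per interface.  First column is
    always time in seconds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = traj.potential.shape[1]
    sub_hdr = "time_s\t" + "\t".join(f"n{j + 1}" for j in range(n))
    if_hdr = "time_s\t" + "\t".join(f"n{j + 1}-n{j + 2}" for j in range(n - 1))
    t = traj.times[:, None]
    (outdir / "ion_order.txt").write_text("\n".join(traj.ion_names) + "\n")
    _save(outdir / "V.tsv", sub_hdr, np.hstack([t, traj.potential]))
    for k, name in enumerate(traj.ion_names):
        _save(
            outdir / f"c_{name}.tsv", sub_hdr,
            np.hstack([t, traj.concentrations[:, k, :]]),
        )
    for attr, fname in _INTERFACE_FILES.items():
        _save(outdir / fname, if_hdr, np.hstack([t, getattr(traj, attr)]))


def read_trajectory(outdir: str | Path) -> Trajectory:
    """Read a trajectory directory written by :func:`write_trajectory`.

    Per-ion interface fluxes are not serialized to text; they are restored
    as zeros (the diagnostics operate on currents and concentrations).
    """
    outdir = Path(outdir)
    v = np.loadtxt(outdir / "V.tsv", skiprows=1, ndmin=2)
    times, potential = v[:, 0], v[:, 1:]
    order_file = outdir / "ion_order.txt"
    if order_file.exists():
        ion_names = tuple(order_file.read_text().split())
    else:
        ion_names = tuple(sorted(p.stem[2:] for p in outdir.glob("c_*.tsv")))
    conc = np.stack(
        [
            np.loadtxt(outdir / f"c_{name}.tsv", skiprows=1, ndmin=2)[:, 1:]
            for name in ion_names
        ],
        axis=1,
    )
    parts = {}
    for attr, fname in _INTERFACE_FILES.items():
        parts[attr] = np.loadtxt(outdir / fname, skiprows=1, ndmin=2)[:, 1:]
    s, k, n = conc.shape
    return Trajectory(
        times=times,
        concentrations=conc,
        potential=potential,
        diffusive_flux=np.zeros((s, k, n - 1)),
        field_flux=np.zeros((s, k, n - 1)),
        diffusive_current=parts["diffusive_current"],
        field_current=parts["field_current"],
        conductivity=parts["conductivity"],
        ion_names=ion_names,
    )


def write_trajectory_hdf5(traj: Trajectory, path: str | Path) -> None:
    """Single binary container mirroring the text layout."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("potential", data=traj.potential)
        fh.create_dataset("concentrations", data=traj.concentrations)
        fh.create_dataset("diffusive_current", data=traj.diffusive_current)
        fh.create_dataset("field_current", data=traj.field_current)
        fh.create_dataset("conductivity", data=traj.conductivity)
        fh.attrs["ion_names"] = list(traj.ion_names)
        fh.attrs["worst_kirchhoff_residual"] = traj.worst_kirchhoff_residual
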