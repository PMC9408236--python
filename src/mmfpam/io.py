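"""HDF5 persistence for transmission-matrix stacks and RVITM stacks."""

from __future__ import annotations

import numpy as np

from .calibration import RVITMatrix
from .fibre import TransmissionMatrix

__all__ = ["save_tm_stack", "load_tm_stack",
           "save_rvitm_stack", "load_rvitm_stack"]


def save_tm_stack(path, stack: list[TransmissionMatrix]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        e = np.stack([tm.entries for tm in stack])
        f.create_dataset("real", data=e.real)
        f.create_dataset("imag", data=e.imag)
        f.create_dataset("plane_z_um", data=[tm.plane_z_um for tm in stack])
        f.attrs["n_inputs"] = stack[0].n_inputs
        f.attrs["pixel_pitch_um"] = stack[0].pixel_pitch_um
        f.attrs["core_diameter_um"] = stack[0].core_diameter_um


def load_tm_stack(path) -> list[TransmissionMatrix]:
    import h5py

    with h5py.File(path, "r") as f:
        e = f["real"][...] + 1j * f["imag"][...]
        zs = f["plane_z_um"][...]
        pitch = float(f.attrs["pixel_pitch_um"])
        core = float(f.attrs["core_diameter_um"])
    return [TransmissionMatrix(e[i], pitch, core, float(zs[i]))
            for i in range(e.shape[0])]


def save_rvitm_stack(path, stack: list[RVITMatrix]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("rvitm", data=np.stack([r.values for r in stack]))
        f.create_dataset("plane_z_um", data=[r.plane_z_um for r in stack])


def load_rvitm_stack(path) -> list[RVITMatrix]:
    import h5py

    with h5py.File(path, "r") as f:
        v = f["rvitm"][...]
        zs = f["plane_z_um"][...]
    return [RVITMatrix(v[i], float(zs[i])) for i in range(v.shape[0])]
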