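"""Digital absorption phantoms for photoacoustic imaging simulation.

Three phantom families mirror the samples used to characterise
optical-resolution photoacoustic endomicroscopes: bar targets
(resolution-target edges), carbon-fibre cylinders (3D sectioning), and
biconcave red-blood-cell discs (biological contrast).  Absorption is a
non-negative scalar per voxel on a regular (y, x, z) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbsorberMap",
    "make_bar_target",
    "make_carbon_fibre_phantom",
    "make_rbc_phantom",
]


@dataclass(frozen=True)
class AbsorberMap:
    """Non-negative absorption on a regular 3D grid.

    ``values[iy, ix, iz]``; voxel centre coordinates are
    ``origin_um + index * pitch_um`` per axis.  ``provenance`` records
    which generator built the map.
    """

    values: np.ndarray                       # (ny, nx, nz) >= 0
    pitch_um: tuple[float, float, float]     # (dy, dx, dz)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "custom"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be a 3D (ny, nx, nz) array")
        if (v < 0).any():
            raise ValueError("absorption must be non-negative")
        if any(p <= 0 for p in self.pitch_um):
            raise ValueError("grid pitches must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_um[axis] + np.arange(self.shape[axis]) * self.pitch_um[axis]

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("absorption", data=self.values)
            d.attrs["pitch_um"] = self.pitch_um
            d.attrs["origin_um"] = self.origin_um
            d.attrs["provenance"] = self.provenance

    @classmethod
    def load_hdf5(cls, path) -> "AbsorberMap":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["absorption"]
            return cls(d[...], tuple(d.attrs["pitch_um"]),
                       tuple(d.attrs["origin_um"]), str(d.attrs["provenance"]))


def _centered_coords(n: int, pitch: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * pitch


def make_bar_target(bar_width_um: float, gap_um: float, n_bars: int, *,
                    extent_um: tuple[float, float] = (50.0, 50.0),
                    pitch_um: float = 0.5, z_um: float = 0.0,
                    thickness_um: float | None = None) -> AbsorberMap:
    """Parallel absorbing bars (bars run along x; edges perpendicular to y).

    Binary absorption {0, 1} in a single thin z plane, bar edges aligned
    to exact lattice coordinates.  The bar block is centred in y.
    """
    if bar_width_um <= 0 or gap_um < 0 or n_bars < 1:
        raise ValueError("bar geometry must be positive")
    ly, lx = extent_um
    ny, nx = int(round(ly / pitch_um)) + 1, int(round(lx / pitch_um)) + 1
    block = n_bars * bar_width_um + (n_bars - 1) * gap_um
    if block > ly:
        raise ValueError(
            f"bars span {block} um but grid extent is only {ly} um")
    y = _centered_coords(ny, pitch_um)
    vals = np.zeros((ny, nx, 1))
    y0 = -block / 2.0
    for b in range(n_bars):
        lo = y0 + b * (bar_width_um + gap_um)
        hi = lo + bar_width_um
        rows = (y >= lo - 1e-9) & (y < hi - 1e-9)
        vals[rows, :, 0] = 1.0
    dz = thickness_um if thickness_um is not None else pitch_um
    return AbsorberMap(vals, (pitch_um, pitch_um, dz),
                       origin_um=(y[0], _centered_coords(nx, pitch_um)[0], z_um),
                       provenance="bar_target")


def make_carbon_fibre_phantom(n_fibres: int, *, radius_um: float = 3.5,
                              extent_um: tuple[float, float, float] = (50.0, 50.0, 300.0),
                              pitch_um: tuple[float, float, float] = (1.0, 1.0, 2.0),
                              poses=None, seed=None) -> AbsorberMap:
    """Absorbing cylinders emulating carbon fibres.

    Each fibre runs parallel to the x axis at depth ``z_um`` and lateral
    position ``y_um``; ``poses`` is a list of (y_um, z_um).  Without
    explicit poses, fibres are placed at random depths/offsets,
    deterministically from ``seed``.
    """
    ly, lx, lz = extent_um
    dy, dx, dz = pitch_um
    ny, nx, nz = (int(round(ly / dy)) + 1, int(round(lx / dx)) + 1,
                  int(round(lz / dz)) + 1)
    y = _centered_coords(ny, dy)
    z = np.arange(nz) * dz
    if poses is None:
        rng = np.random.default_rng(seed)
        margin = radius_um
        poses = [(rng.uniform(y[0] + margin, y[-1] - margin),
                  rng.uniform(z[0] + margin, z[-1] - margin))
                 for _ in range(n_fibres)]
    vals = np.zeros((ny, nx, nz))
    yy, zz = np.meshgrid(y, z, indexing="ij")
    for (yc, zc) in poses:
        if not (y[0] <= yc <= y[-1] and z[0] <= zc <= z[-1]):
            raise ValueError(f"fibre pose {(yc, zc)} outside the grid")
        disc = (yy - yc) ** 2 + (zz - zc) ** 2 <= radius_um**2
        vals = np.maximum(vals, disc[:, None, :].astype(float))
    return AbsorberMap(vals, (dy, dx, dz),
                       origin_um=(y[0], _centered_coords(nx, dx)[0], 0.0),
                       provenance="carbon_fibre")


def rbc_thickness_profile(rho_um: np.ndarray, diameter_um: float) -> np.ndarray:
    """Rotationally symmetric biconcave thickness profile (a.u.).

    Thinner at the centre than at the rim (the defining biconcave
    feature); smooth and compactly supported on the cell disc.  The
    exact coefficients are a stylised choice, not a fit to any
    particular cell.
    """
    u = np.clip(2.0 * np.asarray(rho_um, dtype=float) / diameter_um, 0.0, None)
    inside = u < 1.0
    t = np.zeros_like(u)
    ui = u[inside]
    t[inside] = (0.45 + 1.9 * ui**2) * np.sqrt(1.0 - ui**2)
    return t


def make_rbc_phantom(n_cells: int, *, cell_diameter_um: float = 7.5,
                     extent_um: tuple[float, float] = (60.0, 60.0),
                     pitch_um: float = 0.5, z_um: float = 0.0,
                     seed=None, max_tries_per_cell: int = 200) -> AbsorberMap:
    """Non-overlapping biconcave red-blood-cell discs in a thin plane.

    Cells are placed by rejection sampling (minimum centre distance one
    cell diameter); placement failure after bounded retries raises.
    Absorption is proportional to cell thickness, so a line profile
    through a cell dips at the centre.
    """
    ly, lx = extent_um
    ny, nx = int(round(ly / pitch_um)) + 1, int(round(lx / pitch_um)) + 1
    y = _centered_coords(ny, pitch_um)
    x = _centered_coords(nx, pitch_um)
    rng = np.random.default_rng(seed)
    r = cell_diameter_um / 2.0
    if n_cells > 0 and (ly < cell_diameter_um or lx < cell_diameter_um):
        raise ValueError("grid too small for a single cell")
    centres: list[tuple[float, float]] = []
    for _ in range(n_cells):
        for attempt in range(max_tries_per_cell):
            cy = rng.uniform(y[0] + r, y[-1] - r)
            cx = rng.uniform(x[0] + r, x[-1] - r)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 >= cell_diameter_um**2
                   for oy, ox in centres):
                centres.append((cy, cx))
                break
        else:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells after "
                f"{max_tries_per_cell} tries each; reduce n_cells")
    yy, xx = np.meshgrid(y, x, indexing="ij")
    vals = np.zeros((ny, nx, 1))
    for cy, cx in centres:
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        vals[:, :, 0] += rbc_thickness_profile(rho, cell_diameter_um)
    return AbsorberMap(vals, (pitch_um, pitch_um, pitch_um),
                       origin_um=(y[0], x[0], z_um), provenance="rbc")
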