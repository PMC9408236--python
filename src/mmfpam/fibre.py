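"""Synthetic multimode-fibre (MMF) simulator.

Stands in for the physical fibre + camera of a wavefront-shaping
endomicroscope: it holds a ground-truth *complex* transmission matrix
(TM) mapping DMD micromirrors to the output-plane field, propagates
binary micromirror patterns to output-plane speckle intensities, and
models camera noise.  The ground truth is only ever visible to the
simulator and to test oracles; the characterisation code in
:mod:`mmfpam.calibration` sees intensities alone, exactly as the real
instrument does.

Statistical model
-----------------
TM entries are i.i.d. circular complex Gaussian with variance ``1/N``
per entry inside a circular core of configurable diameter (default
100 um, matching a 0.1 mm-core graded-index fibre) and exactly zero
outside.  The 1/N variance keeps the all-ON reference intensity O(1)
per pixel independent of the mirror count, so focusing gain can be read
directly off intensity ratios.  No mode correlations or bending physics
are modelled; the purpose is validating the intensity-only
characterisation algebra and focusing statistics, not fibre optics.

Micromirror flattening convention: row-major, 0-based, everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransmissionMatrix",
    "DMDPattern",
    "SpeckleImage",
    "ReferenceField",
    "generate_tm",
    "generate_tm_stack",
    "propagate",
    "reference_field",
    "apply_camera_noise",
    "phase_conjugation_oracle",
]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def core_mask(shape: tuple[int, int], pixel_pitch_um: float,
              core_diameter_um: float) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside the fibre core.

    Pixel centres sit on a lattice centred on the grid centre, with the
    optical axis through the middle of the grid.
    """
    rows, cols = shape
    y = (np.arange(rows) - (rows - 1) / 2.0) * pixel_pitch_um
    x = (np.arange(cols) - (cols - 1) / 2.0) * pixel_pitch_um
    yy, xx = np.meshgrid(y, x, indexing="ij")
    r = core_diameter_um / 2.0
    return yy**2 + xx**2 <= r**2 + 1e-9


@dataclass(frozen=True)
class TransmissionMatrix:
    """Complex field map from DMD micromirrors to output-plane pixels.

    ``entries[i, j, n]`` is the complex field at output pixel ``(i, j)``
    when only micromirror ``n`` (row-major index) is ON, with unit input.
    """

    entries: np.ndarray               # complex, (rows, cols, N)
    pixel_pitch_um: float
    core_diameter_um: float
    plane_z_um: float = 0.0
    seed: object = None

    def __post_init__(self):
        e = np.asarray(self.entries)
        if e.ndim != 3:
            raise ValueError("entries must be a (rows, cols, N) array")
        if e.shape[0] * e.shape[1] == 0:
            raise ValueError("zero-sized output grid")
        object.__setattr__(self, "entries", np.ascontiguousarray(e, dtype=complex))

    @property
    def n_inputs(self) -> int:
        return self.entries.shape[2]

    @property
    def output_shape(self) -> tuple[int, int]:
        return self.entries.shape[:2]

    @property
    def core_mask(self) -> np.ndarray:
        return core_mask(self.output_shape, self.pixel_pitch_um,
                         self.core_diameter_um)

    @property
    def matrix(self) -> np.ndarray:
        """Entries flattened to (n_pixels, N), pixels in row-major order."""
        return self.entries.reshape(-1, self.n_inputs)


@dataclass(frozen=True)
class DMDPattern:
    """Binary micromirror pattern; ``mask`` is the flat row-major vector."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask).ravel()
        if not np.isin(m, (0, 1)).all():
            raise ValueError("DMD pattern must be strictly binary (0/1)")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @classmethod
    def from_grid(cls, grid: np.ndarray) -> "DMDPattern":
        return cls(np.asarray(grid).ravel())  # row-major flattening

    @property
    def n(self) -> int:
        return self.mask.size

    def as_grid(self) -> np.ndarray:
        s = int(round(np.sqrt(self.n)))
        if s * s != self.n:
            raise ValueError(f"pattern length {self.n} is not a perfect square")
        return self.mask.reshape(s, s)


@dataclass(frozen=True)
class SpeckleImage:
    intensity: np.ndarray             # (rows, cols), >= 0
    noise_applied: bool = False
    pixel_pitch_um: float = 1.0
    plane_z_um: float = 0.0

    def __post_init__(self):
        i = np.asarray(self.intensity, dtype=float)
        if (i < 0).any():
            raise ValueError("speckle intensities must be non-negative")
        object.__setattr__(self, "intensity", i)

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.intensity.astype(np.float32))


@dataclass(frozen=True)
class ReferenceField:
    """Output field with all micromirrors ON: amplitude A_R and phase phi_R."""

    amplitude: np.ndarray
    phase: np.ndarray

    @property
    def complex_field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


def generate_tm(n_inputs: int, output_shape: tuple[int, int], *,
                plane_z_um: float = 0.0, seed=None,
                pixel_pitch_um: float = 1.0,
                core_diameter_um: float = 100.0) -> TransmissionMatrix:
    """Draw a random ground-truth transmission matrix.

    Entries are i.i.d. circular complex Gaussian, variance ``1/n_inputs``
    inside the core disc and 0 outside; bit-reproducible from ``seed``.
    """
    if not _is_power_of_two(n_inputs) or n_inputs < 2:
        raise ValueError(
            f"n_inputs must be a power of two >= 2 for Hadamard "
            f"calibration compatibility, got {n_inputs}")
    rows, cols = output_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("output grid must be non-empty")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(1.0 / (2.0 * n_inputs))   # per quadrature
    e = rng.normal(0.0, sigma, (rows, cols, n_inputs)) \
        + 1j * rng.normal(0.0, sigma, (rows, cols, n_inputs))
    mask = core_mask((rows, cols), pixel_pitch_um, core_diameter_um)
    e[~mask] = 0.0
    return TransmissionMatrix(e, pixel_pitch_um, core_diameter_um,
                              plane_z_um, seed)


def generate_tm_stack(plane_zs_um, n_inputs: int, output_shape, *,
                      seed=None, pixel_pitch_um: float = 1.0,
                      core_diameter_um: float = 100.0) -> list[TransmissionMatrix]:
    """One independent TM per focal plane; per-plane seed = (seed, index)."""
    zs = [float(z) for z in plane_zs_um]
    if any(b <= a for a, b in itertools.pairwise(zs)):
        raise ValueError("plane_zs_um must be strictly increasing")
    return [
        generate_tm(n_inputs, output_shape, plane_z_um=z,
                    seed=derive_plane_seed(seed, i),
                    pixel_pitch_um=pixel_pitch_um,
                    core_diameter_um=core_diameter_um)
        for i, z in enumerate(zs)
    ]


def derive_plane_seed(seed, plane_index: int):
    """Deterministic per-plane seed, usable directly by generate_tm."""
    base = 0 if seed is None else int(seed)
    return [base, int(plane_index)]


def propagate(tm: TransmissionMatrix, pattern: DMDPattern) -> SpeckleImage:
    """Noiseless output intensity |sum over ON mirrors of the field|^2."""
    if pattern.n != tm.n_inputs:
        raise ValueError(
            f"pattern length {pattern.n} != TM input count {tm.n_inputs}")
    fld = tm.entries @ pattern.mask.astype(float)
    return SpeckleImage(np.abs(fld) ** 2, noise_applied=False,
                        pixel_pitch_um=tm.pixel_pitch_um,
                        plane_z_um=tm.plane_z_um)


def reference_field(tm: TransmissionMatrix) -> ReferenceField:
    fld = tm.entries.sum(axis=2)
    return ReferenceField(np.abs(fld), np.angle(fld))


def apply_camera_noise(img: SpeckleImage, read_noise_sd: float,
                       shot_scale: float, seed=None) -> SpeckleImage:
    """Additive Gaussian read noise + Gaussian shot-noise approximation.

    intensity <- max(0, I + N(0, read_noise_sd) + N(0, shot_scale*sqrt(I)))
    """
    if read_noise_sd < 0 or shot_scale < 0:
        raise ValueError("noise parameters must be >= 0")
    if read_noise_sd == 0 and shot_scale == 0:
        return img
    rng = np.random.default_rng(seed)
    i = img.intensity
    noisy = i + rng.normal(0.0, 1.0, i.shape) * read_noise_sd \
        + rng.normal(0.0, 1.0, i.shape) * (shot_scale * np.sqrt(i))
    return SpeckleImage(np.maximum(noisy, 0.0), noise_applied=True,
                        pixel_pitch_um=img.pixel_pitch_um,
                        plane_z_um=img.plane_z_um)


def phase_conjugation_oracle(tm: TransmissionMatrix,
                             target_pixel: tuple[int, int]) -> float:
    """Upper-bound focus intensity at ``target_pixel`` over binary patterns.

    Exhaustive search over all 2^N patterns for N <= 16; otherwise the
    constructive-phase rule (mirror ON iff cos(theta_mn - phi_R) > 0),
    which is the binary-amplitude analogue of phase conjugation.
    Test-oracle only.
    """
    i, j = target_pixel
    if not tm.core_mask[i, j]:
        raise ValueError(f"target pixel {target_pixel} lies outside the core")
    row = tm.entries[i, j, :]
    n = tm.n_inputs
    if n <= 16:
        best = 0.0
        # enumerate subsets via bit masks
        for bits in range(1, 1 << n):
            sel = (bits >> np.arange(n)) & 1
            val = abs(row @ sel) ** 2
            if val > best:
                best = float(val)
        return best
    ref = tm.entries[i, j, :].sum()
    on = np.cos(np.angle(row) - np.angle(ref)) > 0
    return float(abs(row[on].sum()) ** 2)
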