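"""Real-valued intensity transmission matrix (RVITM) characterisation.

The core algorithm of the package.  A multimode fibre scrambles
coherent input into speckle, so focusing light at its distal tip
requires knowing the fibre's transmission matrix.  Measuring the full
complex matrix needs interferometric phase access; the RVITM approach
instead recovers, from *intensity-only* camera frames under a Hadamard
pattern sequence, the real matrix

    rvitm_mn  ∝  A_mn * A_R * cos(theta_mn - phi_R),

where ``A_mn * exp(i theta_mn)`` is the output field at mode *m* with
only mirror *n* ON, and ``A_R * exp(i phi_R)`` is the all-ON reference
field.  A mirror with positive ``rvitm_mn`` interferes constructively
with the reference at mode *m*; ranking mirrors by ``rvitm_mn`` and
switching ON the top fraction (default 30 %) yields a high-contrast
focus at the chosen output mode without ever measuring a phase.

Calibration sequence: from a Sylvester Hadamard matrix ``H`` in
{-1,+1}^(N x N), two binary matrices ``H1 = (H+1)/2`` and
``H2 = (-H+1)/2`` are built, and the 2N columns of ``[H1, H2]`` are
displayed in order (all H1 columns first).  Writing ``I_mk`` for the
intensity at mode *m* under pattern *k* and ``I_m1`` for the all-ON
(first) column, the estimator is

    RVITM = [2 I_mk - I_m1]_(m x 2N) . [H, -H]^T,

which equals ``2N * A_R A_mn cos(theta_mn - phi_R)`` exactly in the
noiseless case (the ``I_m1`` offset cancels under ``[H, -H]^T`` and is
retained only for fidelity to the estimator's published form).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import hadamard

from .fibre import (DMDPattern, SpeckleImage, TransmissionMatrix,
                    apply_camera_noise, propagate, reference_field)

__all__ = [
    "HadamardPatternSet",
    "SpeckleMeasurementSet",
    "RVITMatrix",
    "FocusPattern",
    "ScanGrid",
    "build_hadamard_pattern_set",
    "acquire_calibration",
    "estimate_rvitm",
    "analytic_rvitm_oracle",
    "select_focus_pattern",
    "make_scan_grid",
    "acquisition_timing",
    "characterise_all_planes",
]


@dataclass(frozen=True)
class HadamardPatternSet:
    """Hadamard parent H and the 2N-column binary display sequence [H1, H2]."""

    order: int
    H: np.ndarray          # (N, N), entries ±1
    H1: np.ndarray         # (N, N), binary
    H2: np.ndarray         # (N, N), binary

    @property
    def display_matrix(self) -> np.ndarray:
        """(N, 2N) binary matrix whose columns are the display sequence."""
        return np.concatenate([self.H1, self.H2], axis=1)

    @property
    def n_patterns(self) -> int:
        return 2 * self.order

    def pattern(self, k: int) -> DMDPattern:
        """k-th displayed pattern (0-based; H1 columns first, then H2)."""
        return DMDPattern(self.display_matrix[:, k])

    @property
    def basis(self) -> np.ndarray:
        """[H, -H] of shape (N, 2N); its transpose inverts the display set."""
        return np.concatenate([self.H, -self.H], axis=1)


@dataclass(frozen=True)
class SpeckleMeasurementSet:
    """Per-mode intensities under the 2N calibration patterns.

    ``intensities[m, k]`` for output mode (camera pixel) m, pattern k;
    modes are the row-major flattening of the camera grid.
    """

    intensities: np.ndarray          # (M, 2N)
    grid_shape: tuple[int, int]
    plane_z_um: float = 0.0

    def __post_init__(self):
        i = np.asarray(self.intensities, dtype=float)
        if (i < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", i)

    @property
    def n_inputs(self) -> int:
        return self.intensities.shape[1] // 2


@dataclass(frozen=True)
class RVITMatrix:
    """Estimated RVITM, one real row of length N per output mode."""

    values: np.ndarray               # (rows, cols, N)
    plane_z_um: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be a (rows, cols, N) array")
        if not np.isfinite(v).all():
            raise ValueError("RVITM values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_inputs(self) -> int:
        return self.values.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def matrix(self) -> np.ndarray:
        return self.values.reshape(-1, self.n_inputs)


@dataclass(frozen=True)
class FocusPattern:
    target_pixel: tuple[int, int]
    pattern: DMDPattern
    on_fraction: float

    def __post_init__(self):
        expected = math.ceil(self.on_fraction * self.pattern.n)
        if int(self.pattern.mask.sum()) != expected:
            raise ValueError("ON-mirror count inconsistent with on_fraction")


@dataclass(frozen=True)
class ScanGrid:
    """Raster-ordered lattice of focus positions inside a circular FOV."""

    fov_diameter_um: float
    step_um: float
    center_um: tuple[float, float]
    positions_um: np.ndarray         # (P, 2) as (x, y)
    plane_zs_um: tuple[float, ...] = (0.0,)

    @property
    def n_positions(self) -> int:
        return self.positions_um.shape[0]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for z in self.plane_zs_um:
            for i, (x, y) in enumerate(self.positions_um):
                rows.append((x, y, z, i))
        return pd.DataFrame(rows,
                            columns=["x_um", "y_um", "plane_z_um", "order_index"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_hadamard_pattern_set(n: int) -> HadamardPatternSet:
    """Sylvester Hadamard matrix of order n and its binary display set."""
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"Hadamard order must be a power of two >= 2, got {n}")
    h = hadamard(n).astype(np.int8)
    h1 = ((h + 1) // 2).astype(np.uint8)
    h2 = ((1 - h) // 2).astype(np.uint8)
    return HadamardPatternSet(n, h, h1, h2)


def acquire_calibration(tm: TransmissionMatrix, patterns: HadamardPatternSet,
                        *, read_noise_sd: float = 0.0,
                        shot_scale: float = 0.0,
                        seed=None) -> SpeckleMeasurementSet:
    """Display the 2N calibration patterns and record output intensities.

    Vectorised equivalent of calling :func:`mmfpam.fibre.propagate` per
    pattern; noise, when enabled, is drawn per pattern exactly as
    :func:`mmfpam.fibre.apply_camera_noise` would.
    """
    if patterns.order != tm.n_inputs:
        raise ValueError(
            f"pattern order {patterns.order} != TM input count {tm.n_inputs}")
    fields = tm.matrix @ patterns.display_matrix.astype(float)   # (M, 2N)
    intensities = np.abs(fields) ** 2
    if read_noise_sd > 0 or shot_scale > 0:
        rng = np.random.default_rng(seed)
        shape = tm.output_shape
        noised = np.empty_like(intensities)
        for k in range(intensities.shape[1]):
            img = SpeckleImage(intensities[:, k].reshape(shape),
                               pixel_pitch_um=tm.pixel_pitch_um)
            noised[:, k] = apply_camera_noise(
                img, read_noise_sd, shot_scale,
                seed=rng.integers(0, 2**31)).intensity.ravel()
        intensities = noised
    return SpeckleMeasurementSet(intensities, tm.output_shape, tm.plane_z_um)


def estimate_rvitm(measurements: SpeckleMeasurementSet,
                   patterns: HadamardPatternSet) -> RVITMatrix:
    """RVITM from intensity-only speckles: [2 I_mk - I_m1] . [H, -H]^T."""
    i = measurements.intensities
    if i.shape[1] != patterns.n_patterns:
        raise ValueError(
            f"expected {patterns.n_patterns} measurement columns, "
            f"got {i.shape[1]}")
    d = 2.0 * i - i[:, [0]]          # I_m1 = all-ON column (first of H1)
    values = d @ patterns.basis.T.astype(float)
    return RVITMatrix(values.reshape(*measurements.grid_shape, patterns.order),
                      measurements.plane_z_um)


def estimate_rvitm_row(intensity_row: np.ndarray,
                       patterns: HadamardPatternSet) -> np.ndarray:
    """Same estimator restricted to one output mode's 2N intensities."""
    i = np.asarray(intensity_row, dtype=float)
    if i.shape != (patterns.n_patterns,):
        raise ValueError("intensity row has wrong length")
    return (2.0 * i - i[0]) @ patterns.basis.T.astype(float)


def analytic_rvitm_oracle(tm: TransmissionMatrix) -> RVITMatrix:
    """Ground-truth RVITM: 2N * A_R A_mn cos(theta_mn - phi_R). Tests only."""
    ref = reference_field(tm).complex_field
    values = 2.0 * tm.n_inputs * np.real(np.conj(ref)[..., None] * tm.entries)
    return RVITMatrix(values, tm.plane_z_um)


def select_focus_pattern(rvitm: RVITMatrix, target_pixel: tuple[int, int],
                         on_fraction: float = 0.30) -> FocusPattern:
    """Switch ON the ceil(on_fraction * N) mirrors with the largest rvitm.

    Ties broken by lowest mirror index (stable descending sort), so the
    selection is deterministic.
    """
    row = rvitm.values[target_pixel[0], target_pixel[1], :]
    return select_focus_pattern_from_row(row, target_pixel, on_fraction)


def select_focus_pattern_from_row(row: np.ndarray,
                                  target_pixel: tuple[int, int],
                                  on_fraction: float = 0.30) -> FocusPattern:
    if not 0.0 < on_fraction <= 1.0:
        raise ValueError(f"on_fraction must be in (0, 1], got {on_fraction}")
    row = np.asarray(row, dtype=float)
    n = row.size
    k = math.ceil(on_fraction * n)
    order = np.argsort(-row, kind="stable")   # ties -> lowest index first
    mask = np.zeros(n, dtype=np.uint8)
    mask[order[:k]] = 1
    return FocusPattern(tuple(target_pixel), DMDPattern(mask), on_fraction)


def make_scan_grid(fov_diameter_um: float = 100.0, step_um: float = 1.0,
                   plane_zs_um=(0.0,),
                   center_um: tuple[float, float] = (0.0, 0.0)) -> ScanGrid:
    """Square lattice of pitch ``step_um``, one point pinned to the FOV
    centre, keeping points whose centre lies within the closed FOV disc;
    raster (row-major in y, then x) order."""
    if step_um <= 0 or fov_diameter_um <= 0:
        raise ValueError("fov_diameter_um and step_um must be positive")
    r = fov_diameter_um / 2.0
    n = int(math.floor(r / step_um))
    offs = np.arange(-n, n + 1) * step_um
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    keep = xx**2 + yy**2 <= r**2 + 1e-9 * r**2
    cx, cy = center_um
    positions = np.column_stack([xx[keep] + cx, yy[keep] + cy])
    zs = tuple(float(z) for z in plane_zs_um)
    if any(b <= a for a, b in itertools.pairwise(zs)):
        raise ValueError("plane_zs_um must be strictly increasing")
    return ScanGrid(fov_diameter_um, step_um, (cx, cy), positions, zs)


def acquisition_timing(n_positions: int, n_planes: int,
                       dmd_rate_hz: float = 22700.0) -> dict:
    """Frame/volume acquisition times for one optimal pattern per position.

    The DMD displays one focusing pattern per scan position, so a frame
    takes ``n_positions / dmd_rate_hz`` seconds.
    """
    if dmd_rate_hz <= 0:
        raise ValueError("dmd_rate_hz must be positive")
    if n_positions < 0 or n_planes < 0:
        raise ValueError("counts must be non-negative")
    frame_time = n_positions / dmd_rate_hz
    return {
        "frame_time_s": frame_time,
        "frame_rate_fps": dmd_rate_hz / n_positions if n_positions else math.inf,
        "volume_time_s": n_planes * frame_time,
    }


def characterise_all_planes(tm_stack, patterns: HadamardPatternSet, *,
                            read_noise_sd: float = 0.0,
                            shot_scale: float = 0.0,
                            seed=None) -> list[RVITMatrix]:
    """One RVITM per focal plane, plane order preserved."""
    out = []
    for i, tm in enumerate(tm_stack):
        meas = acquire_calibration(
            tm, patterns, read_noise_sd=read_noise_sd, shot_scale=shot_scale,
            seed=None if seed is None else [int(seed), i])
        out.append(estimate_rvitm(meas, patterns))
    return out
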