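"""Signal conditioning, image/volume assembly and imaging-quality metrics.

Covers the full path from raw per-position photoacoustic traces to
displayed images and quantitative figures of merit:

* zero-phase low-pass denoising (default 20 MHz, 4th-order Butterworth
  applied forward-backward),
* 2D maximum-intensity-projection (MIP) images on the scan grid,
* 3D volumes by acoustic sectioning (time-of-flight depth, z = c*t,
  one-way propagation to the sensor) or optical sectioning (a stack of
  per-focal-plane MIPs),
* focus metrics (enhancement factor, power ratio, FWHM, fluence) and
  resolution metrology (ESF -> LSF lateral resolution, axial FWHM).

Detection choice: 2D MIPs project the analytic-signal envelope
(sign-insensitive); the acoustic volume projects the *positive part* of
the filtered bipolar signal, because the axial width of a PA pulse is
carrier-limited — the envelope of an 8 MHz / 6.5 MHz-bandwidth pulse is
~4x wider than its positive peak and would wash out the axial
structure.  Both operations accept ``detect`` to override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt, hilbert

from .acoustics import SPEED_OF_SOUND_WATER, PAFrameSet, PATimeSeries
from .calibration import ScanGrid
from .fibre import SpeckleImage

__all__ = [
    "FilterSpec",
    "PAImage",
    "PAVolume",
    "FocusMetrics",
    "lowpass",
    "time_to_depth",
    "mip",
    "assemble_volume_acoustic",
    "assemble_volume_optical",
    "enhancement_factor",
    "power_ratio",
    "profile_fwhm",
    "lateral_resolution_esf",
    "axial_resolution",
    "fluence",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass denoising filter."""

    cutoff_mhz: float = 20.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.cutoff_mhz <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class PAImage:
    """Non-negative MIP amplitude rasterised onto the scan lattice.

    ``mask`` marks pixels that correspond to actual scan positions
    (False outside the circular FOV); masked-out pixels hold 0.
    """

    values: np.ndarray               # (ny, nx) >= 0
    pixel_pitch_um: float
    origin_um: tuple[float, float]   # (y, x) of pixel (0, 0) centre
    mask: np.ndarray | None = None
    plane_z_um: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("image values must be non-negative")
        object.__setattr__(self, "values", v)
        if self.mask is not None:
            object.__setattr__(self, "mask",
                               np.asarray(self.mask, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))


@dataclass(frozen=True)
class PAVolume:
    """(y, x, z) amplitude volume with its sectioning provenance."""

    values: np.ndarray               # (ny, nx, nz)
    pixel_pitch_um: float
    z_pitch_um: float
    z0_um: float
    mode: str                        # "acoustic" | "optical"
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("acoustic", "optical"):
            raise ValueError("mode must be 'acoustic' or 'optical'")

    @property
    def z_coords_um(self) -> np.ndarray:
        return self.z0_um + np.arange(self.values.shape[2]) * self.z_pitch_um

    @property
    def z_span_um(self) -> float:
        """Depth span from first to last plane."""
        return float(self.z_pitch_um * (self.values.shape[2] - 1))

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("volume", data=self.values.astype(np.float32))
            d.attrs["pixel_pitch_um"] = self.pixel_pitch_um
            d.attrs["z_pitch_um"] = self.z_pitch_um
            d.attrs["z0_um"] = self.z0_um
            d.attrs["mode"] = self.mode


@dataclass(frozen=True)
class FocusMetrics:
    ef: float
    power_ratio: float
    fwhm_um: float
    fluence_j_cm2: float


def lowpass(trace: PATimeSeries, spec: FilterSpec = FilterSpec()) -> PATimeSeries:
    """Apply the low-pass; zero-phase (filtfilt) by default."""
    filtered = _lowpass_array(trace.samples[None, :], trace.dt_ns, spec)[0]
    return PATimeSeries(filtered, trace.dt_ns, trace.t0_ns, trace.position_um)


def _lowpass_array(traces: np.ndarray, dt_ns: float,
                   spec: FilterSpec) -> np.ndarray:
    nyquist_mhz = 1e3 / (2.0 * dt_ns)
    if spec.cutoff_mhz >= nyquist_mhz:
        raise ValueError(
            f"cutoff {spec.cutoff_mhz} MHz >= Nyquist {nyquist_mhz} MHz")
    b, a = butter(spec.order, spec.cutoff_mhz / nyquist_mhz)
    if spec.zero_phase:
        return filtfilt(b, a, traces, axis=-1)
    from scipy.signal import lfilter

    return lfilter(b, a, traces, axis=-1)


def time_to_depth(t_ns, c_m_per_s: float = SPEED_OF_SOUND_WATER):
    """One-way time-of-flight to depth: z[um] = c * t."""
    if c_m_per_s <= 0:
        raise ValueError("speed of sound must be positive")
    return np.asarray(t_ns, dtype=float) * (c_m_per_s * 1e-3)


def _detect(traces: np.ndarray, detect: str) -> np.ndarray:
    if detect == "envelope":
        return np.abs(hilbert(traces, axis=-1))
    if detect == "positive":
        return np.maximum(traces, 0.0)
    raise ValueError("detect must be 'envelope' or 'positive'")


def _rasterise(grid: ScanGrid, per_position: np.ndarray):
    """Place per-position scalars onto the bounding lattice of the grid."""
    pos = grid.positions_um
    step = grid.step_um
    x0, y0 = pos[:, 0].min(), pos[:, 1].min()
    ix = np.rint((pos[:, 0] - x0) / step).astype(int)
    iy = np.rint((pos[:, 1] - y0) / step).astype(int)
    shape = (iy.max() + 1, ix.max() + 1)
    if per_position.ndim == 1:
        out = np.zeros(shape)
        out[iy, ix] = per_position
    else:
        out = np.zeros(shape + per_position.shape[1:])
        out[iy, ix, ...] = per_position
    mask = np.zeros(shape, dtype=bool)
    mask[iy, ix] = True
    return out, mask, (y0, x0)


def mip(frames: PAFrameSet, filter_spec: FilterSpec | None = FilterSpec(),
        detect: str = "envelope") -> PAImage:
    """Per-position maximum of the detected (default: envelope) trace."""
    if frames.n_positions == 0:
        raise ValueError("empty frame set")
    traces = frames.traces
    if filter_spec is not None:
        traces = _lowpass_array(traces, frames.dt_ns, filter_spec)
    amp = _detect(traces, detect).max(axis=-1)
    values, mask, origin = _rasterise(frames.grid, amp)
    return PAImage(values, frames.grid.step_um, origin, mask,
                   frames.plane_z_um)


def assemble_volume_acoustic(frames: PAFrameSet,
                             c_m_per_s: float = SPEED_OF_SOUND_WATER,
                             filter_spec: FilterSpec | None = FilterSpec(),
                             detect: str = "positive") -> PAVolume:
    """Depth-resolved volume: each trace mapped onto z = c*t.

    The z axis is the (uniform) time axis scaled by the speed of sound;
    z pitch = c * dt.  Samples at negative depth (pre-trigger padding)
    are dropped.
    """
    traces = frames.traces
    if filter_spec is not None:
        traces = _lowpass_array(traces, frames.dt_ns, filter_spec)
    amp = _detect(traces, detect)
    z = time_to_depth(np.arange(amp.shape[1]) * frames.dt_ns + frames.t0_ns,
                      c_m_per_s)
    keep = z >= 0
    vol, mask, origin = _rasterise(frames.grid, amp[:, keep])
    return PAVolume(vol, frames.grid.step_um,
                    time_to_depth(frames.dt_ns, c_m_per_s),
                    float(z[keep][0]), "acoustic", mask)


def assemble_volume_optical(per_plane_images: list[PAImage]) -> PAVolume:
    """Stack per-focal-plane MIPs into a volume (z pitch = plane interval)."""
    if not per_plane_images:
        raise ValueError("need at least one plane image")
    first = per_plane_images[0]
    zs = np.array([im.plane_z_um for im in per_plane_images], dtype=float)
    if len(zs) > 1:
        dz = np.diff(zs)
        if (dz <= 0).any():
            raise ValueError("plane z positions must be strictly increasing")
        if not np.allclose(dz, dz[0]):
            raise ValueError("plane spacing must be uniform")
        z_pitch = float(dz[0])
    else:
        z_pitch = 0.0
    for im in per_plane_images[1:]:
        if im.shape != first.shape or im.pixel_pitch_um != first.pixel_pitch_um:
            raise ValueError("plane images must share the same grid")
    vol = np.stack([im.values for im in per_plane_images], axis=-1)
    return PAVolume(vol, first.pixel_pitch_um, z_pitch, float(zs[0]),
                    "optical", first.mask)


def _radial_distance(shape, center, pitch):
    yy, xx = np.indices(shape)
    return np.hypot(yy - center[0], xx - center[1]) * pitch


def enhancement_factor(focus_image: SpeckleImage,
                       focal_spot_center: tuple[int, int],
                       fwhm_um: float,
                       core_mask: np.ndarray | None = None) -> float:
    """Peak intensity in the focal disc over the mean background intensity.

    Background = in-core pixels farther than 3x the focus FWHM from the
    focal spot; a zero background yields +inf with a warning.
    """
    img = focus_image.intensity
    if not (img > 0).any():
        raise ValueError("image is identically zero")
    r = _radial_distance(img.shape, focal_spot_center,
                         focus_image.pixel_pitch_um)
    focal = r <= fwhm_um / 2.0
    if not focal.any():
        focal = r == r.min()
    bg = r > 3.0 * fwhm_um
    if core_mask is not None:
        bg &= core_mask
    peak = float(img[focal].max())
    bg_mean = float(img[bg].mean()) if bg.any() else 0.0
    if bg_mean == 0.0:
        warnings.warn("zero background mean; enhancement factor undefined")
        return np.inf
    return peak / bg_mean


def power_ratio(focus_image: SpeckleImage,
                focal_spot_center: tuple[int, int], fwhm_um: float,
                core_mask: np.ndarray | None = None) -> float:
    """Fraction of total (in-core) energy inside the FWHM-diameter disc."""
    img = focus_image.intensity
    r = _radial_distance(img.shape, focal_spot_center,
                         focus_image.pixel_pitch_um)
    focal = r <= fwhm_um / 2.0
    if not focal.any():
        focal = r == r.min()
    total_mask = core_mask if core_mask is not None \
        else np.ones(img.shape, dtype=bool)
    total = float(img[total_mask].sum())
    if total <= 0:
        raise ValueError("total energy is zero")
    return float(img[focal & total_mask].sum()) / total


def _fwhm_linear(y: np.ndarray, pitch: float) -> float:
    """FWHM of a 1D profile by linear interpolation at half maximum."""
    y = np.asarray(y, dtype=float)
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0
    if y[0] >= y[ipk] or y[-1] >= y[ipk]:
        raise ValueError("profile peak must exceed its endpoints")
    left = None
    for i in range(ipk, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0
            left = i - frac
            break
    right = None
    for i in range(ipk, y.size - 1):
        if y[i + 1] <= half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0
            right = i + frac
            break
    if left is None or right is None:
        raise ValueError("no half-maximum crossings on both sides of the peak")
    return float((right - left) * pitch)


def profile_fwhm(image, line: str = "horizontal",
                 through: tuple[int, int] | None = None,
                 pixel_pitch_um: float | None = None) -> float:
    """Linear-interpolated FWHM of the intensity profile through the peak.

    ``image`` may be a 2D array-bearing object (SpeckleImage / PAImage)
    or a 1D profile (then ``pixel_pitch_um`` is required).
    """
    if hasattr(image, "intensity"):
        arr, pitch = image.intensity, image.pixel_pitch_um
    elif hasattr(image, "values"):
        arr, pitch = image.values, image.pixel_pitch_um
    else:
        arr = np.asarray(image, dtype=float)
        if arr.ndim == 1:
            if pixel_pitch_um is None:
                raise ValueError("pixel_pitch_um required for a raw profile")
            return _fwhm_linear(arr, pixel_pitch_um)
        pitch = pixel_pitch_um
        if pitch is None:
            raise ValueError("pixel_pitch_um required for a raw image")
    if through is None:
        through = np.unravel_index(np.argmax(arr), arr.shape)
    if line == "horizontal":
        prof = arr[through[0], :]
    elif line == "vertical":
        prof = arr[:, through[1]]
    else:
        raise ValueError("line must be 'horizontal' or 'vertical'")
    return _fwhm_linear(prof, pitch)


def _gaussian(x, amp, mu, sigma, off):
    return amp * np.exp(-(x - mu) ** 2 / (2.0 * sigma**2)) + off


def fit_gaussian_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of an unweighted least-squares Gaussian fit (moment init)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    off0 = float(y.min())
    w = np.clip(y - off0, 0, None)
    if w.sum() <= 0:
        raise ValueError("degenerate profile for Gaussian fit")
    mu0 = float((x * w).sum() / w.sum())
    sigma0 = float(np.sqrt(((x - mu0) ** 2 * w).sum() / w.sum())) or (x[1] - x[0])
    popt, _ = curve_fit(_gaussian, x, y,
                        p0=[float(y.max() - off0), mu0, sigma0, off0],
                        maxfev=10000)
    return abs(popt[2]) * _FWHM


def lateral_resolution_esf(image: PAImage, edge_region: tuple[slice, slice],
                           n_adjacent: int = 10, axis: int = 1) -> float:
    """Lateral resolution from an edge: averaged ESF -> derivative LSF ->
    FWHM of its Gaussian fit.

    ``edge_region`` selects a patch containing a monotone edge; profiles
    run along ``axis`` (1 = across columns) and ``n_adjacent`` adjacent
    profiles are averaged.
    """
    patch = image.values[edge_region]
    if axis == 0:
        patch = patch.T
    if patch.shape[0] < n_adjacent:
        raise ValueError(
            f"edge region has only {patch.shape[0]} adjacent profiles, "
            f"need {n_adjacent}")
    esf = patch[:n_adjacent].mean(axis=0)
    d = np.diff(esf)
    if d.size and not ((d >= -1e-12).all() or (d <= 1e-12).all()):
        sign = np.sign(d[np.abs(d).argmax()])
        if (np.sign(d) == -sign).sum() > d.size // 4:
            warnings.warn("ESF is not monotone after averaging; "
                          "fitting best effort")
    lsf = np.abs(np.gradient(esf))
    x = np.arange(esf.size) * image.pixel_pitch_um
    return fit_gaussian_fwhm(x, lsf)


def axial_resolution(volume: PAVolume, yx: tuple[int, int]) -> float:
    """Axial FWHM (Gaussian fit) of the z-profile through a structure.

    The profile must have a single dominant lobe: secondary lobes above
    half the main peak raise an error listing their z positions.  The
    fit spans the whole profile, so the zero baseline on either side of
    the lobe constrains the tails.
    """
    prof = volume.values[yx[0], yx[1], :].astype(float)
    z = volume.z_coords_um
    ipk = int(np.argmax(prof))
    half = prof[ipk] / 2.0
    above = prof >= half
    # count connected lobes above half maximum
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1).size + int(above[0])
    if edges > 1:
        lobes = z[above]
        raise ValueError(
            f"multi-lobed z-profile; lobes above half maximum near z = "
            f"{np.unique(np.round(lobes, 1))} um")
    return fit_gaussian_fwhm(z, prof)


def fluence(pulse_energy_nj: float, focus_diameter_um: float) -> float:
    """Optical fluence in J/cm^2 of the pulse energy over the focal disc."""
    if focus_diameter_um <= 0:
        raise ValueError("focus diameter must be positive")
    energy_j = pulse_energy_nj * 1e-9
    area_cm2 = np.pi * (focus_diameter_um / 2.0 * 1e-4) ** 2
    return energy_j / area_cm2
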