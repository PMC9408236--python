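"""Photoacoustic A-line synthesis.

Converts a focused excitation spot interrogating an absorber map into
band-limited, time-resolved ultrasound signals.  The acoustic model is
delay-only: each depth slice of the excited source distribution
contributes a copy of the sensor impulse response delayed by its
one-way time of flight ``z / c``.  Attenuation, diffraction and 1/r
spreading are neglected — over the sub-millimetre depth ranges of a
needle endomicroscope, with a nearly omni-directional fibre-tip sensor,
these are second-order relative to arrival-time geometry.

The sensor is modelled purely by its band-limited impulse response: a
Gaussian-envelope cosine burst whose carrier is the centre frequency
(default 8 MHz) and whose envelope width is set so the amplitude
spectrum's -6 dB full width equals the specified bandwidth
(default 6.5 MHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .calibration import ScanGrid
from .phantoms import AbsorberMap

__all__ = [
    "SensorModel",
    "ExcitationFocus",
    "PATimeSeries",
    "PAFrameSet",
    "sensor_impulse_response",
    "simulate_a_line",
    "simulate_frame",
    "SPEED_OF_SOUND_WATER",
]

SPEED_OF_SOUND_WATER = 1485.0        # m/s, acoustic coupling medium

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))       # FWHM / sigma for a Gaussian
# amplitude ratio at -6 dB; for a Gaussian spectrum the -6 dB full width
# is 2*sqrt(2*ln(1/r6)) sigma_f
_R6 = 10.0 ** (-6.0 / 20.0)
_W6 = 2.0 * np.sqrt(2.0 * np.log(1.0 / _R6))


@dataclass(frozen=True)
class SensorModel:
    """Band-limited, omnidirectional ultrasound sensor."""

    center_freq_mhz: float = 8.0
    minus6db_bandwidth_mhz: float = 6.5
    sample_rate_mhz: float = 250.0

    def __post_init__(self):
        if not 0 < self.minus6db_bandwidth_mhz < 2 * self.center_freq_mhz:
            raise ValueError("need 0 < bandwidth < 2 * center frequency")
        if self.sample_rate_mhz <= 4 * self.center_freq_mhz:
            raise ValueError("sample rate must exceed 4x centre frequency")

    @property
    def dt_ns(self) -> float:
        return 1e3 / self.sample_rate_mhz

    @property
    def envelope_sigma_ns(self) -> float:
        sigma_f_mhz = self.minus6db_bandwidth_mhz / _W6
        return 1e3 / (2.0 * np.pi * sigma_f_mhz)


@dataclass(frozen=True)
class ExcitationFocus:
    """Gaussian focal spot of the wavefront-shaped excitation beam."""

    position_um: tuple[float, float] = (0.0, 0.0)   # (x, y)
    plane_z_um: float = 0.0
    lateral_fwhm_um: float = 1.2
    axial_fwhm_um: float = 22.0       # depth of field of the focus
    pulse_energy_nj: float = 20.0

    def __post_init__(self):
        if self.lateral_fwhm_um <= 0 or self.axial_fwhm_um <= 0:
            raise ValueError("focus extents must be positive")

    @property
    def lateral_sigma_um(self) -> float:
        return self.lateral_fwhm_um / _FWHM

    @property
    def axial_sigma_um(self) -> float:
        return self.axial_fwhm_um / _FWHM

    def at(self, x_um: float, y_um: float) -> "ExcitationFocus":
        return ExcitationFocus((x_um, y_um), self.plane_z_um,
                               self.lateral_fwhm_um, self.axial_fwhm_um,
                               self.pulse_energy_nj)


@dataclass(frozen=True)
class PATimeSeries:
    samples: np.ndarray
    dt_ns: float
    t0_ns: float = 0.0
    position_um: tuple[float, float, float] | None = None   # (x, y, plane_z)

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if not np.isfinite(s).all():
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def times_ns(self) -> np.ndarray:
        return self.t0_ns + np.arange(self.samples.size) * self.dt_ns


@dataclass(frozen=True)
class PAFrameSet:
    """Per-scan-position time series in raster order."""

    traces: np.ndarray               # (P, nt)
    dt_ns: float
    t0_ns: float
    grid: ScanGrid
    plane_z_um: float = 0.0

    @property
    def n_positions(self) -> int:
        return self.traces.shape[0]

    def trace(self, i: int) -> PATimeSeries:
        x, y = self.grid.positions_um[i]
        return PATimeSeries(self.traces[i], self.dt_ns, self.t0_ns,
                            (x, y, self.plane_z_um))

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=self.traces)
            d.attrs["dt_ns"] = self.dt_ns
            d.attrs["t0_ns"] = self.t0_ns
            d.attrs["plane_z_um"] = self.plane_z_um
            g = f.create_dataset("positions_um", data=self.grid.positions_um)
            g.attrs["fov_diameter_um"] = self.grid.fov_diameter_um
            g.attrs["step_um"] = self.grid.step_um
            g.attrs["center_um"] = self.grid.center_um
            g.attrs["plane_zs_um"] = self.grid.plane_zs_um


def sensor_impulse_response(sensor: SensorModel,
                            duration_ns: float = 800.0) -> PATimeSeries:
    """Gaussian-envelope cosine burst centred at t = 0.

    Carrier = centre frequency; envelope sigma set so the amplitude
    spectrum's -6 dB full width equals the sensor bandwidth.
    """
    sigma = sensor.envelope_sigma_ns
    if duration_ns < 6.0 * sigma:
        raise ValueError(
            f"duration {duration_ns} ns must cover >= 6 envelope sigma "
            f"({6 * sigma:.0f} ns)")
    dt = sensor.dt_ns
    n = int(round(duration_ns / dt)) | 1            # odd -> sample at t=0
    t = (np.arange(n) - n // 2) * dt
    h = np.exp(-t**2 / (2.0 * sigma**2)) * np.cos(
        2e-3 * np.pi * sensor.center_freq_mhz * t)
    return PATimeSeries(h, dt, t0_ns=t[0])


def _axial_source(phantom: AbsorberMap, focus: ExcitationFocus) -> np.ndarray:
    """Per-depth-slice excited source strength s(z) for one focus position."""
    y = phantom.axis_coords(0)
    x = phantom.axis_coords(1)
    z = phantom.axis_coords(2)
    fx, fy = focus.position_um
    wy = np.exp(-(y - fy) ** 2 / (2 * focus.lateral_sigma_um**2))
    wx = np.exp(-(x - fx) ** 2 / (2 * focus.lateral_sigma_um**2))
    wz = np.exp(-(z - focus.plane_z_um) ** 2 / (2 * focus.axial_sigma_um**2))
    lateral = np.einsum("yxz,y,x->z", phantom.values, wy, wx)
    return focus.pulse_energy_nj * lateral * wz


def _delay_bank(z_um: np.ndarray, sensor: SensorModel, c_m_per_s: float,
                n_samples: int, t0_ns: float) -> np.ndarray:
    """(nz, nt) matrix of impulse responses delayed by z / c."""
    sigma = sensor.envelope_sigma_ns
    dt = sensor.dt_ns
    t = t0_ns + np.arange(n_samples) * dt                  # (nt,)
    c_um_per_ns = c_m_per_s * 1e-3
    tau = z_um[:, None] / c_um_per_ns                      # (nz, 1)
    arg = t[None, :] - tau
    return np.exp(-arg**2 / (2.0 * sigma**2)) * np.cos(
        2e-3 * np.pi * sensor.center_freq_mhz * arg)


def _default_window(phantom: AbsorberMap, sensor: SensorModel,
                    c_m_per_s: float) -> tuple[float, int]:
    zmax = phantom.axis_coords(2)[-1]
    pad = 4.0 * sensor.envelope_sigma_ns
    t0 = -pad
    t_end = zmax / (c_m_per_s * 1e-3) + pad
    n = int(np.ceil((t_end - t0) / sensor.dt_ns)) + 1
    return t0, n


def simulate_a_line(phantom: AbsorberMap, focus: ExcitationFocus,
                    sensor: SensorModel,
                    c_m_per_s: float = SPEED_OF_SOUND_WATER,
                    noise_sd: float = 0.0, seed=None,
                    t0_ns: float | None = None,
                    n_samples: int | None = None) -> PATimeSeries:
    """Time-resolved PA signal for a single focus position.

    ``signal(t) = sum_z s(z) h(t - z/c) + noise`` where s(z) is the
    absorption weighted by the 3D Gaussian focus and scaled by the pulse
    energy.
    """
    if c_m_per_s <= 0:
        raise ValueError("speed of sound must be positive")
    y, x = phantom.axis_coords(0), phantom.axis_coords(1)
    fx, fy = focus.position_um
    if not (y[0] <= fy <= y[-1] and x[0] <= fx <= x[-1]):
        raise ValueError(f"focus position {(fx, fy)} outside the phantom grid")
    if t0_ns is None or n_samples is None:
        d_t0, d_n = _default_window(phantom, sensor, c_m_per_s)
        t0_ns = d_t0 if t0_ns is None else t0_ns
        n_samples = d_n if n_samples is None else n_samples
    s = _axial_source(phantom, focus)
    bank = _delay_bank(phantom.axis_coords(2), sensor, c_m_per_s,
                       n_samples, t0_ns)
    sig = s @ bank
    if noise_sd > 0:
        sig = sig + np.random.default_rng(seed).normal(0, noise_sd, sig.shape)
    return PATimeSeries(sig, sensor.dt_ns, t0_ns,
                        (fx, fy, focus.plane_z_um))


def simulate_frame(phantom: AbsorberMap, grid: ScanGrid,
                   focus: ExcitationFocus, sensor: SensorModel,
                   c_m_per_s: float = SPEED_OF_SOUND_WATER,
                   noise_sd: float = 0.0, seed=None,
                   plane_z_um: float | None = None) -> PAFrameSet:
    """One A-line per scan position, raster order; vectorised.

    Per depth slice the lateral Gaussian excitation integral is a
    Gaussian filtering of the slice sampled at the scan positions
    (bilinear interpolation between voxel centres), which is the same
    voxel sum as :func:`simulate_a_line` up to interpolation on
    off-lattice positions.
    """
    pz = focus.plane_z_um if plane_z_um is None else plane_z_um
    y, x = phantom.axis_coords(0), phantom.axis_coords(1)
    px, py = grid.positions_um[:, 0], grid.positions_um[:, 1]
    if (py.min() < y[0] - 1e-9 or py.max() > y[-1] + 1e-9
            or px.min() < x[0] - 1e-9 or px.max() > x[-1] + 1e-9):
        raise ValueError("scan grid extends beyond the phantom's lateral extent")
    dy, dx, _ = phantom.pitch_um
    sig_y, sig_x = focus.lateral_sigma_um / dy, focus.lateral_sigma_um / dx
    z = phantom.axis_coords(2)
    wz = np.exp(-(z - pz) ** 2 / (2 * focus.axial_sigma_um**2))
    # sample the laterally blurred slices at the scan positions
    iy = (py - y[0]) / dy
    ix = (px - x[0]) / dx
    nz = z.size
    s = np.empty((grid.n_positions, nz))
    # normalisation: gaussian_filter is a unit-sum kernel; rescale to the
    # unnormalised Gaussian weight sum used by simulate_a_line
    norm = 2.0 * np.pi * sig_y * sig_x
    for j in range(nz):
        blurred = gaussian_filter(phantom.values[:, :, j],
                                  (sig_y, sig_x), mode="constant",
                                  truncate=6.0)
        s[:, j] = map_coordinates(blurred, [iy, ix], order=1,
                                  mode="constant") * norm
    s *= focus.pulse_energy_nj * wz[None, :]
    t0_ns, n_samples = _default_window(phantom, sensor, c_m_per_s)
    bank = _delay_bank(z, sensor, c_m_per_s, n_samples, t0_ns)
    traces = s @ bank
    if noise_sd > 0:
        traces = traces + np.random.default_rng(seed).normal(
            0, noise_sd, traces.shape)
    return PAFrameSet(traces, sensor.dt_ns, t0_ns, grid, pz)
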