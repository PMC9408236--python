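"""Raster-scan photoacoustic imaging of a bar target and lateral
resolution metrology.

Simulates a full photoacoustic frame of a bar-target phantom at 0.5 um
scan step, forms the maximum-intensity-projection image and measures
the lateral resolution from an edge (ESF -> LSF -> Gaussian-fit FWHM).
"""

from mmfpam import (ExcitationFocus, FilterSpec, SensorModel,
                    acquisition_timing, lateral_resolution_esf,
                    make_bar_target, make_scan_grid, mip, simulate_frame)

phantom = make_bar_target(bar_width_um=20.0, gap_um=0.0, n_bars=1,
                          extent_um=(44.0, 44.0), pitch_um=0.25)
grid = make_scan_grid(fov_diameter_um=40.0, step_um=0.5)
focus = ExcitationFocus(lateral_fwhm_um=1.2)     # diffraction-scale spot

frames = simulate_frame(phantom, grid, focus, SensorModel())
image = mip(frames, FilterSpec(cutoff_mhz=20.0))

# the bar edge sits at y = +10 um; average 10 adjacent column profiles
erow = int(round((10.0 - image.origin_um[0]) / image.pixel_pitch_um))
nx = image.shape[1]
region = (slice(erow - 10, erow + 11), slice(nx // 2 - 5, nx // 2 + 5))
resolution = lateral_resolution_esf(image, region, n_adjacent=10, axis=0)

timing = acquisition_timing(grid.n_positions, 1)
print(f"scan positions: {grid.n_positions} (phi-40 um FOV, 0.5 um step)")
print(f"frame acquisition time at 22.7 kHz: {timing['frame_time_s']:.2f} s")
print(f"lateral resolution from the edge: {resolution:.2f} um")
print()
print("The measured resolution tracks the configured focus FWHM "
      f"({focus.lateral_fwhm_um} um): the image of a sharp edge is the "
      "edge spread function of the focal spot.")
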