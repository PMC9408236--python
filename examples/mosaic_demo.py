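"""Mosaicing: enlarge the field of view by translating the probe.

Simulates photoacoustic frames of a red-blood-cell smear while the
probe translates, registers consecutive frames by subpixel DFT
cross-correlation (10x upsampling) and stitches them onto one canvas
with running-average blending in the overlaps.
"""

import numpy as np

from mmfpam import (ExcitationFocus, FilterSpec, RegistrationConfig,
                    SensorModel, make_rbc_phantom, make_scan_grid, mip,
                    run_mosaic, simulate_frame)

phantom = make_rbc_phantom(24, cell_diameter_um=7.5,
                           extent_um=(70.0, 130.0), pitch_um=0.25, seed=4)
sensor, focus = SensorModel(), ExcitationFocus()

# 8 frames, phi-50 um FOV each, probe translating 60 um in total
centres = np.linspace(-30.0, 30.0, 8)
frames = []
for cx in centres:
    grid = make_scan_grid(50.0, 1.0, center_um=(float(cx), 0.0))
    fs = simulate_frame(phantom, grid, focus, sensor)
    frames.append(mip(fs, FilterSpec(20.0)))

canvas, trajectory = run_mosaic(frames, RegistrationConfig(upsample_factor=10))

print(f"frames: {len(frames)}, each {frames[0].shape} px "
      f"(phi-50 um, 1 um step)")
print("recovered probe trajectory (x, um):",
      ", ".join(f"{d.dx_um:.1f}" for d in trajectory))
h = (canvas.accumulator.shape[0] - 1) * canvas.fine_pitch_um
w = (canvas.accumulator.shape[1] - 1) * canvas.fine_pitch_um
print(f"mosaic canvas: {h:.0f} x {w:.0f} um "
      f"({canvas.fine_pitch_um:.1f} um canvas lattice)")
print()
print("The trajectory should step by ~8.6 um per frame; the canvas is "
      "one frame tall and frame + travel wide.")
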