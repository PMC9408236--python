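# Methods

This note records the models behind `mmfpam`, the defaults and why,
what the simulator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Fibre model and RVITM estimation

The ground-truth transmission matrix (TM) maps N binary micromirrors to
the complex field at each output-plane camera pixel.  Entries are
i.i.d. circular complex Gaussian with variance 1/N inside a circular
core (default ϕ100 µm at 1 µm camera pitch) and zero outside.  The 1/N
scaling keeps the all-ON reference intensity O(1) per pixel regardless
of N, so focusing gain reads directly as an intensity ratio.  This
model deliberately omits mode correlations, bending, polarisation and
chromatic effects: it is sufficient to validate the intensity-only
estimation algebra and the statistics of binary-amplitude focusing,
which are the package's subject, and no more.

Calibration displays the 2N columns of `[H1, H2]` (all H1 columns
first, then all H2; Sylvester construction, so N must be a power of
two).  The estimator

    RVITM = [2 I_mk − I_m1] · [H, −H]ᵀ

equals `2N · A_R A_mn cos(θ_mn − φ_R)` exactly in the noiseless case;
the package keeps this raw scale because focus-pattern selection is
rank-based and scale-free.  The subtracted all-ON column `I_m1`
provably cancels under `[H, −H]ᵀ` and is retained only for fidelity to
the estimator's published form (a test asserts the cancellation).
One camera pixel is treated as one output mode.  Focus patterns switch
ON the ⌈0.30·N⌉ top-ranked mirrors; ties break toward the lowest
mirror index so selections are deterministic.  The desk-scale default
is N = 1024 (the physical instrument uses 16384 = 128²); N is fully
configurable and every result that depends on N is tested as a trend
over N ∈ {64, 256, 1024}.

Expected behaviour under this model: the top-30% binary-amplitude
pattern yields an enhancement factor (focus peak over mean in-core
speckle background, background taken beyond 3 focus-FWHM from the
spot) of roughly 0.2·N, checked in the tests as median EF ≥ N/20,
monotone in N, and ≥5× the intensity of random 30%-ON patterns.
Because TM entries are spatially uncorrelated, the simulated focus is a
single-pixel spike; physical focus diameters (~1.2 µm) are therefore a
*configuration input* to the photoacoustic simulator, not an emergent
property of the fibre model.

## Scan grid and acquisition timing

Scan grids are square lattices with one point pinned to the FOV centre,
keeping points whose centre lies in the closed FOV disc, raster
ordered.  A ϕ100 µm FOV yields 7845 positions at 1 µm step and 31417
at 0.5 µm (the lattice-count analogues of the instrument's ~7850 and
~31500 pixels).  Acquisition time assumes one DMD pattern per position
at the 22.7 kHz display rate: frame time = positions/rate, volume time
= planes × frame time.

## Photoacoustic synthesis

The excitation focus is a separable 3D Gaussian: lateral FWHM 1.2 µm
(the instrument's measured focus diameter), axial FWHM 22 µm (its
estimated depth of field), pulse energy 20 nJ.  The per-depth source
strength is the focus-weighted absorption integral; the sensor
contributes a Gaussian-envelope cosine impulse response with 8 MHz
carrier and an envelope width set so the amplitude spectrum's −6 dB
full width is 6.5 MHz.  Propagation is delay-only (z = c·t one-way,
c = 1485 m/s): no attenuation, diffraction or 1/r spreading, justified
over sub-millimetre depths with a near-omnidirectional fibre-tip
sensor.  Default sampling is 250 MHz over a window sized to the
phantom depth plus four envelope widths.  Amplitudes are in arbitrary
units, linear in absorption and pulse energy; no absolute pressure
calibration is attempted.

`simulate_frame` evaluates the same voxel sum as `simulate_a_line` via
per-slice Gaussian filtering sampled at the scan positions (bilinear
between voxel centres); the two agree exactly on-lattice up to the
discrete-vs-continuous Gaussian normalisation (<1% for the default
geometries) and a test pins this equivalence.

## Image formation and detection choice

Traces are low-pass filtered at 20 MHz with a 4th-order Butterworth
applied forward–backward (zero phase; the filter realisation beyond
"20 MHz low-pass" was an open choice).  2D MIP images project the
analytic-signal envelope, which is sign-insensitive and appropriate for
bipolar pulses.  The **acoustic volume projects the positive part of
the filtered signal instead of the envelope**: the axial width of a PA
pulse is carrier-limited — with the default sensor the positive peak
is ~40 ns wide (≈60 µm at 1485 m/s) while the envelope is ~136 ns
(≈200 µm) — so envelope detection would erase the axial structure the
acoustic mode exists to resolve.  Both operations take a `detect`
argument, and the MIP-of-volume = 2D-MIP identity is tested with a
consistent detector.  Secondary positive lobes of the carrier sit at
~9% of the main peak, below the half-maximum threshold used by the
single-lobe check in `axial_resolution`.

Axial resolution is the FWHM of a Gaussian least-squares fit over the
whole z-profile (moment initialisation; the flanking zero baseline
constrains the tails — fitting only the cropped central lobe was found
to inflate the width of cosine-shaped lobes by ~40%).  Lateral
resolution follows the ESF→LSF chain: average 10 adjacent profiles
across an edge, differentiate, fit a Gaussian, report its FWHM.
Enhancement-factor background is the in-core region farther than 3
focus-FWHM from the spot (the notion of "background" was open); the
power-ratio focal area is the disc of one FWHM diameter, consistent
with fluence = energy / (π (d/2)²), which gives 1.77 J/cm² for 20 nJ
over ϕ1.2 µm.

Coordinates: x right, y down, z away from the fibre tip; 0-based
indices; pixel centres on lattice points; micromirror grids flatten
row-major.

## Mosaicing

Registration returns the content displacement between consecutive
frames.  The coarse integer shift comes from FFT cross-correlation;
when frames carry validity masks (a circular FOV has a *static* rim
that plain phase correlation locks onto) the coarse stage uses masked
normalised cross-correlation instead.  Subpixel refinement evaluates an
upsampled DFT (default κ = 10) of the cross-power spectrum locally —
on the cropped common overlap in the masked path, so non-shared content
cannot bias the peak — followed by parabolic interpolation between the
1/κ samples, which removes the systematic 1/(2κ) quantisation bias
that would otherwise accumulate over long constant-velocity sequences.
This single-step local evaluation has the same 1/κ precision contract
as literally upsampling both images κ-fold at a fraction of the cost;
κ-fold bicubic upsampling is retained where it matters for geometry:
frames are placed on a κ-times-finer canvas lattice, accumulated with
per-pixel visit counts, and rendered as accumulator/count so overlaps
average.  Registration is pairwise-sequential (frame k vs k−1) with no
global adjustment; a normalised overlap correlation below 0.2 (tunable)
aborts with the offending frame index.  Frames are not
intensity-normalised before stitching.  By default the canvas is
allocated to the registered trajectory's exact bounding box; an
explicit pre-allocated extent is honoured and overflow raises with the
required growth.

## Phantoms

Bar targets are binary, axis-aligned, in a thin plane.  Carbon fibres
are absorbing cylinders (default radius 3.5 µm) parallel to x at given
(y, z) poses.  Red blood cells use a stylised rotationally symmetric
biconcave thickness profile, `(0.45 + 1.9 u²)·√(1−u²)` with
u = 2ρ/diameter — thinner at the centre than the rim, which is the
property the imaging demonstrations rely on; no specific biomechanical
parameterisation is claimed.  Cells are placed by seeded rejection
sampling with a one-diameter minimum centre distance.

## What the simulator does not show

Passing tests validate the estimation algebra, focusing statistics,
arrival-time geometry, metrology chains and registration/stitching —
under an uncorrelated fibre model, a separable Gaussian focus,
noise-free or Gaussian-noise measurements, and delay-only acoustics.
They do not establish performance under real modal correlations, fibre
bending, aberrated peripheral foci, acoustic attenuation/diffraction,
or detector nonidealities.  Camera noise defaults are zero and the
read/shot-noise parameters are artifact defaults with no measured
counterpart.

## Problem sizes used by the test suite

The suite runs desk-scale problems chosen as the smallest sizes at
which each property is cleanly expressed: 8×8–33×33 camera grids for
estimation/focusing (N up to 1024, with the focusing path evaluated
through the single-target-mode form of the same estimator), ϕ40 µm
FOV for end-to-end resolution metrology, ϕ6 µm scan grids over thin
absorbers for axial sectioning, and a 40-frame ϕ100 µm sequence with
150 µm travel for mosaicing.  Full-scale runs (N = 16384, ϕ100 µm at
0.5 µm step) use the same code paths via configuration.
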