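"""Real-time-style video mosaicing.

Enlarges the probe's field of view by registering consecutive frames
with subpixel DFT cross-correlation and stitching them onto a large
canvas with running-average blending in overlap regions.

Registration: the coarse integer shift comes from FFT cross-correlation
(masked normalized cross-correlation when validity masks are supplied,
since a circular field of view has a *static* rim that plain phase
correlation would lock onto), refined to 1/kappa pixel by evaluating an
upsampled DFT of the cross-power spectrum in a small neighbourhood of
the coarse peak — the single-step matrix-DFT algorithm, which reaches
the same precision as literally upsampling both images kappa-fold at a
tiny fraction of the cost.

Stitching: frames are bicubically upsampled kappa-fold and accumulated
on a kappa-times-finer canvas lattice at offsets rounded to that
lattice; the rendered canvas divides the accumulator by per-pixel visit
counts, so overlaps average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom
from skimage.registration import phase_cross_correlation

from .imaging import PAImage

__all__ = [
    "Displacement",
    "RegistrationConfig",
    "MosaicCanvas",
    "register_translation",
    "stitch",
    "run_mosaic",
    "mosaic_nrmse",
]


@dataclass(frozen=True)
class Displacement:
    """Subpixel frame-to-frame displacement, (dy, dx) in pixels and um."""

    dy_px: float
    dx_px: float
    pixel_pitch_um: float = 1.0
    confidence: float = 1.0

    @property
    def dy_um(self) -> float:
        return self.dy_px * self.pixel_pitch_um

    @property
    def dx_um(self) -> float:
        return self.dx_px * self.pixel_pitch_um

    def __add__(self, other: "Displacement") -> "Displacement":
        return Displacement(self.dy_px + other.dy_px,
                            self.dx_px + other.dx_px,
                            self.pixel_pitch_um,
                            min(self.confidence, other.confidence))


@dataclass(frozen=True)
class RegistrationConfig:
    upsample_factor: int = 10
    confidence_threshold: float = 0.2

    def __post_init__(self):
        if int(self.upsample_factor) != self.upsample_factor \
                or self.upsample_factor < 1:
            raise ValueError("upsample_factor must be an integer >= 1")


def _upsampled_dft(cross_power: np.ndarray, region: int, kappa: int,
                   offset_y: float, offset_x: float) -> np.ndarray:
    """Evaluate the inverse DFT of ``cross_power`` on a kappa-upsampled
    ``region x region`` grid starting at (offset_y, offset_x)."""
    ny, nx = cross_power.shape
    fy = np.fft.fftfreq(ny)
    fx = np.fft.fftfreq(nx)
    gy = (np.arange(region) + offset_y) / kappa
    gx = (np.arange(region) + offset_x) / kappa
    ky = np.exp(2j * np.pi * np.outer(gy, fy))
    kx = np.exp(2j * np.pi * np.outer(fx, gx))
    return ky @ cross_power @ kx


def _ncc_at_shift(a: np.ndarray, b: np.ndarray, dy: int, dx: int,
                  mask_a=None, mask_b=None) -> float:
    """Pearson correlation of the overlap when b is shifted by (dy, dx)."""
    # b(y, x) ~= a(y - dy, x - dx): overlap pairs a[y] with b[y + dy]
    ny, nx = a.shape
    ya0, yb0 = max(0, -dy), max(0, dy)
    xa0, xb0 = max(0, -dx), max(0, dx)
    h, w = ny - abs(dy), nx - abs(dx)
    if h <= 1 or w <= 1:
        return 0.0
    pa = a[ya0:ya0 + h, xa0:xa0 + w]
    pb = b[yb0:yb0 + h, xb0:xb0 + w]
    valid = np.ones(pa.shape, dtype=bool)
    if mask_a is not None:
        valid &= mask_a[ya0:ya0 + h, xa0:xa0 + w]
    if mask_b is not None:
        valid &= mask_b[yb0:yb0 + h, xb0:xb0 + w]
    if valid.sum() < 8:
        return 0.0
    va, vb = pa[valid], pb[valid]
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((va - va.mean()) * (vb - vb.mean())).mean() / (sa * sb))


def register_translation(frame_a, frame_b,
                         cfg: RegistrationConfig = RegistrationConfig(),
                         mask_a: np.ndarray | None = None,
                         mask_b: np.ndarray | None = None) -> Displacement:
    """Displacement of ``frame_b`` content relative to ``frame_a``.

    Returns d such that frame_b ~= frame_a translated by d (i.e. a
    feature at (y, x) in frame_a appears at (y + dy, x + dx) in
    frame_b).  Accepts PAImage or plain 2D arrays; PAImage masks are
    used automatically unless explicit masks are given.
    """
    a, pitch_a, ma = _unpack(frame_a)
    b, pitch_b, mb = _unpack(frame_b)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if not a.any() or not b.any():
        raise ValueError("cannot register an all-zero frame")
    mask_a = ma if mask_a is None else mask_a
    mask_b = mb if mask_b is None else mask_b
    kappa = int(cfg.upsample_factor)

    if mask_a is not None or mask_b is not None:
        mask_a = np.ones(a.shape, bool) if mask_a is None else mask_a
        mask_b = np.ones(b.shape, bool) if mask_b is None else mask_b
        coarse = phase_cross_correlation(
            a, b, reference_mask=mask_a, moving_mask=mask_b)
        shift = coarse[0] if isinstance(coarse, tuple) else coarse
        dy0, dx0 = -float(shift[0]), -float(shift[1])
        dy, dx = _refine_on_overlap(a, b, mask_a, mask_b,
                                    int(round(dy0)), int(round(dx0)), kappa)
    else:
        shift, _, _ = phase_cross_correlation(
            a, b, upsample_factor=kappa, normalization=None)
        dy, dx = -float(shift[0]), -float(shift[1])
    conf = _ncc_at_shift(a, b, int(round(dy)), int(round(dx)),
                         mask_a, mask_b)
    pitch = pitch_a or pitch_b or 1.0
    return Displacement(dy, dx, pitch, conf)


def _refine_on_overlap(a: np.ndarray, b: np.ndarray,
                       mask_a: np.ndarray, mask_b: np.ndarray,
                       dy0: int, dx0: int, kappa: int) -> tuple[float, float]:
    """Subpixel residual on the common overlap after the coarse shift.

    Cropping both frames to their overlap at the integer shift leaves
    two nearly identical images whose remaining displacement is
    subpixel, so a local upsampled-DFT evaluation around zero is
    unbiased by non-shared content.
    """
    ny, nx = a.shape
    ya0, yb0 = max(0, -dy0), max(0, dy0)
    xa0, xb0 = max(0, -dx0), max(0, dx0)
    h, w = ny - abs(dy0), nx - abs(dx0)
    if kappa == 1 or h < 8 or w < 8:
        return float(dy0), float(dx0)
    pa = a[ya0:ya0 + h, xa0:xa0 + w]
    pb = b[yb0:yb0 + h, xb0:xb0 + w]
    valid = mask_a[ya0:ya0 + h, xa0:xa0 + w] & mask_b[yb0:yb0 + h, xb0:xb0 + w]
    if not valid.any():
        return float(dy0), float(dx0)
    pa = np.where(valid, pa - pa[valid].mean(), 0.0)
    pb = np.where(valid, pb - pb[valid].mean(), 0.0)
    rdy, rdx = _refine(pa, pb, 0.0, 0.0, kappa)
    # residual must stay subpixel; otherwise trust the coarse shift
    if abs(rdy) > 1.5 or abs(rdx) > 1.5:
        return float(dy0), float(dx0)
    return dy0 + rdy, dx0 + rdx


def _refine(a: np.ndarray, b: np.ndarray, dy0: float, dx0: float,
            kappa: int) -> tuple[float, float]:
    """Local upsampled-DFT refinement around the integer shift (dy0, dx0).

    Convention: returns (dy, dx) such that b(y, x) ~= a(y - dy, x - dx).
    """
    if kappa == 1:
        return dy0, dx0
    cross = np.fft.fft2(b) * np.conj(np.fft.fft2(a))
    region = int(np.ceil(kappa * 1.5))
    # CC(s) peaks at s = (dy, dx); evaluate around the coarse estimate
    off_y = dy0 * kappa - region // 2
    off_x = dx0 * kappa - region // 2
    cc = np.abs(_upsampled_dft(cross, region, kappa, off_y, off_x))
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    # parabolic interpolation between upsampled samples removes the
    # 1/(2 kappa) quantisation bias of the grid argmax
    sy = iy + _parabolic_offset(cc[:, ix], iy)
    sx = ix + _parabolic_offset(cc[iy, :], ix)
    return (off_y + sy) / kappa, (off_x + sx) / kappa


def _parabolic_offset(c: np.ndarray, i: int) -> float:
    if i == 0 or i == c.size - 1:
        return 0.0
    denom = c[i - 1] - 2 * c[i] + c[i + 1]
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (c[i - 1] - c[i + 1]) / denom, -0.5, 0.5))


def _unpack(frame):
    if isinstance(frame, PAImage):
        return frame.values, frame.pixel_pitch_um, frame.mask
    return np.asarray(frame, dtype=float), None, None


@dataclass
class MosaicCanvas:
    """Accumulating stitched image with per-pixel visit counts.

    The canvas lattice is ``upsample_factor`` times finer than the frame
    lattice; ``origin_px`` is the frame-pixel coordinate (can be
    negative) of canvas pixel (0, 0).
    """

    accumulator: np.ndarray
    counts: np.ndarray
    upsample_factor: int
    pixel_pitch_um: float            # frame pixel pitch
    origin_px: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def allocate(cls, shape_px: tuple[float, float], upsample_factor: int,
                 pixel_pitch_um: float,
                 origin_px: tuple[float, float] = (0.0, 0.0)) -> "MosaicCanvas":
        k = upsample_factor
        ny = int(np.ceil(shape_px[0] * k)) + 1
        nx = int(np.ceil(shape_px[1] * k)) + 1
        return cls(np.zeros((ny, nx)), np.zeros((ny, nx)), k,
                   pixel_pitch_um, origin_px)

    @property
    def fine_pitch_um(self) -> float:
        return self.pixel_pitch_um / self.upsample_factor

    def rendered(self) -> np.ndarray:
        out = np.zeros_like(self.accumulator)
        np.divide(self.accumulator, self.counts, out=out,
                  where=self.counts > 0)
        return out

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.rendered().astype(np.float32))


def _upsample_frame(frame: PAImage, kappa: int):
    vals = zoom(frame.values, kappa, order=3, grid_mode=True,
                mode="grid-constant", prefilter=True)
    vals = np.clip(vals, 0.0, None)
    if frame.mask is not None:
        m = zoom(frame.mask.astype(float), kappa, order=0, grid_mode=True,
                 mode="grid-constant") > 0.5
    else:
        m = np.ones(vals.shape, dtype=bool)
    return vals, m


def stitch(canvas: MosaicCanvas, frame: PAImage,
           cumulative_offset: Displacement) -> MosaicCanvas:
    """Add a frame into the canvas at the given cumulative offset.

    The offset is rounded on the upsampled canvas lattice; out-of-canvas
    placement raises and reports the required growth.  In place.
    """
    k = canvas.upsample_factor
    vals, m = _upsample_frame(frame, k)
    oy = int(round((cumulative_offset.dy_px - canvas.origin_px[0]) * k))
    ox = int(round((cumulative_offset.dx_px - canvas.origin_px[1]) * k))
    ny, nx = vals.shape
    cy, cx = canvas.accumulator.shape
    if oy < 0 or ox < 0 or oy + ny > cy or ox + nx > cx:
        need_y = max(0, -oy) + max(0, oy + ny - cy)
        need_x = max(0, -ox) + max(0, ox + nx - cx)
        raise ValueError(
            f"frame at offset ({cumulative_offset.dy_px:.2f}, "
            f"{cumulative_offset.dx_px:.2f}) px falls outside the canvas; "
            f"grow by ({need_y / k:.1f}, {need_x / k:.1f}) frame pixels")
    sl = (slice(oy, oy + ny), slice(ox, ox + nx))
    canvas.accumulator[sl][m] += vals[m]
    canvas.counts[sl][m] += 1
    return canvas


def run_mosaic(frames: list[PAImage],
               cfg: RegistrationConfig = RegistrationConfig(),
               canvas_extent_px: tuple[float, float] | None = None
               ) -> tuple[MosaicCanvas, list[Displacement]]:
    """Register consecutive frames and stitch them all.

    Frame 0 is placed at the origin; each later frame is registered to
    its predecessor and placed at the summed offset.  The returned
    displacements are cumulative frame *placement* offsets (the probe
    trajectory): the negative of the registered content motion, since a
    fixed sample seen by a moving probe shows content moving opposite
    to the probe.  A registration
    whose overlap correlation falls below the confidence threshold
    aborts, reporting the frame index.  By default the canvas is
    allocated to the exact trajectory bounding box; an explicit
    ``canvas_extent_px`` is honoured instead (stitching errors if
    exceeded).
    """
    if not frames:
        raise ValueError("need at least one frame")
    pitch = frames[0].pixel_pitch_um
    cum = [Displacement(0.0, 0.0, pitch)]
    ones = np.ones(frames[0].shape, dtype=bool)
    for i in range(1, len(frames)):
        # the masked path handles the moving-window geometry exactly,
        # so it is used even for unmasked (rectangular) frames
        d = register_translation(
            frames[i - 1], frames[i], cfg,
            mask_a=frames[i - 1].mask if frames[i - 1].mask is not None else ones,
            mask_b=frames[i].mask if frames[i].mask is not None else ones)
        if d.confidence < cfg.confidence_threshold:
            raise RuntimeError(
                f"low-confidence registration at frame {i} "
                f"(confidence {d.confidence:.3f} < "
                f"{cfg.confidence_threshold})")
        cum.append(cum[-1] + Displacement(-d.dy_px, -d.dx_px,
                                          d.pixel_pitch_um, d.confidence))
    dys = np.array([c.dy_px for c in cum])
    dxs = np.array([c.dx_px for c in cum])
    h, w = frames[0].shape
    if canvas_extent_px is None:
        origin = (float(dys.min()), float(dxs.min()))
        extent = (dys.max() - dys.min() + h, dxs.max() - dxs.min() + w)
    else:
        origin = (float(min(dys.min(), 0.0)), float(min(dxs.min(), 0.0)))
        extent = canvas_extent_px
    canvas = MosaicCanvas.allocate(extent, cfg.upsample_factor, pitch, origin)
    for frame, off in zip(frames, cum):
        stitch(canvas, frame, off)
    return canvas, cum


def mosaic_nrmse(canvas: MosaicCanvas, truth_fine: np.ndarray,
                 exclude_border_frame_px: int = 2) -> float:
    """Normalised RMS error of the rendered canvas against a ground-truth
    image sampled on the same fine lattice, over covered pixels with a
    border ring (in frame pixels) eroded away.  Normalisation: truth range."""
    from scipy.ndimage import binary_erosion

    rendered = canvas.rendered()
    ny = min(rendered.shape[0], truth_fine.shape[0])
    nx = min(rendered.shape[1], truth_fine.shape[1])
    rendered, truth = rendered[:ny, :nx], truth_fine[:ny, :nx]
    covered = canvas.counts[:ny, :nx] > 0
    it = exclude_border_frame_px * canvas.upsample_factor
    if it > 0:
        covered = binary_erosion(covered, iterations=it)
    if not covered.any():
        raise ValueError("no covered pixels after border exclusion")
    err = rendered[covered] - truth[covered]
    rng = truth[covered].max() - truth[covered].min()
    return float(np.sqrt(np.mean(err**2)) / rng)
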