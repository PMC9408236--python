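"""End-to-end experiment orchestration.

``run_experiment`` wires the simulator, characterisation, acquisition
and image-formation modules into named desk-scale recipes:

* ``characterise`` — synthetic fibre + Hadamard calibration -> RVITM per
  focal plane (HDF5) and focusing metrics at probe pixels (CSV).
* ``image2d``      — raster-scanned photoacoustic MIP of a phantom (TIFF).
* ``volume3d``     — 3D volume with acoustic or optical sectioning (HDF5).
* ``mosaic``       — translated-frame sequence registered and stitched
  (TIFF + trajectory CSV).
* ``metrics``      — focusing/fluence metrics table from a fresh
  characterisation (CSV).

Everything is deterministic from (config, seed): the master seed fans
out to per-stage seeds, and re-running a recipe reproduces every output
byte-for-byte (checksums recorded in the run record exclude nothing).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calibration as cal
from . import fibre, imaging, io as mio, mosaic as mos
from .acoustics import (ExcitationFocus, SensorModel, simulate_frame)
from .config import RunConfig, config_hash, save_config
from .phantoms import make_bar_target, make_carbon_fibre_phantom, make_rbc_phantom

__all__ = ["RunRecord", "run_experiment"]

log = logging.getLogger("mmfpam")

RECIPES = ("characterise", "image2d", "volume3d", "mosaic", "metrics")


@dataclass(frozen=True)
class RunRecord:
    recipe: str
    config_hash: str
    seed: int
    manifest: dict[str, str]         # relative path -> sha256
    timings_s: dict[str, float]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "recipe": self.recipe, "config_hash": self.config_hash,
            "seed": self.seed, "manifest": self.manifest,
            "timings_s": self.timings_s}, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(timings, name):
    class _T:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t = time.perf_counter()
            return self

        def __exit__(self, *exc):
            timings[name] = time.perf_counter() - self.t
            log.info("stage %s: %.2f s", name, timings[name])

    return _T()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _plane_zs(cfg: RunConfig) -> list[float]:
    return [i * cfg.plane_interval_um for i in range(cfg.n_planes)]


def _sensor(cfg: RunConfig) -> SensorModel:
    return SensorModel(cfg.sensor_center_freq_mhz, cfg.sensor_bandwidth_mhz,
                       cfg.sample_rate_mhz)


def _focus(cfg: RunConfig) -> ExcitationFocus:
    return ExcitationFocus(lateral_fwhm_um=cfg.focus_fwhm_um,
                           axial_fwhm_um=cfg.focus_dof_um,
                           pulse_energy_nj=cfg.pulse_energy_nj)


def run_experiment(config: RunConfig, recipe: str, out_dir,
                   seed: int | None = None) -> RunRecord:
    """Execute a named pipeline end-to-end and write its outputs."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.seed if seed is None else int(seed)
    timings: dict[str, float] = {}
    save_config(config, out / "config.yaml")
    written = [out / "config.yaml"]

    try:
        fn = {"characterise": _run_characterise, "image2d": _run_image2d,
              "volume3d": _run_volume3d, "mosaic": _run_mosaic,
              "metrics": _run_metrics}[recipe]
        written += fn(config, out, master, timings)
    except Exception as exc:
        raise RuntimeError(f"recipe {recipe!r} failed: {exc}") from exc

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    record = RunRecord(recipe, config_hash(config), master, manifest, timings)
    record.save(out / "run_record.json")
    return record


def _characterise_stack(cfg: RunConfig, master: int, timings):
    shape = (cfg.output_grid, cfg.output_grid)
    with _stage(timings, "simulate_tm"):
        stack = fibre.generate_tm_stack(
            _plane_zs(cfg), cfg.n_mirrors, shape,
            seed=_stage_seed(master, "tm"),
            pixel_pitch_um=cfg.pixel_pitch_um,
            core_diameter_um=cfg.fov_diameter_um)
    patterns = cal.build_hadamard_pattern_set(cfg.n_mirrors)
    with _stage(timings, "characterise"):
        rvitms = cal.characterise_all_planes(
            stack, patterns, read_noise_sd=cfg.read_noise_sd,
            shot_scale=cfg.shot_scale, seed=_stage_seed(master, "noise"))
    return stack, patterns, rvitms


def _focus_metrics_rows(cfg: RunConfig, stack, patterns, rvitms):
    """EF / power ratio / FWHM at the central pixel of each plane."""
    rows = []
    for tm, rv in zip(stack, rvitms):
        centre = (tm.output_shape[0] // 2, tm.output_shape[1] // 2)
        fp = cal.select_focus_pattern(rv, centre, cfg.on_fraction)
        img = fibre.propagate(tm, fp.pattern)
        fwhm = imaging.profile_fwhm(img, through=centre)
        ef = imaging.enhancement_factor(img, centre, fwhm, tm.core_mask)
        pr = imaging.power_ratio(img, centre, fwhm, tm.core_mask)
        rows.append({"plane_z_um": tm.plane_z_um, "ef": ef,
                     "power_ratio": pr, "focus_fwhm_um": fwhm,
                     "fluence_j_cm2": imaging.fluence(
                         cfg.pulse_energy_nj, cfg.focus_fwhm_um)})
    return rows


def _write_metrics_csv(rows, path):
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _run_characterise(cfg, out, master, timings):
    stack, patterns, rvitms = _characterise_stack(cfg, master, timings)
    with _stage(timings, "persist"):
        mio.save_tm_stack(out / "tm_stack.h5", stack)
        mio.save_rvitm_stack(out / "rvitm_stack.h5", rvitms)
        _write_metrics_csv(_focus_metrics_rows(cfg, stack, patterns, rvitms),
                           out / "focus_metrics.csv")
    return [out / "tm_stack.h5", out / "rvitm_stack.h5",
            out / "focus_metrics.csv"]


def _phantom_for(cfg: RunConfig, master: int, kind: str):
    extent = (cfg.fov_diameter_um + 10, cfg.fov_diameter_um + 10)
    if kind == "bars":
        return make_bar_target(10.0, 10.0, 3, extent_um=extent,
                               pitch_um=cfg.step_um / 2)
    if kind == "rbc":
        n_cells = max(1, min(20, int(extent[0] * extent[1] / 450)))
        return make_rbc_phantom(n_cells, extent_um=extent,
                                pitch_um=cfg.step_um / 2,
                                seed=_stage_seed(master, "phantom"))
    if kind == "fibres":
        return make_carbon_fibre_phantom(
            2, extent_um=(extent[0], extent[1], 300.0),
            pitch_um=(cfg.step_um, cfg.step_um, 2.0),
            poses=[(-10.0, 100.0), (10.0, 250.0)])
    raise ValueError(f"unknown phantom kind {kind!r}")


def _run_image2d(cfg, out, master, timings):
    phantom = _phantom_for(cfg, master, "rbc")
    grid = cal.make_scan_grid(cfg.fov_diameter_um, cfg.step_um)
    with _stage(timings, "pa_synthesis"):
        frames = simulate_frame(phantom, grid, _focus(cfg), _sensor(cfg),
                                cfg.c_m_per_s, cfg.trace_noise_sd,
                                _stage_seed(master, "trace_noise"))
    with _stage(timings, "image_formation"):
        img = imaging.mip(frames,
                          imaging.FilterSpec(cfg.lowpass_cutoff_mhz))
        img.save_tiff(out / "mip.tif")
        grid.to_csv(out / "scan_grid.csv")
    return [out / "mip.tif", out / "scan_grid.csv"]


def _run_volume3d(cfg, out, master, timings, mode: str = "optical"):
    sensor = _sensor(cfg)
    if mode == "acoustic":
        phantom = _phantom_for(cfg, master, "fibres")
        grid = cal.make_scan_grid(cfg.fov_diameter_um, cfg.step_um)
        with _stage(timings, "pa_synthesis"):
            frames = simulate_frame(phantom, grid, _focus(cfg), sensor,
                                    cfg.c_m_per_s)
        with _stage(timings, "volume"):
            vol = imaging.assemble_volume_acoustic(
                frames, cfg.c_m_per_s,
                imaging.FilterSpec(cfg.lowpass_cutoff_mhz))
    else:
        phantom = _phantom_for(cfg, master, "rbc")
        grid = cal.make_scan_grid(cfg.fov_diameter_um, cfg.step_um,
                                  plane_zs_um=_plane_zs(cfg) or (0.0,))
        images = []
        with _stage(timings, "pa_synthesis"):
            for z in grid.plane_zs_um:
                focus = ExcitationFocus((0, 0), z, cfg.focus_fwhm_um,
                                        cfg.focus_dof_um, cfg.pulse_energy_nj)
                frames = simulate_frame(phantom, grid, focus, sensor,
                                        cfg.c_m_per_s, plane_z_um=z)
                images.append(imaging.mip(
                    frames, imaging.FilterSpec(cfg.lowpass_cutoff_mhz)))
        with _stage(timings, "volume"):
            vol = imaging.assemble_volume_optical(images)
    vol.save_hdf5(out / f"volume_{mode}.h5")
    return [out / f"volume_{mode}.h5"]


def _run_mosaic(cfg, out, master, timings, n_frames: int = 8,
                total_travel_um: float = 30.0):
    extent = (cfg.fov_diameter_um + 20,
              cfg.fov_diameter_um + total_travel_um + 20)
    phantom = make_rbc_phantom(
        18, extent_um=extent, pitch_um=cfg.step_um / 2,
        seed=_stage_seed(master, "phantom"))
    sensor, focus = _sensor(cfg), _focus(cfg)
    shifts = np.linspace(0.0, total_travel_um, n_frames)
    frames = []
    with _stage(timings, "frames"):
        for dx in shifts:
            grid = cal.make_scan_grid(cfg.fov_diameter_um, cfg.step_um,
                                      center_um=(dx - total_travel_um / 2, 0))
            fs = simulate_frame(phantom, grid, focus, sensor, cfg.c_m_per_s)
            frames.append(imaging.mip(
                fs, imaging.FilterSpec(cfg.lowpass_cutoff_mhz)))
    with _stage(timings, "mosaic"):
        cfg_reg = mos.RegistrationConfig(cfg.upsample_factor)
        canvas, traj = mos.run_mosaic(frames, cfg_reg)
        canvas.save_tiff(out / "mosaic.tif")
        _write_metrics_csv(
            [{"frame_index": i, "cum_dy_um": d.dy_um, "cum_dx_um": d.dx_um,
              "confidence": d.confidence} for i, d in enumerate(traj)],
            out / "trajectory.csv")
    return [out / "mosaic.tif", out / "trajectory.csv"]


def _run_metrics(cfg, out, master, timings):
    stack, patterns, rvitms = _characterise_stack(cfg, master, timings)
    rows = _focus_metrics_rows(cfg, stack, patterns, rvitms)
    grid = cal.make_scan_grid(cfg.fov_diameter_um, cfg.step_um)
    timing = cal.acquisition_timing(grid.n_positions, cfg.n_planes,
                                    cfg.dmd_rate_hz)
    for r in rows:
        r.update(n_positions=grid.n_positions, **timing)
    _write_metrics_csv(rows, out / "metrics.csv")
    return [out / "metrics.csv"]
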