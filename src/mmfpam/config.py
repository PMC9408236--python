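"""Run configuration: every tunable of the simulated instrument.

Defaults mirror the hardware configuration the package emulates; entries
marked "artifact default" have no instrument counterpart and are free
choices of the simulator.  Configs round-trip losslessly through
YAML/JSON; unknown keys are rejected with an exhaustive listing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    # fibre / DMD
    n_mirrors: int = 1024            # desk-scale default; instrument: 16384
    fov_diameter_um: float = 100.0   # fibre core / scan FOV diameter
    pixel_pitch_um: float = 1.0      # camera pixel pitch at the output plane
    output_grid: int = 100           # camera grid side (artifact default)
    dmd_rate_hz: float = 22700.0
    on_fraction: float = 0.30        # top-ranked mirror fraction per focus
    # scanning / sectioning
    step_um: float = 1.0             # raster step (0.5 or 1 in practice)
    plane_interval_um: float = 5.0
    n_planes: int = 5
    # acoustics
    c_m_per_s: float = 1485.0
    sensor_center_freq_mhz: float = 8.0
    sensor_bandwidth_mhz: float = 6.5
    sample_rate_mhz: float = 250.0   # artifact default
    lowpass_cutoff_mhz: float = 20.0
    # excitation focus
    focus_fwhm_um: float = 1.2
    focus_dof_um: float = 22.0
    pulse_energy_nj: float = 20.0
    # mosaicing
    upsample_factor: int = 10
    # noise (artifact defaults; the instrument's camera noise is unspecified)
    read_noise_sd: float = 0.0
    shot_scale: float = 0.0
    trace_noise_sd: float = 0.0
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def _field_names() -> set[str]:
    return {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load YAML or JSON; unknown keys rejected, missing keys defaulted."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    unknown = sorted(set(data) - _field_names())
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
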