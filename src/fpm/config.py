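"""Run configuration shared by the CLI and scripted workflows.

Defaults mirror the reference instrument: 50 um channel, R = 0.68
coating, water-like medium (n_m = 1.33), 515-519 nm scan in 35 steps with
a 0.29 nm laser linewidth, 0.868 um/px sampling, 8-bit camera.  A config
is fully serializable to YAML and is snapshotted next to every output so
any run can be reproduced; all randomness flows from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .optics import CavitySpec, LaserLine
from .render import CameraModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # cavity
    channel_height_um: float = 50.0
    reflectivity: float = 0.68
    medium_index: float = 1.33
    coating_band_nm: tuple[float, float] = (515.0, 560.0)
    # illumination
    laser_center_nm: float = 516.0
    laser_fwhm_nm: float = 0.29
    lambda_start_nm: float = 515.0
    lambda_stop_nm: float = 519.0
    n_steps: int = 35
    # scene / camera
    pixel_size_um: float = 0.868
    scene_kind: str = "cell"
    scene_size_px: int = 256
    bit_depth: int = 8
    full_well: float = 20000.0
    read_noise: float = 1.0
    photon_noise: bool = True
    # reproducibility
    seed: int = 0

    def cavity(self) -> CavitySpec:
        if self.reflectivity > 0:
            return CavitySpec(self.channel_height_um, self.reflectivity,
                              self.medium_index, tuple(self.coating_band_nm))
        # R = 0 means "uncoated": represented by a vanishing reflectivity
        return CavitySpec(self.channel_height_um, 1e-12, self.medium_index,
                          tuple(self.coating_band_nm))

    def line(self) -> LaserLine:
        return LaserLine(self.laser_center_nm, self.laser_fwhm_nm,
                         (self.lambda_start_nm, self.lambda_stop_nm), self.n_steps)

    def camera(self) -> CameraModel:
        return CameraModel(self.bit_depth, self.full_well, self.read_noise,
                           self.photon_noise, quantize=True, seed=self.seed)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["coating_band_nm"] = list(d["coating_band_nm"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coating_band_nm" in data:
            data["coating_band_nm"] = tuple(data["coating_band_nm"])
        return cls(**data)
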