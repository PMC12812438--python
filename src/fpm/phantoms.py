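"""Synthetic sample scenes with known ground truth.

A :class:`SampleScene` describes the specimen inside the channel on a pixel
grid: its physical thickness ``PT_s(x, y)`` (um), refractive index
``n_s(x, y)`` and single-pass amplitude attenuation.  The optical thickness
the cavity sees is

    OT(x, y) = n_s * PT_s + n_m * (d - PT_s),

so the sample-induced excess over the fluid-only background is
``dOT = (n_s - n_m) * PT_s``.  Generators cover the reconstruction targets:
silica beads (7.0 um nominal), epithelial-cell-like smooth phase objects,
Poisson bacterial point fields at 1e7-1e8 cells/mL, and sub-resolution
point sources.
"""

from __future__ import annotations

import ast
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile

__all__ = [
    "SampleScene",
    "BacterialFieldTruth",
    "bead_scene",
    "cell_scene",
    "bacteria_scene",
    "point_source_scene",
    "empty_scene",
    "scene_ot_map",
    "scene_delta_ot_map",
    "write_scene",
    "read_scene",
]

DEFAULT_PIXEL_SIZE_UM = 0.868


@dataclass
class SampleScene:
    """Per-pixel specimen maps plus channel/medium context.

    ``ground_truth`` keeps the generating parameters (and, where natural,
    a ground-truth dOT map) for parameter-recovery tests.
    """

    pt_map: np.ndarray          # physical thickness, um
    n_map: np.ndarray           # sample refractive index (n_m where empty)
    atten_map: np.ndarray       # single-pass amplitude attenuation in [0, 1)
    medium_index: float = 1.33
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel_height_um: float = 50.0
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pt_map = np.asarray(self.pt_map, dtype=float)
        self.n_map = np.asarray(self.n_map, dtype=float)
        self.atten_map = np.asarray(self.atten_map, dtype=float)
        if not (self.pt_map.shape == self.n_map.shape == self.atten_map.shape):
            raise ValueError("scene maps must share one shape")
        if np.any(self.pt_map < 0) or np.any(self.pt_map > self.channel_height_um):
            raise ValueError("physical thickness must lie in [0, channel height]")
        if np.any(self.n_map[self.pt_map > 0] < 1):
            raise ValueError("sample refractive index must be >= 1 where present")
        if np.any((self.atten_map < 0) | (self.atten_map >= 1)):
            raise ValueError("attenuation must lie in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pt_map.shape

    @property
    def fov_area_mm2(self) -> float:
        ny, nx = self.shape
        return ny * nx * (self.pixel_size_um * 1e-3) ** 2


@dataclass
class BacterialFieldTruth:
    """Ground truth of a random bacterial field."""

    positions_um: np.ndarray          # (n, 2) as (x, y)
    nominal_concentration_per_ml: float
    fov_area_mm2: float
    channel_height_um: float

    @property
    def count(self) -> int:
        return len(self.positions_um)

    @property
    def expected_count(self) -> float:
        volume_ml = self.fov_area_mm2 * self.channel_height_um * 1e-6  # mm^2 * um -> cm^3
        return self.nominal_concentration_per_ml * volume_ml


def _grids_um(shape: tuple[int, int], pixel_size_um: float):
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size_um
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_um
    return np.meshgrid(x, y)


def empty_scene(
    shape: tuple[int, int] = (64, 64),
    *,
    medium_index: float = 1.33,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel_height_um: float = 50.0,
) -> SampleScene:
    """Fluid-only channel: zero thickness, zero attenuation everywhere."""
    z = np.zeros(shape)
    return SampleScene(z, np.full(shape, medium_index), z.copy(),
                       medium_index, pixel_size_um, channel_height_um,
                       ground_truth={"kind": "empty"})


def bead_scene(
    diameter_um: float = 7.0,
    n_bead: float = 1.45,
    n_medium: float = 1.33,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = (64, 64),
    channel_height_um: float = 50.0,
    attenuation: float = 0.0,
    center_um: tuple[float, float] = (0.0, 0.0),
) -> SampleScene:
    """Spherical bead phantom with chord thickness profile.

    ``PT(r) = 2 sqrt((D/2)^2 - r^2)`` inside the disc of radius D/2 and 0
    outside; the refractive-index map is ``n_bead`` on the disc.  Mirrors
    the 7.0 +- 0.15 um silica reference microspheres.
    """
    if diameter_um > channel_height_um:
        raise ValueError("bead diameter exceeds channel height; bead does not fit")
    xx, yy = _grids_um(shape, pixel_size_um)
    r2 = (xx - center_um[0]) ** 2 + (yy - center_um[1]) ** 2
    rad = diameter_um / 2.0
    inside = r2 < rad**2
    pt = np.where(inside, 2.0 * np.sqrt(np.maximum(rad**2 - r2, 0.0)), 0.0)
    n = np.where(inside, n_bead, n_medium)
    att = np.where(inside, attenuation, 0.0)
    return SampleScene(pt, n, att, n_medium, pixel_size_um, channel_height_um,
                       ground_truth={"kind": "bead", "diameter_um": diameter_um,
                                     "n_bead": n_bead})


def cell_scene(
    body_radius_um: float = 25.0,
    body_delta_ot_nm: float = 100.0,
    organelles: Sequence[tuple[tuple[float, float], float, float]] = (),
    *,
    n_sample: float = 1.38,
    n_medium: float = 1.33,
    attenuation: float = 0.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = (256, 256),
    channel_height_um: float = 50.0,
    center_um: tuple[float, float] = (0.0, 0.0),
    edge_softness: float = 0.25,
) -> SampleScene:
    """Epithelial-cell-like smooth phase object specified by its dOT.

    The cell body is a cosine-tapered disc with peak excess optical
    thickness ``body_delta_ot_nm``; each organelle is a Gaussian bump
    ``((cx, cy), radius_um, extra_delta_ot_nm)`` added on top (overlaps
    superpose).  Amplitudes are in dOT (the observable); with a fixed
    nominal ``n_sample`` the thickness map is derived as
    ``PT = dOT / (n_s - n_m)``.  The ground-truth dOT map (um) is stored.
    """
    xx, yy = _grids_um(shape, pixel_size_um)
    r = np.hypot(xx - center_um[0], yy - center_um[1])
    # raised-cosine taper over the outer `edge_softness` fraction of the radius
    flat_r = body_radius_um * (1.0 - edge_softness)
    taper = np.clip((r - flat_r) / max(body_radius_um - flat_r, 1e-9), 0.0, 1.0)
    body = np.where(r < body_radius_um, 0.5 * (1.0 + np.cos(np.pi * taper)), 0.0)
    dot_nm = body_delta_ot_nm * body
    for (cx, cy), rad, amp in organelles:
        if np.hypot(cx - center_um[0], cy - center_um[1]) > body_radius_um:
            warnings.warn("organelle centre lies outside the cell body", stacklevel=2)
        rr2 = (xx - cx) ** 2 + (yy - cy) ** 2
        dot_nm = dot_nm + amp * np.exp(-0.5 * rr2 / rad**2)
    dot_um = dot_nm * 1e-3
    pt = dot_um / (n_sample - n_medium)
    pt = np.clip(pt, 0.0, channel_height_um)
    n = np.where(pt > 0, n_sample, n_medium)
    att = np.asarray(attenuation * (pt > 0), dtype=float)
    return SampleScene(pt, n, att, n_medium, pixel_size_um, channel_height_um,
                       ground_truth={"kind": "cell", "delta_ot_um": dot_um,
                                     "body_delta_ot_nm": body_delta_ot_nm})


def bacteria_scene(
    concentration_per_ml: float,
    *,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel_height_um: float = 50.0,
    seed: int | None = None,
    cell_delta_ot_nm: float = 120.0,
    cell_attenuation: float = 0.05,
    n_medium: float = 1.33,
    n_sample: float = 1.38,
) -> tuple[SampleScene, BacterialFieldTruth]:
    """Random bacterial point field at a nominal concentration.

    The number of cells is Poisson with mean ``concentration x observable
    volume`` (FOV area x channel height); positions are uniform over the
    field.  Each cell occupies a 2 x 1 px footprint of fixed dOT -- the
    discrete high-contrast spots that are counted, with no rod morphology.
    """
    if concentration_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    fov_area_mm2 = ny * nx * (pixel_size_um * 1e-3) ** 2
    volume_ml = fov_area_mm2 * channel_height_um * 1e-6
    count = int(rng.poisson(concentration_per_ml * volume_ml))
    # uniform positions, kept one pixel off the border for the 2-px footprint
    px = rng.uniform(1, nx - 2, size=count)
    py = rng.uniform(1, ny - 2, size=count)
    dot_um = np.zeros(shape)
    att = np.zeros(shape)
    for x, y in zip(px, py):
        i, j = int(round(y)), int(round(x))
        dot_um[i, j : j + 2] += cell_delta_ot_nm * 1e-3
        att[i, j : j + 2] = np.minimum(att[i, j : j + 2] + cell_attenuation, 0.99)
    pt = np.clip(dot_um / (n_sample - n_medium), 0.0, channel_height_um)
    n = np.where(pt > 0, n_sample, n_medium)
    scene = SampleScene(pt, n, att, n_medium, pixel_size_um, channel_height_um,
                        ground_truth={"kind": "bacteria",
                                      "concentration_per_ml": concentration_per_ml,
                                      "count": count})
    pos_um = np.column_stack([(px - (nx - 1) / 2.0) * pixel_size_um,
                              (py - (ny - 1) / 2.0) * pixel_size_um])
    truth = BacterialFieldTruth(pos_um, concentration_per_ml, fov_area_mm2,
                                channel_height_um)
    return scene, truth


def point_source_scene(
    delta_ot_nm: float = 150.0,
    attenuation: float = 0.3,
    *,
    shape: tuple[int, int] = (65, 65),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel_height_um: float = 50.0,
    n_medium: float = 1.33,
    n_sample: float = 1.45,
) -> SampleScene:
    """Sub-resolution point source: a single-pixel delta at the centre.

    Used for through-focus / PSF characterization; the physical 50 nm
    particle size enters only through being below the diffraction limit.
    """
    pt = np.zeros(shape)
    att = np.zeros(shape)
    i, j = shape[0] // 2, shape[1] // 2
    pt[i, j] = delta_ot_nm * 1e-3 / (n_sample - n_medium)
    att[i, j] = attenuation
    n = np.where(pt > 0, n_sample, n_medium)
    return SampleScene(pt, n, att, n_medium, pixel_size_um, channel_height_um,
                       ground_truth={"kind": "point", "position_px": (i, j)})


def scene_ot_map(scene: SampleScene) -> np.ndarray:
    """Per-pixel optical thickness ``n_s PT + n_m (d - PT)`` in um."""
    return (scene.n_map * scene.pt_map
            + scene.medium_index * (scene.channel_height_um - scene.pt_map))


def scene_delta_ot_map(scene: SampleScene) -> np.ndarray:
    """Per-pixel excess optical thickness ``(n_s - n_m) PT`` in um."""
    return (scene.n_map - scene.medium_index) * scene.pt_map


# ---------------------------------------------------------------------------
# Scene serialization: float TIFF per map + key=value sidecar
# ---------------------------------------------------------------------------

_SIDE = "scene.txt"
_MAPS = {"pt": "pt_um.tif", "n": "n_index.tif", "atten": "attenuation.tif"}


def write_scene(scene: SampleScene, directory: str | Path, overwrite: bool = False) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not overwrite and any(directory.iterdir()):
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    tifffile.imwrite(directory / _MAPS["pt"], scene.pt_map.astype(np.float64))
    tifffile.imwrite(directory / _MAPS["n"], scene.n_map.astype(np.float64))
    tifffile.imwrite(directory / _MAPS["atten"], scene.atten_map.astype(np.float64))
    gt = {k: v for k, v in scene.ground_truth.items() if np.ndim(v) == 0}
    lines = ["# fpm-scene v1",
             f"medium_index={scene.medium_index!r}",
             f"pixel_size_um={scene.pixel_size_um!r}",
             f"channel_height_um={scene.channel_height_um!r}"]
    lines += [f"gt_{k}={v!r}" for k, v in gt.items()]
    (directory / _SIDE).write_text("\n".join(lines) + "\n")
    return directory


def _parse_value(text: str) -> Any:
    try:
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def read_scene(directory: str | Path) -> SampleScene:
    directory = Path(directory)
    meta: dict[str, Any] = {}
    gt: dict[str, Any] = {}
    for line in (directory / _SIDE).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        parsed = _parse_value(val)
        if key.startswith("gt_"):
            gt[key[3:]] = parsed
        else:
            meta[key] = parsed
    return SampleScene(
        tifffile.imread(directory / _MAPS["pt"]),
        tifffile.imread(directory / _MAPS["n"]),
        tifffile.imread(directory / _MAPS["atten"]),
        medium_index=float(meta["medium_index"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_height_um=float(meta["channel_height_um"]),
        ground_truth=gt,
    )
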