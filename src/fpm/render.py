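"""Forward imaging of sample scenes through the cavity.

Renders wavelength stacks (the FPM scan), 740-nm dye-absorption frames
(the Beer-Lambert physical-thickness channel) and through-focus stacks of
point sources (PSF / ghost-focus characterization), with an optional
camera noise model (Poisson shot noise, Gaussian read noise, bit-depth
quantization).

Intensity model for the scan: per pixel and per illumination wavelength

    I = I0 * (1 - atten)^2 * T_eff(OT(x, y); lambda_c, dlambda, R),

i.e. a double-pass single-pass-amplitude attenuation times the effective
(finite-linewidth) cavity transmission.  Absorption inside the resonator
modifying the finesse is deliberately not modelled.  The 740-nm dye frame
is pure Beer-Lambert with no etalon term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import CavitySpec, LaserLine, effective_transmission, ghost_foci
from .phantoms import SampleScene, scene_delta_ot_map, scene_ot_map
from .recon import beer_lambert_mu
from .stack_io import AcquisitionMetadata, WavelengthStack

__all__ = [
    "CameraModel",
    "DyeSpec",
    "DefocusPSF",
    "render_stack",
    "render_dye_image",
    "render_through_focus",
    "add_noise",
]


@dataclass
class CameraModel:
    """Camera noise/quantization model.

    ``full_well`` is the photon count mapped to unit intensity for shot
    noise; ``read_noise`` is the Gaussian read noise in digital counts at
    the configured bit depth.  With ``photon_noise=False``, zero read
    noise and ``quantize=False`` the camera is an exact identity.
    """

    bit_depth: int = 8
    full_well: float = 20000.0
    read_noise: float = 1.0
    photon_noise: bool = True
    quantize: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @classmethod
    def noiseless(cls) -> "CameraModel":
        return cls(photon_noise=False, read_noise=0.0, quantize=False)

    @property
    def levels(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class DyeSpec:
    """Infrared-absorbing dye used for the physical-thickness channel.

    The absorbance ``A`` of the dyed medium over a reference thickness
    ``d_r`` fixes the attenuation coefficient ``mu = A/d_r`` (natural-log
    convention; ``A ln 10 / d_r`` decadic).  The dye absorbs strongly at
    the 740-nm imaging wavelength and is transparent in the 515-519 nm
    scan window.
    """

    absorbance: float = 5.0
    reference_thickness_um: float = 50.0
    convention: str = "natural"
    imaging_wavelength_nm: float = 740.0

    @property
    def mu_per_um(self) -> float:
        return beer_lambert_mu(self.absorbance, self.reference_thickness_um,
                               self.convention)


@dataclass
class DefocusPSF:
    """Linear-growth defocus blur calibrated to the in-focus lateral FWHM.

    ``sigma(z) = sigma0 + defocus_rate * |z - z_focus|`` with
    ``sigma0 = fwhm / (2 sqrt(2 ln 2))``; the on-axis intensity of a point
    image falls as ``(sigma0 / sigma(z))^2`` (energy conservation).
    """

    in_focus_fwhm_um: float = 1.2
    defocus_rate: float = 0.05      # um of sigma per um of defocus

    @property
    def sigma0_um(self) -> float:
        return self.in_focus_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def sigma_at(self, defocus_um: float | np.ndarray) -> float | np.ndarray:
        return self.sigma0_um + self.defocus_rate * np.abs(defocus_um)


def add_noise(frame: np.ndarray, camera: CameraModel,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply shot noise, read noise and quantization to one frame.

    Deterministic: the same camera seed always produces bit-identical
    output (pass ``rng`` to draw from an external stream instead).
    """
    out = np.asarray(frame, dtype=float)
    if camera.photon_noise or camera.read_noise > 0:
        if rng is None:
            rng = np.random.default_rng(camera.seed)
        if camera.photon_noise:
            out = rng.poisson(np.maximum(out, 0.0) * camera.full_well) / camera.full_well
        if camera.read_noise > 0:
            out = out + rng.normal(0.0, camera.read_noise / camera.levels, out.shape)
    if camera.quantize:
        out = np.round(np.clip(out, 0.0, 1.0) * camera.levels) / camera.levels
    return out


def render_stack(
    scene: SampleScene,
    cavity: CavitySpec,
    line: LaserLine,
    wavelengths_nm: Sequence[float] | None = None,
    camera: CameraModel | None = None,
    *,
    intensity: float = 1.0,
    psf_sigma_px: float | None = None,
) -> WavelengthStack:
    """Render a scene into a wavelength-scanned stack.

    One frame per wavelength (default: the line's 35-step tuning scan);
    each frame is the attenuated effective cavity transmission of the
    scene's optical-thickness map, optionally blurred by a lateral
    Gaussian PSF, then passed through the camera model.  The ground-truth
    OT and dOT maps ride along for recovery tests.
    """
    if wavelengths_nm is None:
        wavelengths_nm = line.scan_wavelengths()
    lam = np.asarray(wavelengths_nm, dtype=float)
    band = cavity.coating_band_nm
    if np.any((lam < band[0]) | (lam > band[1])):
        raise ValueError(f"scan wavelengths outside the coating band {band}")
    if not np.isclose(scene.channel_height_um, cavity.channel_height_um):
        raise ValueError("scene and cavity disagree on channel height")
    if not np.isclose(scene.medium_index, cavity.medium_index):
        raise ValueError("scene and cavity disagree on medium index")
    ot = scene_ot_map(scene)
    base = intensity * (1.0 - scene.atten_map) ** 2
    camera = camera or CameraModel.noiseless()
    streams = np.random.SeedSequence(camera.seed).spawn(len(lam))
    frames = np.empty((len(lam),) + scene.shape)
    for i, lc in enumerate(lam):
        t = effective_transmission(ot, line.at(float(lc)),
                                   float(cavity.reflectivity_at(float(lc))))
        frame = base * t
        if psf_sigma_px:
            frame = gaussian_filter(frame, psf_sigma_px)
        frames[i] = add_noise(frame, camera, np.random.default_rng(streams[i]))
    meta = AcquisitionMetadata(sample_info=str(scene.ground_truth.get("kind", "scene")),
                               central_wavelengths_nm=list(lam))
    return WavelengthStack(frames, lam, meta, scene.pixel_size_um,
                           ground_truth={"ot_map_um": ot,
                                         "delta_ot_map_um": scene_delta_ot_map(scene),
                                         "scene": scene, "intensity": intensity})


def render_dye_image(
    scene: SampleScene,
    dye: DyeSpec,
    camera: CameraModel | None = None,
    *,
    intensity: float = 1.0,
) -> np.ndarray:
    """Render the 740-nm dye-absorption frame.

    The dye-filled background transmits ``I_b = I0 exp(-mu d)``; where the
    sample displaces dye over its physical thickness the path through the
    absorber shortens, so ``I = I_b exp(mu PT)`` -- samples appear bright
    on a dark background.  No etalon term is applied at 740 nm.
    """
    mu = dye.mu_per_um
    i_b = intensity * np.exp(-mu * scene.channel_height_um)
    frame = i_b * np.exp(mu * scene.pt_map)
    camera = camera or CameraModel.noiseless()
    return add_noise(frame, camera)


def render_through_focus(
    scene: SampleScene,
    cavity: CavitySpec | None,
    z_grid_um: Sequence[float],
    psf: DefocusPSF | None = None,
    *,
    k_max: int = 2,
) -> np.ndarray:
    """Through-focus stack of the scene's point sources.

    Returns a background-subtracted signal stack ``(nz, ny, nx)``: each
    point source produces a defocus-blurred image at the primary plane
    plus, when a coated cavity is supplied, ghost images displaced by
    ``2dk/n_m`` with relative intensities ``R^(2k)``.  Pass
    ``cavity=None`` (or k_max=0) for the uncoated single-focus reference.
    """
    psf = psf or DefocusPSF()
    z = np.asarray(z_grid_um, dtype=float)
    if cavity is None:
        offsets = np.array([0.0])
        weights = np.array([1.0])
    else:
        series = ghost_foci(cavity, k_max)
        offsets = series.offsets_um
        weights = series.relative_intensities
    ny, nx = scene.shape
    px = scene.pixel_size_um
    yy, xx = np.mgrid[0:ny, 0:nx]
    sources = np.argwhere(scene.pt_map > 0)
    amplitudes = scene.atten_map[scene.pt_map > 0]
    amplitudes = np.where(amplitudes > 0, amplitudes, 1.0)
    out = np.zeros((len(z), ny, nx))
    for iz, zval in enumerate(z):
        for (si, sj), amp in zip(sources, amplitudes):
            r2 = ((yy - si) ** 2 + (xx - sj) ** 2) * px**2
            for off, w in zip(offsets, weights):
                sig = psf.sigma_at(zval - off)
                out[iz] += amp * w * (psf.sigma0_um / sig) ** 2 * np.exp(-0.5 * r2 / sig**2)
    return out
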