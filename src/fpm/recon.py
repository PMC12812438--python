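"""Reconstruction of contrast, optical thickness, physical thickness and
refractive index from wavelength-scanned stacks.

Pipeline (per stack): estimate the local background, form absolute Weber
contrast maps ``C = |I - I_b| / I_b`` per wavelength and their
max-over-wavelength projection, average over one free spectral range for
the wide-field (WFM) baseline, locate the per-pixel resonance wavelength
``lambda_max``, convert to optical thickness ``OT = N lambda_max / 2``
with the interference order ``N`` calibrated on background regions,
subtract the background reference for ``dOT``, and -- when a dye frame is
available -- invert Beer-Lambert for physical thickness and combine
``n_s = n_m + dOT / PT``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import zoom as _ndzoom
from skimage.restoration import unwrap_phase

from .stack_io import WavelengthStack

__all__ = [
    "ContrastMap",
    "ResonanceMap",
    "OTMap",
    "RIMap",
    "estimate_background",
    "weber_contrast",
    "weber_contrast_stack",
    "max_contrast_map",
    "wfm_baseline",
    "resonance_map",
    "ot_map",
    "delta_ot_map",
    "wrap_delta_ot",
    "unwrap_delta_ot",
    "beer_lambert_mu",
    "physical_thickness_map",
    "refractive_index_map",
]

Roi = tuple[int, int, int, int]  # (y0, y1, x0, x1)


@dataclass
class ContrastMap:
    values: np.ndarray                       # absolute Weber contrast, >= 0
    argmax_wavelength_nm: np.ndarray | None = None
    background: np.ndarray | float = 0.0


@dataclass
class ResonanceMap:
    """Per-pixel resonance wavelength of the scan."""

    lambda_max_nm: np.ndarray
    peak_quality: np.ndarray                 # (I_peak - I_min) / I_peak
    unrefined: np.ndarray                    # peak at scan edge or degenerate
    flat: np.ndarray                         # all-equal intensity trace


@dataclass
class OTMap:
    ot_um: np.ndarray
    order: int
    delta_ot_um: np.ndarray | None = None
    background_ot_um: float | None = None
    wrapped: np.ndarray | None = None        # |dOT| beyond the lambda/4 window


@dataclass
class RIMap:
    n_map: np.ndarray                        # NaN where undefined
    defined: np.ndarray
    min_pt_um: float


# ---------------------------------------------------------------------------
# Background and contrast
# ---------------------------------------------------------------------------

def estimate_background(
    frame: np.ndarray,
    roi: Roi | None = None,
    mode: str = "global",
    tile: int = 32,
    outlier_warn_fraction: float = 0.2,
) -> float | np.ndarray:
    """Local background intensity ``I_b`` of one frame.

    ``global`` mode returns the median over the ROI (whole frame when no
    ROI is given) -- robust to a sparse sample.  ``local`` mode computes
    per-tile medians and interpolates them back to a smooth background
    field.  A warning is raised when the ROI looks contaminated by sample
    pixels (large fraction of >5 MAD outliers).
    """
    frame = np.asarray(frame, dtype=float)
    region = frame if roi is None else frame[roi[0]:roi[1], roi[2]:roi[3]]
    if region.size == 0:
        raise ValueError("background region is empty")
    if mode == "global":
        med = float(np.median(region))
        mad = float(np.median(np.abs(region - med)))
        if mad > 0:
            frac = np.mean(np.abs(region - med) > 5 * mad)
            if frac > outlier_warn_fraction:
                warnings.warn(
                    f"background ROI looks contaminated ({frac:.0%} outliers)",
                    stacklevel=2,
                )
        return med
    if mode == "local":
        ny, nx = frame.shape
        ty, tx = max(ny // tile, 1), max(nx // tile, 1)
        coarse = np.empty((ty, tx))
        for i in range(ty):
            for j in range(tx):
                coarse[i, j] = np.median(
                    frame[i * tile:(i + 1) * tile if i < ty - 1 else ny,
                          j * tile:(j + 1) * tile if j < tx - 1 else nx])
        return _ndzoom(coarse, (ny / ty, nx / tx), order=1, mode="nearest")
    raise ValueError(f"unknown background mode {mode!r}")


def weber_contrast(frame: np.ndarray, background: float | np.ndarray) -> np.ndarray:
    """Absolute Weber contrast ``|I - I_b| / I_b``."""
    ib = np.asarray(background, dtype=float)
    if np.any(ib <= 0):
        raise ValueError("degenerate background (I_b <= 0)")
    return np.abs(np.asarray(frame, dtype=float) - ib) / ib


def weber_contrast_stack(
    stack: WavelengthStack,
    backgrounds: Sequence[float] | np.ndarray | None = None,
    roi: Roi | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength contrast maps; returns ``(contrast, backgrounds)``.

    When ``backgrounds`` is omitted each frame's ``I_b`` is estimated from
    the ROI (median).
    """
    if backgrounds is None:
        backgrounds = np.array([estimate_background(f, roi) for f in stack.frames])
    else:
        backgrounds = np.asarray(backgrounds, dtype=float)
    contrast = np.stack([weber_contrast(f, b) for f, b in zip(stack.frames, backgrounds)])
    return contrast, backgrounds


def max_contrast_map(
    contrast_stack: np.ndarray,
    wavelengths_nm: Sequence[float],
) -> ContrastMap:
    """Per-pixel maximum contrast over the scan and the wavelength
    attaining it (ties resolve to the lowest wavelength)."""
    c = np.asarray(contrast_stack, dtype=float)
    lam = np.asarray(wavelengths_nm, dtype=float)
    order = np.argsort(lam, kind="stable")
    c, lam = c[order], lam[order]
    idx = np.argmax(c, axis=0)   # first occurrence = lowest wavelength
    return ContrastMap(np.max(c, axis=0), lam[idx])


def wfm_baseline(
    stack: WavelengthStack,
    fsr_nm: float,
) -> np.ndarray:
    """Wide-field-equivalent image: unweighted mean of the frames whose
    wavelengths lie within one free spectral range of the scan start.

    Averaging over a full FSR washes out the resonance term (the Airy
    mean is independent of optical thickness), leaving the plain
    absorption image a conventional microscope would record.
    """
    lam = stack.wavelengths_nm
    span = lam[-1] - lam[0]
    if span < fsr_nm:
        warnings.warn(
            f"scan span {span:.3f} nm is below one FSR ({fsr_nm:.3f} nm); "
            "baseline will retain resonance contrast", stacklevel=2)
    sel = lam <= lam[0] + fsr_nm
    return stack.frames[sel].mean(axis=0)


# ---------------------------------------------------------------------------
# Resonance mapping and optical thickness
# ---------------------------------------------------------------------------

def _parabolic_vertex(x1, x2, x3, y1, y2, y3):
    # vertex of the parabola through three (possibly unevenly spaced) points
    a = (x2 - x1) * (y2 - y3)
    b = (x2 - x3) * (y2 - y1)
    denom = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = x2 - 0.5 * ((x2 - x1) * a - (x2 - x3) * b) / denom
    return vx, denom


def resonance_map(stack: WavelengthStack) -> ResonanceMap:
    """Per-pixel wavelength of maximal transmission, sub-step refined.

    The raw per-pixel argmax over the sorted scan is refined by the vertex
    of a parabola through the peak sample and its two neighbours.  Peaks
    at the scan edges (no neighbour on one side) and degenerate fits are
    left at the sampled wavelength and flagged ``unrefined``; all-equal
    traces are additionally flagged ``flat``.
    """
    if len(stack) < 3:
        raise ValueError("resonance mapping needs at least 3 frames")
    stack = stack.sorted_by_wavelength()
    frames, lam = stack.frames, stack.wavelengths_nm
    n = len(lam)
    idx = np.argmax(frames, axis=0)
    flat = np.ptp(frames, axis=0) <= 0
    edge = (idx == 0) | (idx == n - 1)
    inner = np.clip(idx, 1, n - 2)
    ii, jj = np.indices(idx.shape)
    y1 = frames[inner - 1, ii, jj]
    y2 = frames[inner, ii, jj]
    y3 = frames[inner + 1, ii, jj]
    vx, denom = _parabolic_vertex(lam[inner - 1], lam[inner], lam[inner + 1], y1, y2, y3)
    degenerate = ~np.isfinite(vx) | (denom == 0)
    lam_max = lam[idx].astype(float)
    ok = ~(edge | degenerate | flat)
    lam_max[ok] = vx[ok]
    # refinement never moves the peak outside the bracketing samples
    lam_max = np.clip(lam_max, lam[0], lam[-1])
    peak = frames[idx, ii, jj]
    with np.errstate(divide="ignore", invalid="ignore"):
        quality = np.where(peak > 0, (peak - frames.min(axis=0)) / peak, 0.0)
    return ResonanceMap(lam_max, quality, unrefined=edge | degenerate | flat, flat=flat)


def ot_map(resonance: ResonanceMap, order: int) -> OTMap:
    """Optical thickness ``OT = N lambda_max / 2`` (um) from the resonance
    condition ``2 OT = N lambda``; ``N`` comes from background calibration
    (``optics.interference_order``), shared by all pixels."""
    if order < 1:
        raise ValueError("interference order must be >= 1")
    return OTMap(order * resonance.lambda_max_nm * 1e-3 / 2.0, order)


def delta_ot_map(
    otm: OTMap,
    background_roi: Roi | None = None,
    wavelength_nm: float = 516.0,
) -> OTMap:
    """Background-subtracted relative optical thickness.

    ``dOT = OT - median(OT over the background ROI)``; pixels with
    ``|dOT| > lambda/4`` are flagged wrapped -- with a single shared
    interference order the reconstruction is only unambiguous within
    +-lambda/4 (order-jump ambiguity of lambda/2).
    """
    ot = otm.ot_um
    region = ot if background_roi is None else ot[background_roi[0]:background_roi[1],
                                                  background_roi[2]:background_roi[3]]
    ref = float(np.median(region))
    dot = ot - ref
    lam_um = wavelength_nm * 1e-3
    return OTMap(ot, otm.order, delta_ot_um=dot, background_ot_um=ref,
                 wrapped=np.abs(dot) > lam_um / 4.0)


def wrap_delta_ot(delta_ot_um: np.ndarray, wavelength_nm: float = 516.0) -> np.ndarray:
    """Map dOT into the principal interval [-lambda/4, lambda/4)."""
    half = wavelength_nm * 1e-3 / 2.0
    return (np.asarray(delta_ot_um) + half / 2.0) % half - half / 2.0


def unwrap_delta_ot(
    delta_ot_um: np.ndarray,
    wavelength_nm: float = 516.0,
    background_roi: Roi | None = None,
) -> np.ndarray:
    """Spatially unwrap a wrapped dOT field across order jumps.

    The wrapped dOT (period lambda/2) is mapped to a phase of period 2 pi,
    unwrapped with a quality-guided 2-D algorithm, mapped back, and
    re-anchored so the background median is zero.  Requires the true dOT
    increment between neighbouring pixels to stay below lambda/4 (i.e.
    adequately fine pixel sampling of steep samples).
    """
    half = wavelength_nm * 1e-3 / 2.0
    phase = np.asarray(delta_ot_um, dtype=float) * (2.0 * np.pi / half)
    out = unwrap_phase(phase) * (half / (2.0 * np.pi))
    region = out if background_roi is None else out[background_roi[0]:background_roi[1],
                                                    background_roi[2]:background_roi[3]]
    shift = np.round(np.median(region) / half) * half
    return out - shift


# ---------------------------------------------------------------------------
# Beer-Lambert physical thickness and refractive index
# ---------------------------------------------------------------------------

def beer_lambert_mu(absorbance: float, reference_thickness_um: float,
                    convention: str = "natural") -> float:
    """Attenuation coefficient ``mu = A / d_r`` (1/um).

    ``natural`` treats the absorbance as a natural-log optical depth (the
    convention matching ``PT = ln(I_s/I_b)/mu``); ``decadic`` converts a
    log10 instrument absorbance via ``mu = A ln(10) / d_r``.
    """
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    if reference_thickness_um <= 0:
        raise ValueError("reference thickness must be positive")
    if convention == "natural":
        return absorbance / reference_thickness_um
    if convention == "decadic":
        return absorbance * np.log(10.0) / reference_thickness_um
    raise ValueError(f"unknown convention {convention!r}")


def physical_thickness_map(
    sample_frame: np.ndarray,
    background: float | np.ndarray,
    mu_per_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Physical thickness ``PT = ln(I_s/I_b) / mu`` from the dye frame.

    Where the sample displaces the absorbing dye the transmitted intensity
    rises above the background, so ``ln(I_s/I_b) >= 0``.  Negative values
    (sample darker than background, violating the displacement model) are
    clipped to zero and flagged; returns ``(pt_map, clipped_mask)``.
    """
    if mu_per_um <= 0:
        raise ValueError("mu must be positive")
    ib = np.asarray(background, dtype=float)
    if np.any(ib <= 0):
        raise ValueError("background intensity must be positive")
    i_s = np.asarray(sample_frame, dtype=float)
    if np.any(i_s <= 0):
        i_s = np.maximum(i_s, np.finfo(float).tiny)
    pt = np.log(i_s / ib) / mu_per_um
    clipped = pt < 0
    return np.where(clipped, 0.0, pt), clipped


def refractive_index_map(
    delta_ot_um: np.ndarray,
    pt_um: np.ndarray,
    medium_index: float = 1.33,
    min_pt_um: float = 0.5,
) -> RIMap:
    """Refractive index ``n_s = n_m + dOT / PT`` where the thickness is
    trustworthy (``PT >= min_pt``); NaN (masked) elsewhere."""
    pt = np.asarray(pt_um, dtype=float)
    dot = np.asarray(delta_ot_um, dtype=float)
    defined = pt >= min_pt_um
    n = np.full(pt.shape, np.nan)
    n[defined] = medium_index + dot[defined] / pt[defined]
    return RIMap(n, defined, min_pt_um)
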