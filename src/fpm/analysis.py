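"""Particle counting with uncertainty, and through-focus characterization.

Discrete high-contrast spots (bacteria, nanoparticles) are detected on a
contrast map by thresholding and 8-connected component labelling, counted,
and converted to a concentration via the observable sample volume (channel
height x imaged area).  Through-focus stacks are characterized by radial
intensity profiles, FWHM estimation and axial peak (ghost-focus) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "ParticleSet",
    "ConcentrationEstimate",
    "detect_particles",
    "count_concentration",
    "default_threshold",
    "radial_profile",
    "fwhm",
    "axial_peaks",
]


@dataclass
class ParticleSet:
    centroids_px: np.ndarray        # (n, 2) as (y, x), sub-pixel
    areas_px: np.ndarray
    peak_contrast: np.ndarray

    @property
    def count(self) -> int:
        return len(self.centroids_px)


@dataclass
class ConcentrationEstimate:
    """Concentration with Poisson counting and FOV-geometry uncertainty."""

    value_per_ml: float
    poisson_se_per_ml: float
    fov_se_per_ml: float

    @property
    def total_se_per_ml(self) -> float:
        return float(np.hypot(self.poisson_se_per_ml, self.fov_se_per_ml))


def default_threshold(contrast_map: np.ndarray, k: float = 5.0) -> float:
    """Detection threshold ``k`` x the background contrast MAD above the median."""
    c = np.asarray(contrast_map, dtype=float)
    med = np.median(c)
    mad = np.median(np.abs(c - med))
    return float(med + k * max(mad, 1e-12))


def detect_particles(
    contrast_map: np.ndarray,
    threshold: float,
    min_area_px: int = 1,
) -> ParticleSet:
    """Threshold -> 8-connected components -> area filter -> centroids.

    Spots merged below the resolution of the map are counted once (a
    documented limitation of connectivity-based counting).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    c = np.asarray(contrast_map, dtype=float)
    mask = c > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return ParticleSet(np.empty((0, 2)), np.empty(0, dtype=int), np.empty(0))
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask, labels, ids).astype(int)
    keep = areas >= min_area_px
    ids, areas = ids[keep], areas[keep]
    if len(ids) == 0:
        return ParticleSet(np.empty((0, 2)), np.empty(0, dtype=int), np.empty(0))
    centroids = np.array(ndimage.center_of_mass(c, labels, ids))
    peaks = np.array(ndimage.maximum(c, labels, ids))
    return ParticleSet(centroids, areas, peaks)


def count_concentration(
    count: int,
    channel_height_um: float,
    fov_area_mm2: float,
    fov_relative_uncertainty: float = 0.0,
) -> ConcentrationEstimate:
    """Convert a particle count to a concentration in cells/mL.

    ``c = count / (d x A)`` with the observable volume ``d x A`` in mL
    (mm^2 x um x 1e-6).  Poisson SE is ``sqrt(count)/V`` (``sqrt(count+1)``
    at zero count so the uncertainty never degenerates); the FOV term is
    propagated linearly from the relative area uncertainty.
    """
    if channel_height_um <= 0 or fov_area_mm2 <= 0:
        raise ValueError("volume dimensions must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    volume_ml = fov_area_mm2 * channel_height_um * 1e-6
    value = count / volume_ml
    poisson = np.sqrt(count if count > 0 else count + 1) / volume_ml
    fov = value * fov_relative_uncertainty
    return ConcentrationEstimate(value, float(poisson), float(fov))


# ---------------------------------------------------------------------------
# Through-focus characterization
# ---------------------------------------------------------------------------

def radial_profile(
    frame: np.ndarray,
    center: tuple[float, float],
    bin_width_px: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal mean in annular bins around ``center`` (y, x).

    Returns ``(radii_px, mean_intensity)`` with radii at bin centres.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    cy, cx = center
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("center lies outside the frame")
    yy, xx = np.indices(frame.shape)
    r = np.hypot(yy - cy, xx - cx)
    nbins = int(np.ceil(r.max() / bin_width_px))
    which = np.minimum((r / bin_width_px).astype(int), nbins - 1)
    sums = np.bincount(which.ravel(), weights=frame.ravel(), minlength=nbins)
    counts = np.bincount(which.ravel(), minlength=nbins)
    radii = (np.arange(nbins) + 0.5) * bin_width_px
    return radii, sums / np.maximum(counts, 1)


def fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a single-peaked sampled curve.

    The two half-maximum crossings bracketing the global peak are located
    by linear interpolation; raises if the peak is truncated (no crossing
    on one side).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0
    left = None
    for i in range(ipk, 0, -1):
        if y[i - 1] <= half <= y[i]:
            left = np.interp(half, [y[i - 1], y[i]], [x[i - 1], x[i]])
            break
    right = None
    for i in range(ipk, len(y) - 1):
        if y[i + 1] <= half <= y[i]:
            right = np.interp(half, [y[i + 1], y[i]], [x[i + 1], x[i]])
            break
    if left is None or right is None:
        raise ValueError("truncated peak: no half-maximum crossing on one side")
    return float(right - left)


def axial_peaks(
    intensity: np.ndarray,
    z_grid_um: np.ndarray,
    prominence: float = 0.02,
) -> dict:
    """Axial peak analysis of a through-focus intensity curve.

    Finds local maxima above a prominence threshold (relative to the
    strongest peak), normalizes intensities to the primary, and reports
    the successive relative drops ``drop_k = 1 - I_k / I_{k-1}``.
    """
    y = np.asarray(intensity, dtype=float)
    z = np.asarray(z_grid_um, dtype=float)
    idx, _ = find_peaks(y, prominence=prominence * y.max())
    if len(idx) == 0:  # monotone or single-sample peak: fall back to argmax
        idx = np.array([int(np.argmax(y))])
    order = np.argsort(z[idx])
    idx = idx[order]
    rel = y[idx] / y[idx].max()
    drops = 1.0 - y[idx][1:] / y[idx][:-1]
    return {"positions_um": z[idx], "relative_intensities": rel,
            "successive_drops": drops}
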