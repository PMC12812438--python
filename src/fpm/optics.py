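"""Closed-form physics of the microfluidic Fabry-Perot cavity.

The imaging channel is a fluid-filled gap of height ``d`` (default 50 um)
between two partially reflective dielectric coatings (reflectivity ``R``,
nominally 0.68 in the 515-560 nm band).  Collimated narrowband light at
normal incidence is transmitted according to the Airy function

    T(OT, lambda) = 1 / (1 + F * sin^2(2*pi*OT/lambda)),

where ``OT`` is the one-way optical thickness of the cavity and
``F = 4R/(1-R)^2`` is the coefficient of finesse.  All lengths are in
micrometres except wavelengths, which are in nanometres throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CavitySpec",
    "LaserLine",
    "GhostSeries",
    "coefficient_of_finesse",
    "classical_finesse",
    "airy_transmission",
    "airy_mean_transmission",
    "free_spectral_range",
    "interference_order",
    "ot_resolution_limit",
    "effective_transmission",
    "transmission_spectrum",
    "ghost_foci",
    "FWHM_TO_SIGMA",
]

#: Conversion between the FWHM and sigma of a Gaussian line, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class CavitySpec:
    """Geometry and mirror reflectivity of the Fabry-Perot flow channel.

    Parameters
    ----------
    channel_height_um
        Etched channel height ``d`` in micrometres.
    reflectivity
        Mirror (coating) reflectivity, either a scalar fraction in (0, 1)
        or a 2-column table ``(wavelength_nm, R)`` with a strictly
        increasing wavelength grid; treated as wavelength-flat when scalar.
    medium_index
        Refractive index ``n_m`` of the fluid filling the channel.
    coating_band_nm
        Wavelength interval over which the coating is specified.
    """

    channel_height_um: float = 50.0
    reflectivity: float | np.ndarray = 0.68
    medium_index: float = 1.33
    coating_band_nm: tuple[float, float] = (515.0, 560.0)

    def __post_init__(self) -> None:
        if self.channel_height_um <= 0:
            raise ValueError("channel_height_um must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if np.ndim(self.reflectivity) == 0:
            r = float(self.reflectivity)
            if not 0.0 < r < 1.0:
                raise ValueError("reflectivity must lie in (0, 1)")
        else:
            tab = np.asarray(self.reflectivity, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2:
                raise ValueError("tabulated reflectivity must be (n, 2)")
            if np.any(np.diff(tab[:, 0]) <= 0):
                raise ValueError("reflectivity wavelength grid must be increasing")
            if np.any((tab[:, 1] <= 0) | (tab[:, 1] >= 1)):
                raise ValueError("tabulated reflectivity values must lie in (0, 1)")
            self.reflectivity = tab

    def reflectivity_at(self, wavelength_nm: float | np.ndarray) -> float | np.ndarray:
        """Reflectivity at the given wavelength (interpolated when tabulated)."""
        if np.ndim(self.reflectivity) == 0:
            return float(self.reflectivity) if np.ndim(wavelength_nm) == 0 else np.full(
                np.shape(wavelength_nm), float(self.reflectivity)
            )
        tab = self.reflectivity
        lam = np.asarray(wavelength_nm, dtype=float)
        if np.any(lam < tab[0, 0]) or np.any(lam > tab[-1, 0]):
            raise ValueError("wavelength outside tabulated reflectivity grid")
        out = np.interp(lam, tab[:, 0], tab[:, 1])
        return float(out) if np.ndim(wavelength_nm) == 0 else out

    @property
    def background_ot_um(self) -> float:
        """Optical thickness ``n_m * d`` of the empty (fluid-only) channel."""
        return self.medium_index * self.channel_height_um


@dataclass
class LaserLine:
    """Tunable narrowband illumination line (Gaussian spectral shape)."""

    center_nm: float = 516.0
    fwhm_nm: float = 0.29
    tuning_range_nm: tuple[float, float] = (515.0, 519.0)
    n_steps: int = 35

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / FWHM_TO_SIGMA

    def scan_wavelengths(self) -> np.ndarray:
        """The discrete wavelengths of a full tuning scan (ascending)."""
        lo, hi = self.tuning_range_nm
        return np.linspace(lo, hi, self.n_steps)

    def at(self, center_nm: float) -> "LaserLine":
        """The same line retuned to a new central wavelength."""
        return LaserLine(center_nm, self.fwhm_nm, self.tuning_range_nm, self.n_steps)


@dataclass
class GhostSeries:
    """Axial ghost-focus series from extra cavity round trips.

    ``offsets_um[k]`` is the apparent axial displacement of the k-th image
    (k = 0 is the primary focus at 0) and ``relative_intensities[k]`` its
    intensity relative to the primary.
    """

    offsets_um: np.ndarray
    relative_intensities: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_um = np.asarray(self.offsets_um, dtype=float)
        self.relative_intensities = np.asarray(self.relative_intensities, dtype=float)
        if np.any(np.diff(self.offsets_um) <= 0):
            raise ValueError("ghost offsets must be strictly increasing")
        if np.any(np.diff(self.relative_intensities) >= 0):
            raise ValueError("ghost intensities must be strictly decreasing")
        if np.any(self.relative_intensities > 1):
            raise ValueError("relative intensities cannot exceed the primary")


# ---------------------------------------------------------------------------
# Finesse and the Airy transmission function
# ---------------------------------------------------------------------------

def coefficient_of_finesse(reflectivity: float | np.ndarray) -> float | np.ndarray:
    """Coefficient of finesse ``F = 4R/(1-R)^2`` of a lossless etalon.

    This is the quantity that sets the Airy peak-to-valley transmission
    ratio ``1 + F`` and hence the attainable contrast enhancement; at
    R = 0.68 it evaluates to 26.56.
    """
    r = np.asarray(reflectivity, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1):
        raise ValueError("reflectivity must lie in (0, 1)")
    out = 4.0 * r / (1.0 - r) ** 2
    return float(out) if np.ndim(reflectivity) == 0 else out


def classical_finesse(reflectivity: float | np.ndarray) -> float | np.ndarray:
    """Classical reflectivity finesse ``pi*sqrt(R)/(1-R)`` (FSR / peak FWHM).

    Distinct from :func:`coefficient_of_finesse`; at R = 0.68 it is 8.1.
    """
    r = np.asarray(reflectivity, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1):
        raise ValueError("reflectivity must lie in (0, 1)")
    out = np.pi * np.sqrt(r) / (1.0 - r)
    return float(out) if np.ndim(reflectivity) == 0 else out


def airy_transmission(
    ot_um: float | np.ndarray,
    wavelength_nm: float | np.ndarray,
    reflectivity: float,
) -> float | np.ndarray:
    """Airy transmission ``1/(1 + F sin^2(2 pi OT / lambda))``.

    Periodic in ``ot_um`` with period ``lambda/2``; equals 1 on resonance
    (``2 OT = N lambda``) and ``1/(1+F)`` at anti-resonance.
    """
    ot = np.asarray(ot_um, dtype=float)
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(ot <= 0):
        raise ValueError("optical thickness must be positive")
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    f = coefficient_of_finesse(reflectivity)
    phase = 2.0 * np.pi * (ot * 1000.0) / lam
    out = 1.0 / (1.0 + f * np.sin(phase) ** 2)
    if np.ndim(ot_um) == 0 and np.ndim(wavelength_nm) == 0:
        return float(out)
    return out


def airy_mean_transmission(reflectivity: float) -> float:
    """Mean of the Airy function over one period, ``(1 + F)^(-1/2)``.

    This is the wide-field (WFM) background level obtained by averaging a
    wavelength scan over one free spectral range; it is independent of the
    cavity optical thickness, which is why pure phase objects vanish in
    the averaged image.
    """
    return 1.0 / np.sqrt(1.0 + coefficient_of_finesse(reflectivity))


# ---------------------------------------------------------------------------
# Spectral bookkeeping: FSR, interference order, resolution limit
# ---------------------------------------------------------------------------

def free_spectral_range(wavelength_nm: float, ot_um: float) -> float:
    """Free spectral range ``lambda^2 / (2 OT)`` in nm.

    Valid in the usual high-order regime ``OT >> lambda``; for the
    water-filled 50 um channel at 516 nm this is about 2.0 nm.
    """
    if ot_um <= 0:
        raise ValueError("optical thickness must be positive")
    return wavelength_nm**2 / (2.0 * ot_um * 1000.0)


def interference_order(medium_index: float, channel_height_um: float, wavelength_nm: float) -> int:
    """Interference order ``N = round(2 n_m d / lambda)``.

    Calibrated against background (fluid-only) regions; round-half-to-even
    so that order calibration is deterministic on exact half-integers.
    """
    if medium_index <= 0 or channel_height_um <= 0 or wavelength_nm <= 0:
        raise ValueError("inputs must be positive")
    return int(np.round(2.0 * medium_index * channel_height_um * 1000.0 / wavelength_nm))


def ot_resolution_limit(order: int, fwhm_nm: float) -> float:
    """Optical-thickness resolution limit ``N * dlambda / 2`` in nm.

    The smallest resolvable change in optical thickness, set by the
    spectral width of the illumination and the interference order of the
    cavity (37.4 nm for N = 258, dlambda = 0.29 nm).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    return order * fwhm_nm / 2.0


# ---------------------------------------------------------------------------
# Finite-linewidth (effective) transmission
# ---------------------------------------------------------------------------

def _line_quadrature(line: LaserLine, n_points: int, span_sigmas: float):
    sig = line.sigma_nm
    lam = np.linspace(line.center_nm - span_sigmas * sig,
                      line.center_nm + span_sigmas * sig, n_points)
    w = np.exp(-0.5 * ((lam - line.center_nm) / sig) ** 2)
    return lam, w / w.sum()


def effective_transmission(
    ot_um: float | np.ndarray,
    line: LaserLine,
    reflectivity: float,
    *,
    n_points: int = 61,
    span_sigmas: float = 4.0,
) -> float | np.ndarray:
    """Transmission of a finite-bandwidth Gaussian line through the cavity.

    Cross-correlates the normalized laser spectrum ``S(lambda)`` with the
    Airy function::

        T_eff = int S(lambda) T(OT, lambda) dlambda / int S(lambda) dlambda

    The finite bandwidth rounds off the resonance peaks: ``T_eff < 1`` on
    resonance for any ``fwhm > 0``, converging to the Airy function as the
    bandwidth goes to zero.
    """
    if span_sigmas < 3.0:
        raise ValueError("quadrature grid must span at least +-3 sigma")
    ot = np.asarray(ot_um, dtype=float)
    lam, w = _line_quadrature(line, n_points, span_sigmas)
    phase = 2.0 * np.pi * (ot[..., None] * 1000.0) / lam
    f = coefficient_of_finesse(reflectivity)
    t = 1.0 / (1.0 + f * np.sin(phase) ** 2)
    out = t @ w
    return float(out) if np.ndim(ot_um) == 0 else out


def transmission_spectrum(
    ot_um: float,
    wavelengths_nm: Sequence[float],
    cavity: CavitySpec,
    line: LaserLine,
) -> np.ndarray:
    """Effective transmission versus illumination wavelength at fixed OT.

    This is the theoretical background-level curve that measured empty-
    channel intensities are validated against; peaks are spaced by the
    free spectral range.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    if np.any(np.diff(lam) < 0):
        raise ValueError("wavelength grid must be sorted ascending")
    out = np.empty(lam.shape, dtype=float)
    for i, lc in enumerate(lam):
        out[i] = effective_transmission(ot_um, line.at(float(lc)), cavity.reflectivity_at(float(lc)))
    return out


# ---------------------------------------------------------------------------
# Ghost foci
# ---------------------------------------------------------------------------

def ghost_foci(cavity: CavitySpec, k_max: int = 2) -> GhostSeries:
    """Axial ghost-image series from k extra cavity round trips.

    Light making ``k`` additional round trips between the partially
    reflective surfaces travels an extra path ``2 d k``; in the paraxial
    focal-shift approximation the k-th ghost image appears displaced by
    ``2 d k / n_m`` with relative intensity ``R^(2k)`` (two additional
    mirror reflections per round trip).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    d = cavity.channel_height_um
    n_m = cavity.medium_index
    r = cavity.reflectivity_at(np.mean(cavity.coating_band_nm)) if np.ndim(
        cavity.reflectivity
    ) else float(cavity.reflectivity)
    k = np.arange(k_max + 1)
    return GhostSeries(offsets_um=2.0 * d * k / n_m, relative_intensities=r ** (2 * k))
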