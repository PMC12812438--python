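"""On-disk acquisition dialect and spectral-center fitting.

A wavelength scan is stored as one grayscale image per illumination step
(BMP, PNG or TIFF), a plain-text metadata file of ``key=value`` lines with
a versioned header, and optionally one two-column CSV spectrum per frame.
Images are named ``frame_{index:03d}_{wavelength_nm:.3f}.<ext>``.  The
central wavelength of each recorded spectrum is obtained by least-squares
fitting a Gaussian; failed fits fall back to the argmax wavelength and are
flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.optimize import curve_fit

__all__ = [
    "SpectrumRecord",
    "AcquisitionMetadata",
    "WavelengthStack",
    "fit_center_wavelength",
    "read_stack",
    "write_stack",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

METADATA_FILE = "metadata.txt"
METADATA_HEADER = "# fpm-acquisition v1"

#: ITU-R BT.601 luminance weights for collapsing color frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AcquisitionMetadata:
    """Camera/illumination metadata logged next to every stack."""

    exposure_ms: float = 350.0
    gain: float = 200.0
    magnification: float = 50.0
    sample_info: str = ""
    central_wavelengths_nm: list[float] = field(default_factory=list)


@dataclass
class WavelengthStack:
    """Ordered set of 2-D intensity frames with their central wavelengths.

    Frames are float arrays in [0, 1] (8-bit data divided by 255) sorted
    ascending in wavelength; ``ground_truth`` may carry simulation truth.
    """

    frames: np.ndarray                      # (n_frames, ny, nx)
    wavelengths_nm: np.ndarray              # (n_frames,)
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)
    pixel_size_um: float = 0.868
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) array")
        if len(self.wavelengths_nm) != len(self.frames):
            raise ValueError("one wavelength per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def sorted_by_wavelength(self) -> "WavelengthStack":
        order = np.argsort(self.wavelengths_nm, kind="stable")
        return WavelengthStack(self.frames[order], self.wavelengths_nm[order],
                               self.metadata, self.pixel_size_um, self.ground_truth)


@dataclass
class SpectrumRecord:
    """A measured laser spectrum and its fitted central wavelength."""

    wavelength_grid_nm: np.ndarray
    counts: np.ndarray
    fitted_center_nm: float = float("nan")
    fit_ok: bool = False


def _gaussian(x, amp, center, sigma, offset):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_center_wavelength(
    wavelength_grid_nm: Sequence[float],
    counts: Sequence[float],
) -> SpectrumRecord:
    """Fit a Gaussian (amplitude, center, width, offset) to a spectrum.

    Returns the fitted center; on any fit failure (or a fitted center
    outside the grid) the record falls back to the first argmax wavelength
    with ``fit_ok=False``.
    """
    lam = np.asarray(wavelength_grid_nm, dtype=float)
    cts = np.asarray(counts, dtype=float)
    if lam.size == 0:
        raise ValueError("empty spectrum")
    if lam.size < 5:
        raise ValueError("spectrum needs at least 5 samples")
    if np.any(cts < 0):
        raise ValueError("counts must be nonnegative")
    rec = SpectrumRecord(lam, cts)
    fallback = float(lam[int(np.argmax(cts))])
    span = lam[-1] - lam[0]
    if np.ptp(cts) <= 0:
        rec.fitted_center_nm = fallback
        return rec
    p0 = [float(np.ptp(cts)), fallback, max(span / 10.0, 1e-6), float(np.min(cts))]
    try:
        popt, _ = curve_fit(_gaussian, lam, cts, p0=p0, maxfev=5000)
    except (RuntimeError, ValueError):
        rec.fitted_center_nm = fallback
        return rec
    center = float(popt[1])
    if not lam[0] <= center <= lam[-1]:
        rec.fitted_center_nm = fallback
        return rec
    rec.fitted_center_nm = center
    rec.fit_ok = True
    return rec


# ---------------------------------------------------------------------------
# Stack reading / writing
# ---------------------------------------------------------------------------

_FRAME_EXTS = (".bmp", ".png", ".tif", ".tiff")


def _read_frame(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise OSError(f"unreadable frame {path.name}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:  # color -> luminance
        img = img[..., :3] @ _LUMA
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / float(np.iinfo(img.dtype).max)
    return img.astype(float)


def read_stack(directory: str | Path, crop: tuple[int, int, int, int] | None = None) -> WavelengthStack:
    """Read an acquisition directory into a wavelength-sorted stack.

    8-bit frames are promoted to floats in [0, 1]; ``crop`` is an optional
    ``(y0, y1, x0, x1)`` window.  The frame count must match the metadata's
    central-wavelength count, and all frames must share one shape.
    """
    directory = Path(directory)
    meta = _read_metadata(directory / METADATA_FILE)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _FRAME_EXTS and p.stem.startswith("frame_"))
    if len(files) != len(meta.central_wavelengths_nm):
        raise ValueError(
            f"frame count ({len(files)}) does not match metadata wavelength "
            f"count ({len(meta.central_wavelengths_nm)})"
        )
    if not files:
        raise ValueError(f"no frames found in {directory}")
    # wavelength from the filename keeps the frame<->wavelength pairing robust
    # to directory listing order; stable sort tie-breaks by filename
    lam = np.array([float(p.stem.split("_")[-1]) for p in files])
    frames = [_read_frame(p) for p in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have inconsistent shapes: {sorted(shapes)}")
    stack = WavelengthStack(np.stack(frames), lam, meta).sorted_by_wavelength()
    if crop is not None:
        y0, y1, x0, x1 = crop
        stack = WavelengthStack(stack.frames[:, y0:y1, x0:x1], stack.wavelengths_nm,
                                stack.metadata, stack.pixel_size_um)
    return stack


def write_stack(
    stack: WavelengthStack,
    directory: str | Path,
    *,
    image_format: str = "bmp",
    overwrite: bool = False,
    spectra: Sequence[SpectrumRecord] | None = None,
) -> list[Path]:
    """Write a stack in the acquisition dialect; returns the file manifest.

    Frames are quantized to 8 bit for BMP/PNG (the acquisition bit depth)
    or written as float TIFF for lossless storage.
    """
    if len(stack) == 0:
        raise ValueError("cannot write an empty stack")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not overwrite and any(directory.iterdir()):
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    manifest: list[Path] = []
    for i, (frame, lam) in enumerate(zip(stack.frames, stack.wavelengths_nm)):
        path = directory / f"frame_{i:03d}_{lam:.3f}.{image_format}"
        if image_format in ("tif", "tiff"):
            tifffile.imwrite(path, frame.astype(np.float32))
        else:
            img8 = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
            iio.imwrite(path, img8)
        manifest.append(path)
    meta = stack.metadata
    lines = [METADATA_HEADER,
             f"exposure_ms={meta.exposure_ms}",
             f"gain={meta.gain}",
             f"magnification={meta.magnification}",
             f"sample_info={meta.sample_info}",
             f"pixel_size_um={stack.pixel_size_um}",
             "central_wavelengths_nm=" + ",".join(f"{w:.6f}" for w in stack.wavelengths_nm)]
    mpath = directory / METADATA_FILE
    mpath.write_text("\n".join(lines) + "\n")
    manifest.append(mpath)
    if spectra is not None:
        for i, rec in enumerate(spectra):
            spath = directory / f"spectrum_{i:03d}.csv"
            write_spectrum_csv(rec, spath)
            manifest.append(spath)
    return manifest


def _read_metadata(path: Path) -> AcquisitionMetadata:
    if not path.exists():
        raise FileNotFoundError(f"missing metadata file {path}")
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# fpm-acquisition"):
        raise ValueError(f"{path} lacks the fpm-acquisition header")
    meta = AcquisitionMetadata()
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        if key == "exposure_ms":
            meta.exposure_ms = float(val)
        elif key == "gain":
            meta.gain = float(val)
        elif key == "magnification":
            meta.magnification = float(val)
        elif key == "sample_info":
            meta.sample_info = val
        elif key == "central_wavelengths_nm":
            meta.central_wavelengths_nm = [float(v) for v in val.split(",") if v]
    return meta


def write_spectrum_csv(record: SpectrumRecord, path: str | Path) -> None:
    data = np.column_stack([record.wavelength_grid_nm, record.counts])
    np.savetxt(path, data, delimiter=",", header="wavelength_nm,counts")


def read_spectrum_csv(path: str | Path) -> SpectrumRecord:
    data = np.loadtxt(path, delimiter=",")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a two-column spectrum")
    return fit_center_wavelength(data[:, 0], data[:, 1])
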