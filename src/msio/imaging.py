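"""Downstream operations on loaded spectra and pixel grids.

* base-peak and total-ion chromatograms for LC-MS / ambient-MS runs,
* ion-image slicing: per-pixel aggregation of intensity inside a narrow
  m/z window,
* TrIQ (Threshold Intensity Quantization): contrast optimization that caps
  intensities at the smallest observed value covering a target cumulative
  probability, then quantizes linearly to L levels,
* 8-bit indexed-palette BMP export (viridis by default).

The window aggregate defaults to SUM (robust when a centroided peak splits
across the window); ``agg="max"`` is available.  Window bounds are closed on
both ends, so boundary ties are included deterministically.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import MsioError, OutOfGridError
from .imzml_reader import ImageDims, PixelSpectrum
from .mzml_reader import SpectraSet


@dataclass(frozen=True)
class IonImage:
    """2-D intensity map for one m/z window, shape (max_y, max_x)."""

    values: np.ndarray
    target_mz: float
    tol: float


@dataclass(frozen=True)
class QuantizedImage:
    """Integer level matrix in [0, L-1] plus the TrIQ threshold that made it."""

    levels: np.ndarray
    L: int
    p: float
    threshold: float


Palette = List[Tuple[int, int, int]]


def get_slice(
    pixels: Iterable[PixelSpectrum],
    dims: ImageDims,
    target_mz: float,
    tol: float,
    agg: str = "sum",
) -> IonImage:
    """Extract an ion image: per pixel, aggregate intensity within
    ``[target_mz - tol, target_mz + tol]`` (closed interval).

    Grid cells with no stored pixel stay 0.  ``agg`` selects SUM (default)
    or MAX aggregation over the window.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if agg not in ("sum", "max"):
        raise ValueError(f"agg must be 'sum' or 'max', got {agg!r}")
    lo, hi = target_mz - tol, target_mz + tol
    values = np.zeros((dims.max_y, dims.max_x), dtype=np.float64)
    for px in pixels:
        if not (1 <= px.x <= dims.max_x and 1 <= px.y <= dims.max_y):
            raise OutOfGridError(
                f"pixel ({px.x}, {px.y}) outside {dims.max_x} x {dims.max_y} grid"
            )
        mz = np.asarray(px.mz)
        mask = (mz >= lo) & (mz <= hi)
        if not mask.any():
            continue
        window = np.asarray(px.intensity)[mask]
        contrib = window.sum() if agg == "sum" else window.max()
        if agg == "sum":
            values[px.y - 1, px.x - 1] += contrib
        else:
            values[px.y - 1, px.x - 1] = max(values[px.y - 1, px.x - 1], contrib)
    return IonImage(values=values, target_mz=target_mz, tol=tol)


def triq_threshold(values: np.ndarray, p: float) -> float:
    """Smallest observed value v with ``count(values <= v) / n >= p``.

    This is the exact empirical quantile over the sorted values — no
    histogram binning, so there is no bin-count parameter.
    """
    flat = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = flat.size
    if n == 0:
        raise ValueError("empty image")
    k = int(np.ceil(p * n))
    return float(flat[max(k, 1) - 1])


def triq(image, L: int, p: float) -> QuantizedImage:
    """Threshold Intensity Quantization.

    Caps the image at the threshold ``T`` covering cumulative probability
    ``p`` of all pixel values, then quantizes ``[v_min, T]`` into ``L``
    equal-width bins: ``level(v) = min(L - 1, floor((min(v, T) - v_min) /
    (T - v_min) * L))``, so values at or above ``T`` map to ``L - 1``.  A
    constant image maps to all zeros.  The intensity→level mapping is
    monotone non-decreasing.
    """
    if not isinstance(L, (int, np.integer)) or L < 2:
        raise ValueError(f"L must be an integer >= 2, got {L!r}")
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p!r}")
    values = image.values if isinstance(image, IonImage) else np.asarray(image)
    values = values.astype(np.float64, copy=False)
    v_min = float(values.min())
    T = triq_threshold(values, p)
    if T == v_min:
        levels = np.zeros(values.shape, dtype=np.uint16)
    else:
        clipped = np.minimum(values, T)
        levels = np.floor((clipped - v_min) / (T - v_min) * L).astype(np.uint16)
        np.minimum(levels, L - 1, out=levels)
    return QuantizedImage(levels=levels, L=int(L), p=float(p), threshold=T)


def bpc(spectra: SpectraSet | Iterable) -> np.ndarray:
    """Base-peak chromatogram: per-spectrum maximum intensity (0 if empty)."""
    return np.array(
        [s.intensity.max() if len(s.intensity) else 0.0 for s in spectra],
        dtype=np.float64,
    )


def tic(spectra: SpectraSet | Iterable) -> np.ndarray:
    """Total-ion chromatogram: per-spectrum summed intensity (0 if empty)."""
    return np.array(
        [s.intensity.sum() if len(s.intensity) else 0.0 for s in spectra],
        dtype=np.float64,
    )


def write_chromatogram_csv(values: Sequence[float], path) -> None:
    """Write a BPC/TIC vector as two-column CSV with header ``scan,value``."""
    with open(path, "w", newline="") as fh:
        fh.write("scan,value\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{v:.12g}\n")


def viridis_palette() -> Palette:
    """The canonical 256-entry viridis colormap as 8-bit RGB triples."""
    from matplotlib import colormaps

    rgba = colormaps["viridis"](np.linspace(0.0, 1.0, 256))
    rgb = np.rint(rgba[:, :3] * 255).astype(int)
    return [tuple(int(c) for c in row) for row in rgb]


def save_bitmap(
    quantized: QuantizedImage | np.ndarray,
    path,
    palette: Optional[Palette] = None,
) -> None:
    """Write an 8-bit indexed-color Windows BMP.

    Layout: BITMAPFILEHEADER + BITMAPINFOHEADER, a 256-entry BGRA color
    table, then bottom-up pixel rows padded to 4-byte multiples; each pixel
    byte is the quantization level, so an independent reader recovers levels
    and palette losslessly.  Row 1 of the matrix appears at the top of the
    rendered image.
    """
    levels = (
        quantized.levels if isinstance(quantized, QuantizedImage) else quantized
    )
    levels = np.asarray(levels)
    if isinstance(quantized, QuantizedImage) and quantized.L > 256:
        raise MsioError(
            f"cannot export {quantized.L} levels in an 8-bit indexed bitmap"
        )
    if levels.size and levels.max() > 255:
        raise MsioError("levels above 255 cannot be stored in an 8-bit bitmap")
    if palette is None:
        palette = viridis_palette()
    if len(palette) != 256:
        raise ValueError(f"palette must have 256 entries, got {len(palette)}")
    height, width = levels.shape
    stride = (width + 3) & ~3
    image_size = stride * height
    data_offset = 14 + 40 + 256 * 4
    with open(path, "wb") as fh:
        fh.write(struct.pack("<2sIHHI", b"BM", data_offset + image_size, 0, 0,
                             data_offset))
        fh.write(struct.pack("<IiiHHIIiiII", 40, width, height, 1, 8, 0,
                             image_size, 2835, 2835, 256, 0))
        for r, g, b in palette:
            fh.write(struct.pack("<BBBB", b, g, r, 0))
        pad = b"\x00" * (stride - width)
        arr = levels.astype(np.uint8)
        for row in arr[::-1]:  # bottom-up storage
            fh.write(row.tobytes() + pad)


def save_png(
    quantized: QuantizedImage | np.ndarray,
    path,
    palette: Optional[Palette] = None,
) -> None:
    """Convenience PNG export with identical pixel semantics to the BMP."""
    from PIL import Image

    levels = (
        quantized.levels if isinstance(quantized, QuantizedImage) else quantized
    )
    if palette is None:
        palette = viridis_palette()
    img = Image.fromarray(np.asarray(levels).astype(np.uint8), mode="P")
    img.putpalette([c for rgb in palette for c in rgb])
    img.save(path, format="PNG")
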