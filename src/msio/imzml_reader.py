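"""Processed-mode imzML + ibd loader.

imzML splits mass spectrometry imaging data in two files: an XML document
(``.imzML``) describing every pixel's spectrum, and a raw binary stream
(``.ibd``) holding the actual float vectors, addressed by byte offset and
element count.  In *processed* mode every pixel owns a distinct m/z axis;
*continuous* mode (one shared axis) is rejected explicitly.

Axis encodings come from the document-level ``<referenceableParamGroup>``
elements; image dimensions from the ``<scanSettings>`` maximum-pixel-count
accessions and the ``<spectrumList count>`` attribute (the count attribute is
authoritative — files legitimately store fewer pixels than the grid product).
Per-pixel reads use a skip-byte strategy: the distance between successive
``<spectrum>`` elements is estimated from the first pair, the scanner jumps
ahead by that hint (with a guard margin) and re-verifies the landmark, so the
result is identical to a naive full scan.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import BinaryIO, List, Optional, Tuple

from . import xml_scan
from .binary_codec import ArrayEncoding, bytes_to_array
from .errors import (
    CorruptLocatorError,
    MalformedFileError,
    MalformedPixelError,
    PairedFileError,
    UnsupportedModeError,
)
from .mzml_reader import AxisConfig, _axis_from_block

IBD_UUID_BYTES = 16


class ImzCvAccession:
    """Imaging-MS controlled-vocabulary accessions used by the reader."""

    POS_X = "IMS:1000050"
    POS_Y = "IMS:1000051"
    MAX_X = "IMS:1000042"
    MAX_Y = "IMS:1000043"
    EXT_OFFSET = "IMS:1000102"
    EXT_LENGTH = "IMS:1000103"
    EXT_ENCODED_LENGTH = "IMS:1000104"
    MODE_CONTINUOUS = "IMS:1000030"
    MODE_PROCESSED = "IMS:1000031"


@dataclass(frozen=True)
class ImageDims:
    """Grid extents plus the authoritative stored-pixel count."""

    max_x: int
    max_y: int
    n_spectra: int


@dataclass(frozen=True)
class PixelSpectrum:
    """One pixel: 1-based grid coordinates (as stored) and its spectrum."""

    x: int
    y: int
    mz: "np.ndarray"
    intensity: "np.ndarray"


@dataclass(frozen=True)
class AxisLocator:
    """Where one axis's values live in the ibd stream."""

    offset: int
    count: int
    encoded_length: int  # bytes on disk (== count * width when uncompressed)


@dataclass(frozen=True)
class PixelLocator:
    mz: AxisLocator
    intensity: AxisLocator


def load_imzml(
    imzml_path: str | os.PathLike,
) -> Tuple[List[PixelSpectrum], ImageDims]:
    """Load every stored pixel of a processed-mode imzML/ibd pair.

    Returns the pixels in file order (not grid order) together with the
    image dimensions.  The sibling ``.ibd`` file must share the basename.
    """
    imzml_path = os.fspath(imzml_path)
    base, _ = os.path.splitext(imzml_path)
    ibd_path = base + ".ibd"
    if not os.path.exists(ibd_path):
        raise PairedFileError(f"missing ibd file for {imzml_path}: {ibd_path}")
    with open(imzml_path, "rb") as doc, open(ibd_path, "rb") as ibd:
        _check_mode(doc)
        doc.seek(0)
        configs = axes_config_img(doc)
        doc.seek(0)
        dims = get_img_dimensions(doc)
        pixels = load_img_data(doc, ibd, dims, configs)
    return pixels, dims


def _check_mode(doc: BinaryIO) -> None:
    """Reject documents declaring continuous mode (shared m/z axis)."""
    doc.seek(0)
    block = xml_scan.read_element_block(doc, "fileDescription")
    if block is None:
        return  # no declaration: assume processed
    if ImzCvAccession.MODE_CONTINUOUS.encode() in block[1]:
        raise UnsupportedModeError(
            "continuous-mode imzML is not supported (processed mode only)"
        )


def axes_config_img(doc: BinaryIO) -> Tuple[AxisConfig, AxisConfig]:
    """Decode both axis encodings from the referenceableParamGroup elements.

    Returns ``(mz_config, intensity_config)``; each config records the
    group's ``id`` so per-pixel ``<referenceableParamGroupRef>`` elements can
    be matched back to an axis role.
    """
    found = {}
    while True:
        block = xml_scan.read_element_block(doc, "referenceableParamGroup")
        if block is None:
            break
        text = block[1]
        mid = re.search(rb'\bid="([^"]+)"', text)
        if mid is None:
            continue
        if b'accession="MS:1000514"' not in text and (
            b'accession="MS:1000515"' not in text
        ):
            continue  # not an array-describing group
        cfg = _axis_from_block(text, "first")
        cfg = AxisConfig(
            role=cfg.role,
            encoding=cfg.encoding,
            position="first" if cfg.role == "mz" else "second",
            group_ref=mid.group(1).decode("utf-8"),
        )
        found[cfg.role] = cfg
    if "mz" not in found or "intensity" not in found:
        raise MalformedFileError(
            "referenceableParamGroup elements do not describe both the m/z "
            "and intensity axes"
        )
    return found["mz"], found["intensity"]


def get_img_dimensions(doc: BinaryIO) -> ImageDims:
    """Read max pixel counts (scanSettings) and the stored-spectrum count."""
    doc.seek(0)
    settings = xml_scan.read_element_block(doc, "scanSettings")
    if settings is None:
        raise MalformedFileError("no <scanSettings> element")
    max_x = _cv_value(settings[1], ImzCvAccession.MAX_X)
    max_y = _cv_value(settings[1], ImzCvAccession.MAX_Y)
    if max_x is None or max_y is None:
        raise MalformedFileError(
            "scanSettings lacks the maximum-pixel-count accessions"
        )
    hit = xml_scan.find_tag(doc, "spectrumList")
    if hit is None:
        raise MalformedFileError("no <spectrumList> element")
    count = xml_scan.read_attribute(hit.element_text, "count")
    if count is None or not count.isdigit() or int(count) < 1:
        raise MalformedFileError(
            f"spectrumList count attribute invalid: {count!r}"
        )
    if int(max_x) < 1 or int(max_y) < 1:
        raise MalformedFileError("image dimensions must be >= 1")
    return ImageDims(int(max_x), int(max_y), int(count))


def _cv_value(block: bytes, accession: str) -> Optional[int]:
    m = re.search(
        rb'<cvParam\b[^>]*accession="%s"[^>]*>' % accession.encode("ascii"),
        block,
    )
    if m is None:
        return None
    val = xml_scan.read_attribute(m.group(0).decode("utf-8"), "value")
    if val is None:
        return None
    return int(val)


def get_spectrum_attributes(
    spectrum_text: bytes | str, configs: Tuple[AxisConfig, AxisConfig]
) -> Tuple[int, int, PixelLocator]:
    """Pixel coordinates and ibd locators from one ``<spectrum>`` element.

    Coordinates come from the scan's position accessions; each axis's
    external offset / element count / encoded length from the IMS accessions
    inside its ``<binaryDataArray>`` block, matched to a role via the
    ``<referenceableParamGroupRef>`` it carries (or a direct array-role
    accession).  Both placements seen in the wild are accepted.
    """
    text = (
        spectrum_text.encode("utf-8")
        if isinstance(spectrum_text, str)
        else spectrum_text
    )
    x = _cv_value(text, ImzCvAccession.POS_X)
    y = _cv_value(text, ImzCvAccession.POS_Y)
    if x is None or y is None:
        raise MalformedPixelError("spectrum lacks x/y position accessions")
    mz_cfg, int_cfg = configs
    locators = {}
    for block in re.findall(
        rb"<binaryDataArray\b.*?</binaryDataArray>", text, re.DOTALL
    ):
        role = _block_role(block, mz_cfg, int_cfg)
        if role is None:
            continue
        offset = _cv_value(block, ImzCvAccession.EXT_OFFSET)
        count = _cv_value(block, ImzCvAccession.EXT_LENGTH)
        if offset is None or count is None:
            raise MalformedPixelError(
                f"{role} array lacks external offset/length accessions"
            )
        enc = (mz_cfg if role == "mz" else int_cfg).encoding
        enc_len = _cv_value(block, ImzCvAccession.EXT_ENCODED_LENGTH)
        if enc_len is None:
            if enc.compression != "none":
                raise MalformedPixelError(
                    f"compressed {role} array lacks the encoded-length accession"
                )
            enc_len = count * enc.value_width
        locators[role] = AxisLocator(offset, count, enc_len)
    if "mz" not in locators or "intensity" not in locators:
        raise MalformedPixelError("spectrum lacks locators for both axes")
    return x, y, PixelLocator(locators["mz"], locators["intensity"])


def _block_role(
    block: bytes, mz_cfg: AxisConfig, int_cfg: AxisConfig
) -> Optional[str]:
    m = re.search(rb'<referenceableParamGroupRef\s+ref="([^"]+)"', block)
    if m is not None:
        ref = m.group(1).decode("utf-8")
        if ref == mz_cfg.group_ref:
            return "mz"
        if ref == int_cfg.group_ref:
            return "intensity"
    if b'accession="MS:1000514"' in block:
        return "mz"
    if b'accession="MS:1000515"' in block:
        return "intensity"
    return None


#: guard margin backed off a skip hint before re-locating <spectrum>
_SKIP_GUARD = 256


def load_img_data(
    doc: BinaryIO,
    ibd: BinaryIO,
    dims: ImageDims,
    configs: Tuple[AxisConfig, AxisConfig],
    use_skip_hints: bool = True,
) -> List[PixelSpectrum]:
    """Read all stored pixels, in file order.

    With ``use_skip_hints`` the document pointer jumps ahead by the stride
    observed between the first two ``<spectrum>`` elements (minus a guard)
    before re-locating the next tag; with it off the scanner reads the
    document linearly.  Both paths produce identical results — the naive
    path exists as the correctness oracle for the optimized one.
    """
    mz_cfg, int_cfg = configs
    ibd.seek(0, os.SEEK_END)
    ibd_size = ibd.tell()
    doc.seek(0)
    pixels: List[PixelSpectrum] = []
    stride_hint: Optional[int] = None
    prev_start: Optional[int] = None
    for ordinal in range(dims.n_spectra):
        if use_skip_hints and stride_hint is not None and prev_start is not None:
            target = prev_start + stride_hint - _SKIP_GUARD
            if target > doc.tell():
                doc.seek(target)
        block = xml_scan.read_element_block(doc, "spectrum")
        if block is None and use_skip_hints and prev_start is not None:
            # hint overshot: fall back to scanning from the previous element
            doc.seek(prev_start + 1)
            block = xml_scan.read_element_block(doc, "spectrum")
        if block is None:
            raise MalformedFileError(
                f"expected {dims.n_spectra} <spectrum> elements, "
                f"found {ordinal}"
            )
        start, text = block
        if prev_start is not None and stride_hint is None:
            stride_hint = start - prev_start
        prev_start = start
        try:
            x, y, loc = get_spectrum_attributes(text, configs)
        except MalformedPixelError as exc:
            raise MalformedPixelError(f"pixel {ordinal}: {exc}") from exc
        if not (1 <= x <= dims.max_x and 1 <= y <= dims.max_y):
            raise MalformedPixelError(
                f"pixel {ordinal}: position ({x}, {y}) outside "
                f"{dims.max_x} x {dims.max_y} grid"
            )
        vectors = {}
        for role, axloc, cfg in (
            ("mz", loc.mz, mz_cfg),
            ("intensity", loc.intensity, int_cfg),
        ):
            if axloc.offset + axloc.encoded_length > ibd_size:
                raise CorruptLocatorError(
                    f"pixel {ordinal}: {role} locator (offset {axloc.offset}, "
                    f"{axloc.encoded_length} bytes) exceeds ibd size {ibd_size}"
                )
            ibd.seek(axloc.offset)
            raw = ibd.read(axloc.encoded_length)
            vectors[role] = bytes_to_array(raw, cfg.encoding, axloc.count)
        if len(vectors["mz"]) != len(vectors["intensity"]):
            raise MalformedPixelError(
                f"pixel {ordinal}: axis lengths differ"
            )
        pixels.append(
            PixelSpectrum(x=x, y=y, mz=vectors["mz"], intensity=vectors["intensity"])
        )
    return pixels
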