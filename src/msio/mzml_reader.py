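"""Indexed mzML loader.

An indexed mzML document wraps the spectra in ``<indexedmzML>`` and appends a
``<indexList>`` of byte offsets, whose own position is recorded in
``<indexListOffset>`` near the end of the file.  The loader resolves that
tail offset, parses the spectrum offset list, configures the two data axes
(m/z and intensity) from the FIRST spectrum only — axis order, float width
and compression are assumed constant across the file — and then decodes every
spectrum by direct seek.  Non-indexed files are rejected.

Precursor, MS-level and retention-time metadata are not parsed; spectra are
addressed positionally.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import BinaryIO, List, Optional, Sequence, Tuple

import numpy as np

from . import xml_scan
from .binary_codec import ArrayEncoding, decode_binary_array
from .errors import (
    CorruptIndexError,
    MalformedFileError,
    SpectrumDecodeError,
    UnsupportedEncodingError,
)


class CvAccession:
    """PSI-MS controlled-vocabulary accessions this reader relies on."""

    MZ_ARRAY = "MS:1000514"
    INTENSITY_ARRAY = "MS:1000515"
    FLOAT32 = "MS:1000521"
    FLOAT64 = "MS:1000523"
    ZLIB = "MS:1000574"
    NO_COMPRESSION = "MS:1000576"


# accessions that denote value types we deliberately do not support
_REJECTED_TYPES = {"MS:1000519", "MS:1000522"}  # 32/64-bit integer arrays

#: bytes backed off before re-verifying a skip-byte landing (attribute
#: lengths vary between spectra, so the hint may overshoot slightly)
_SKIP_GUARD = 128


@dataclass(frozen=True)
class AxisConfig:
    """Per-axis decoding recipe, read once from the first spectrum.

    ``skip_bytes`` is the byte distance from ``<spectrum`` to its
    ``<binaryDataArrayList`` in that first spectrum — an optimization hint
    only: later spectra are re-verified after skipping.
    """

    role: str  # "mz" | "intensity"
    encoding: ArrayEncoding
    position: str  # "first" | "second"
    skip_bytes: int = 0
    group_ref: Optional[str] = None


@dataclass(frozen=True)
class Spectrum:
    """One scan: paired m/z and intensity vectors of equal length."""

    mz: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class SpectraSet:
    """Ordered spectra, index order equal to the file's offset-list order."""

    spectra: List[Spectrum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]


def load_mzml(path: str | os.PathLike, strict: bool = False) -> SpectraSet:
    """Load every spectrum of an indexed mzML file.

    Parameters
    ----------
    path : path-like
        Indexed mzML document (``<indexedmzML>`` wrapper required).
    strict : bool
        When true, every spectrum's axis accessions are re-checked against
        the first spectrum's configuration instead of being assumed constant.

    Raises
    ------
    IndexRequiredError
        if the file carries no tail ``<indexListOffset>``.
    MalformedFileError, UnsupportedEncodingError, SpectrumDecodeError
        on structural or per-spectrum decoding problems (the latter names
        the failing spectrum's ordinal).
    """
    index_offset = xml_scan.read_tail_offset(path)
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        offsets = parse_offset_list(fh, index_offset)
        for off in offsets:
            if off >= size:
                raise CorruptIndexError(
                    f"{os.fspath(path)}: spectrum offset {off} is beyond "
                    f"file size {size}"
                )
        if not offsets:
            return SpectraSet()
        fh.seek(offsets[0])
        block = xml_scan.read_element_block(fh, "spectrum")
        if block is None:
            raise MalformedFileError(
                f"{os.fspath(path)}: first offset does not address a "
                f"<spectrum> element"
            )
        configs = config_spec_dim(block[1])
        return load_spectra(fh, offsets, configs, strict=strict)


def parse_offset_list(stream: BinaryIO, index_offset: int) -> List[int]:
    """Extract the byte offsets under the ``<index name="spectrum">`` entry.

    The index region sits at the file tail and is small, so it is read to the
    end of the stream and parsed in memory; file order is preserved.
    """
    stream.seek(index_offset)
    region = stream.read()
    m = re.search(
        rb'<index\s+name="spectrum"\s*(?:/>|>(.*?)</index>)', region, re.DOTALL
    )
    if m is None:
        raise MalformedFileError('no <index name="spectrum"> in the index list')
    body = m.group(1) or b""
    return [
        int(g)
        for g in re.findall(rb"<offset[^>]*>\s*(\d+)\s*</offset>", body)
    ]


def _axis_from_block(block: bytes, position: str) -> AxisConfig:
    """Derive one AxisConfig from a ``<binaryDataArray>`` block's cvParams."""
    accs = set(re.findall(rb'accession="([^"]+)"', block))
    accs = {a.decode("ascii") for a in accs}
    if CvAccession.MZ_ARRAY in accs and CvAccession.INTENSITY_ARRAY in accs:
        raise MalformedFileError("binary array claims both axis roles")
    if CvAccession.MZ_ARRAY in accs:
        role = "mz"
    elif CvAccession.INTENSITY_ARRAY in accs:
        role = "intensity"
    else:
        raise MalformedFileError(
            "binary array carries neither MS:1000514 nor MS:1000515"
        )
    if accs & _REJECTED_TYPES:
        raise UnsupportedEncodingError(
            f"integer array types are not supported ({accs & _REJECTED_TYPES})"
        )
    if CvAccession.FLOAT64 in accs:
        value_type = "float64"
    elif CvAccession.FLOAT32 in accs:
        value_type = "float32"
    else:
        raise UnsupportedEncodingError(
            f"{role} array declares no recognized float width accession"
        )
    if CvAccession.ZLIB in accs:
        compression = "zlib"
    elif CvAccession.NO_COMPRESSION in accs:
        compression = "none"
    else:
        raise UnsupportedEncodingError(
            f"{role} array declares no recognized compression accession"
        )
    mref = re.search(rb'<referenceableParamGroupRef\s+ref="([^"]+)"', block)
    group_ref = mref.group(1).decode("utf-8") if mref else None
    return AxisConfig(
        role=role,
        encoding=ArrayEncoding(value_type, compression),
        position=position,
        group_ref=group_ref,
    )


_BDA_RE = re.compile(rb"<binaryDataArray\b.*?</binaryDataArray>", re.DOTALL)


def config_spec_dim(
    first_spectrum_text: bytes | str,
) -> Tuple[AxisConfig, AxisConfig]:
    """Configure both axes from the first spectrum's element text.

    Returns ``(mz_config, intensity_config)``; ``position`` records which of
    the two ``<binaryDataArray>`` blocks each axis occupies, and
    ``skip_bytes`` the distance from ``<spectrum`` to
    ``<binaryDataArrayList``.
    """
    text = (
        first_spectrum_text.encode("utf-8")
        if isinstance(first_spectrum_text, str)
        else first_spectrum_text
    )
    skip = text.find(b"<binaryDataArrayList")
    if skip < 0:
        raise MalformedFileError("spectrum has no <binaryDataArrayList>")
    blocks = _BDA_RE.findall(text)
    if len(blocks) != 2:
        raise MalformedFileError(
            f"expected 2 <binaryDataArray> elements, found {len(blocks)}"
        )
    first = _axis_from_block(blocks[0], "first")
    second = _axis_from_block(blocks[1], "second")
    if first.role == second.role:
        raise MalformedFileError(
            f"both binary arrays claim the {first.role!r} role"
        )
    first = AxisConfig(first.role, first.encoding, "first", skip, first.group_ref)
    second = AxisConfig(
        second.role, second.encoding, "second", skip, second.group_ref
    )
    return (first, second) if first.role == "mz" else (second, first)


_BINARY_RE = re.compile(rb"<binary(?:\s[^>]*)?(/>|>(.*?)</binary>)", re.DOTALL)


def _extract_payloads(block: bytes) -> List[bytes]:
    """The raw base64 payloads of each <binary> element, in file order."""
    return [m.group(2) or b"" for m in _BINARY_RE.finditer(block)]


def load_spectra(
    stream: BinaryIO,
    offsets: Sequence[int],
    configs: Tuple[AxisConfig, AxisConfig],
    strict: bool = False,
) -> SpectraSet:
    """Decode every spectrum at the given offsets using the axis configs.

    For each offset the reader seeks directly to the spectrum, advances by
    the precomputed skip-byte hint (minus a small guard, since attribute
    lengths vary between spectra), verifies the ``<binaryDataArrayList>``
    landmark, and decodes the two ``<binary>`` payloads in file order,
    assigning them to axes by the configured positions.
    """
    mz_cfg, int_cfg = configs
    skip = max(0, mz_cfg.skip_bytes - _SKIP_GUARD)
    out = SpectraSet()
    for i, off in enumerate(offsets):
        try:
            stream.seek(off + skip)
            block = xml_scan.read_element_block(stream, "binaryDataArrayList")
            if block is None:
                raise MalformedFileError("no <binaryDataArrayList> found")
            payloads = _extract_payloads(block[1])
            if len(payloads) != 2:
                raise MalformedFileError(
                    f"expected 2 <binary> payloads, found {len(payloads)}"
                )
            if strict:
                blocks = _BDA_RE.findall(block[1])
                chk_first = _axis_from_block(blocks[0], "first")
                chk_second = _axis_from_block(blocks[1], "second")
                for chk, cfg in (
                    (chk_first, mz_cfg if mz_cfg.position == "first" else int_cfg),
                    (chk_second, mz_cfg if mz_cfg.position == "second" else int_cfg),
                ):
                    if chk.role != cfg.role or chk.encoding != cfg.encoding:
                        raise MalformedFileError(
                            "axis configuration differs from first spectrum"
                        )
            first_txt, second_txt = payloads
            mz_txt = first_txt if mz_cfg.position == "first" else second_txt
            int_txt = second_txt if mz_cfg.position == "first" else first_txt
            mz = decode_binary_array(mz_txt.decode("ascii"), mz_cfg.encoding)
            inten = decode_binary_array(int_txt.decode("ascii"), int_cfg.encoding)
            if len(mz) != len(inten):
                raise MalformedFileError(
                    f"m/z length {len(mz)} != intensity length {len(inten)}"
                )
        except SpectrumDecodeError:
            raise
        except Exception as exc:
            raise SpectrumDecodeError(i, str(exc)) from exc
        out.spectra.append(Spectrum(mz=mz, intensity=inten))
    return out


def load_mzml_bytes(data: bytes, strict: bool = False) -> SpectraSet:
    """Convenience: load an in-memory indexed mzML document (tests)."""
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".mzML", delete=False) as fh:
        fh.write(data)
        name = fh.name
    try:
        return load_mzml(name, strict=strict)
    finally:
        os.unlink(name)
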