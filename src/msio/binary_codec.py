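"""Encode/decode the binary arrays of mzML and imzML.

mzML stores each m/z or intensity vector as base64 text, optionally
zlib-compressed, holding little-endian IEEE-754 floats; imzML's external
.ibd file stores the same float streams as raw bytes.  Both paths share the
byte-level codec here.  Integer array types and lossy compressions
(numpress) are out of scope and rejected explicitly.
"""

from __future__ import annotations

import base64
import binascii
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DecodeError, UnsupportedEncodingError

_DTYPES = {"float32": np.dtype("<f4"), "float64": np.dtype("<f8")}
_COMPRESSIONS = ("none", "zlib")


@dataclass(frozen=True)
class ArrayEncoding:
    """Value type and compression of one binary array (byte order is always
    little-endian, as the mzML standard mandates)."""

    value_type: str  # "float32" | "float64"
    compression: str = "none"  # "none" | "zlib"

    def __post_init__(self):
        if self.value_type not in _DTYPES:
            raise UnsupportedEncodingError(
                f"unsupported value type {self.value_type!r}"
            )
        if self.compression not in _COMPRESSIONS:
            raise UnsupportedEncodingError(
                f"unsupported compression {self.compression!r}"
            )

    @property
    def dtype(self) -> np.dtype:
        return _DTYPES[self.value_type]

    @property
    def value_width(self) -> int:
        return self.dtype.itemsize


def bytes_to_array(
    raw: bytes, enc: ArrayEncoding, expected_count: Optional[int] = None
) -> np.ndarray:
    """Reinterpret (optionally zlib-inflating first) raw bytes as a float vector."""
    if enc.compression == "zlib" and raw:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise DecodeError(f"zlib inflate failed: {exc}") from exc
    width = enc.value_width
    if len(raw) % width != 0:
        raise DecodeError(
            f"byte length {len(raw)} is not a multiple of value width {width}"
        )
    values = np.frombuffer(raw, dtype=enc.dtype)
    if expected_count is not None and len(values) != expected_count:
        raise DecodeError(
            f"decoded {len(values)} values, expected {expected_count}"
        )
    return values


def array_to_bytes(values, enc: ArrayEncoding) -> bytes:
    """Inverse of :func:`bytes_to_array`; float32 path rounds to float32 first."""
    with np.errstate(over="ignore"):  # float32 overflow -> inf, permitted
        arr = np.asarray(values, dtype=enc.dtype)
    raw = arr.tobytes()
    if enc.compression == "zlib" and raw:
        raw = zlib.compress(raw)
    return raw


def decode_binary_array(
    text: str, enc: ArrayEncoding, expected_count: Optional[int] = None
) -> np.ndarray:
    """Decode one ``<binary>`` payload into a numeric vector.

    Whitespace inside the base64 text is stripped (writers line-wrap).
    An empty payload decodes to an empty vector.
    """
    compact = "".join(text.split())
    try:
        raw = base64.b64decode(compact, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise DecodeError(f"invalid base64 payload: {exc}") from exc
    return bytes_to_array(raw, enc, expected_count)


def encode_binary_array(values, enc: ArrayEncoding) -> str:
    """Exact inverse of :func:`decode_binary_array` for the same encoding."""
    return base64.b64encode(array_to_bytes(values, enc)).decode("ascii")
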