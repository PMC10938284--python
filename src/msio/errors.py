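"""Exception hierarchy for msio.

Anticipated data problems raise :class:`MsioError` subclasses so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class MsioError(Exception):
    """Base class for all anticipated msio errors."""


class IndexRequiredError(MsioError):
    """File is not an indexed mzML document (no <indexListOffset> in the tail)."""


class CorruptIndexError(MsioError):
    """The spectrum byte index is present but inconsistent with the file."""


class MalformedFileError(MsioError):
    """Required structural elements or accessions are missing or contradictory."""


class UnsupportedEncodingError(MsioError):
    """A binary array declares a value type or compression this reader does not handle."""


class UnsupportedModeError(MsioError):
    """imzML document declares continuous mode; only processed mode is supported."""


class PairedFileError(MsioError):
    """The sibling .ibd binary file for an imzML document is missing."""


class CorruptLocatorError(MsioError):
    """An external-data locator points outside the ibd file."""


class MalformedPixelError(MsioError):
    """A pixel <spectrum> element lacks coordinates or a usable locator."""


class SpectrumDecodeError(MsioError):
    """Decoding one spectrum failed; carries the zero-based spectrum ordinal."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"spectrum {index}: {message}")


class DecodeError(MsioError):
    """Binary payload could not be decoded (base64, zlib, alignment or length)."""


class OutOfGridError(MsioError):
    """A pixel coordinate lies outside the declared image dimensions."""
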