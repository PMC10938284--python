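"""Forward-only byte scanner for locating XML tags without building a tree.

mzML and imzML documents are large but extremely regular, so instead of a DOM
parser the readers use a dedicated scanner: it searches a buffered byte stream
for ``<tagname`` occurrences, returns the opening tag's text, and leaves the
stream positioned just past it.  Element names in these formats are ASCII;
attribute values are decoded as UTF-8.  No validation, namespaces, or entity
expansion — by design.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import BinaryIO, Optional

from .errors import CorruptIndexError, IndexRequiredError

#: default read granularity for chunked scans
DEFAULT_CHUNK = 64 * 1024

#: default tail window searched for <indexListOffset>
DEFAULT_TAIL_WINDOW = 1024

# a tag candidate is confirmed by the byte that follows the name
_TAG_DELIMS = b" \t\r\n>/"


@dataclass(frozen=True)
class TagHit:
    """One located opening tag.

    Attributes
    ----------
    tag_name : str
        The element name that was searched for.
    start_offset : int
        0-based byte offset of the ``<`` in the underlying file.
    element_text : str
        The opening tag from ``<`` through its closing ``>``, attributes
        included (for self-closing elements this is the whole element).
    """

    tag_name: str
    start_offset: int
    element_text: str


def find_tag(
    stream: BinaryIO,
    tag_name: str,
    stop_tag: Optional[str] = None,
    chunk_size: int = DEFAULT_CHUNK,
) -> Optional[TagHit]:
    """Find the next ``<tag_name ...>`` at or after the current stream position.

    Scans forward in ``chunk_size`` blocks, keeping a small overlap so tags
    spanning block boundaries are still found.  On success the stream is left
    positioned just past the opening tag's ``>``.  If ``stop_tag`` occurs
    first, returns ``None`` with the stream positioned at the stop tag's
    ``<``.  Returns ``None`` at end of stream.
    """
    if not tag_name:
        raise ValueError("tag_name must be non-empty")
    pat = b"<" + tag_name.encode("ascii")
    stop_pat = b"<" + stop_tag.encode("ascii") if stop_tag else None
    keep = max(len(pat), len(stop_pat) if stop_pat else 0) + 1

    buf = b""
    buf_start = stream.tell()
    search_from = 0
    eof = False
    while True:
        hit = _candidate(buf, pat, search_from, eof)
        stop_hit = _candidate(buf, stop_pat, search_from, eof) if stop_pat else -1
        if hit == -2 or stop_hit == -2:
            pass  # candidate at buffer edge: need more bytes to confirm
        elif stop_hit >= 0 and (hit < 0 or stop_hit < hit):
            stream.seek(buf_start + stop_hit)
            return None
        elif hit >= 0:
            # extend the buffer until the opening tag's '>' is present
            gt = buf.find(b">", hit)
            while gt < 0 and not eof:
                chunk = stream.read(chunk_size)
                if not chunk:
                    eof = True
                    break
                buf += chunk
                gt = buf.find(b">", hit)
            if gt < 0:
                return None  # truncated tag at EOF
            element = buf[hit : gt + 1].decode("utf-8")
            stream.seek(buf_start + gt + 1)
            return TagHit(tag_name, buf_start + hit, element)
        elif eof:
            return None
        else:
            # no candidate: retain only the overlap tail
            if len(buf) > keep:
                drop = len(buf) - keep
                buf = buf[drop:]
                buf_start += drop
            search_from = 0
            chunk = stream.read(chunk_size)
            if not chunk:
                eof = True
            buf += chunk
            continue
        # reached only from the "need more bytes" branch
        chunk = stream.read(chunk_size)
        if not chunk:
            eof = True
        buf += chunk


def _candidate(buf: bytes, pat: Optional[bytes], start: int, eof: bool) -> int:
    """Index of a confirmed ``pat`` occurrence, -1 if none, -2 if undecidable."""
    if pat is None:
        return -1
    pos = start
    while True:
        idx = buf.find(pat, pos)
        if idx < 0:
            return -1
        end = idx + len(pat)
        if end >= len(buf):
            return -1 if eof else -2
        if buf[end : end + 1] in _TAG_DELIMS:
            return idx
        pos = idx + 1


_ATTR_CACHE: dict[str, re.Pattern] = {}


def read_attribute(element_text: str, attr_name: str) -> Optional[str]:
    """Extract ``attr_name="..."`` from one opening tag; ``None`` if absent.

    The value is returned exactly as written (no type coercion, no entity
    expansion).  Both quote styles are accepted.
    """
    pat = _ATTR_CACHE.get(attr_name)
    if pat is None:
        pat = re.compile(
            r"""\b%s\s*=\s*("([^"]*)"|'([^']*)')""" % re.escape(attr_name)
        )
        _ATTR_CACHE[attr_name] = pat
    m = pat.search(element_text)
    if m is None:
        return None
    return m.group(2) if m.group(2) is not None else m.group(3)


def read_tail_offset(path: str | os.PathLike, window: int = DEFAULT_TAIL_WINDOW) -> int:
    """Locate ``<indexListOffset>`` in the final ``window`` bytes of ``path``.

    Indexed mzML files carry the byte offset of their ``<indexList>`` near the
    end of the file; only that tail window is read, never the whole document.
    Returns the integer offset, which must point at a ``<indexList`` element.

    Raises
    ------
    IndexRequiredError
        if the element is absent from the tail window (non-indexed file).
    CorruptIndexError
        if the content is non-numeric, out of file bounds, or does not point
        at an ``<indexList`` element.
    """
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        fh.seek(max(0, size - window))
        tail = fh.read(window)
        m = re.search(rb"<indexListOffset>\s*([^<]*?)\s*</indexListOffset>", tail)
        if m is None:
            raise IndexRequiredError(
                f"{os.fspath(path)}: no <indexListOffset> in the final "
                f"{window} bytes; an indexed mzML file is required"
            )
        content = m.group(1)
        if not content.isdigit():
            raise CorruptIndexError(
                f"{os.fspath(path)}: non-numeric indexListOffset {content!r}"
            )
        offset = int(content)
        if offset >= size:
            raise CorruptIndexError(
                f"{os.fspath(path)}: indexListOffset {offset} is beyond "
                f"file size {size}"
            )
        fh.seek(offset)
        probe = fh.read(len(b"<indexList") + 1)
        if not probe.startswith(b"<indexList"):
            raise CorruptIndexError(
                f"{os.fspath(path)}: indexListOffset {offset} does not point "
                f"at an <indexList> element"
            )
    return offset


def read_element_block(
    stream: BinaryIO, tag_name: str, chunk_size: int = DEFAULT_CHUNK
) -> Optional[tuple[int, bytes]]:
    """Read the next whole ``<tag_name>...</tag_name>`` element as raw bytes.

    Finds the opening tag from the current position, then reads through the
    matching ``</tag_name>`` (nested same-name elements are not expected in
    mzML/imzML and not handled).  Self-closing elements are returned as-is.
    Returns ``(start_offset, element_bytes)`` or ``None`` if not found; the
    stream is left positioned just past the element.
    """
    hit = find_tag(stream, tag_name, chunk_size=chunk_size)
    if hit is None:
        return None
    opening = hit.element_text.encode("utf-8")
    if opening.endswith(b"/>"):
        return hit.start_offset, opening
    close = b"</" + tag_name.encode("ascii") + b">"
    buf = bytearray(opening)
    while True:
        idx = bytes(buf).find(close, len(opening))
        if idx >= 0:
            end = idx + len(close)
            stream.seek(hit.start_offset + end)
            return hit.start_offset, bytes(buf[:end])
        chunk = stream.read(chunk_size)
        if not chunk:
            return None
        buf += chunk
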