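"""Deterministic synthetic mzML / imzML writers with recorded ground truth.

These writers produce small but structurally complete files — indexed mzML
with a real byte-offset index, and processed-mode imzML paired with a raw
ibd stream — so every reader path can be exercised without any external
download.  Each writer returns a ground-truth record (true byte offsets,
skip distances, ibd locators) that tests use as the oracle.

The XML is built with ElementTree (never string pasting) and serialized
once; byte offsets are then patched into fixed-width placeholder fields in a
second pass, so the emitted document is always well-formed and the recorded
offsets are exact.  Attribute-length jitter and cvParam-order shuffling are
available to stress the scanner, which must not depend on either.

``corrupt`` derives deterministic broken variants for error-path tests.
"""

from __future__ import annotations

import os
import re
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .binary_codec import ArrayEncoding, array_to_bytes, encode_binary_array
from .imzml_reader import ImageDims, PixelSpectrum
from .mzml_reader import Spectrum
from .xml_scan import read_tail_offset

_OFFSET_WIDTH = 12  # zero-padded decimal placeholder width

_CV_NAMES = {
    "MS:1000514": "m/z array",
    "MS:1000515": "intensity array",
    "MS:1000521": "32-bit float",
    "MS:1000523": "64-bit float",
    "MS:1000574": "zlib compression",
    "MS:1000576": "no compression",
}
_TYPE_ACC = {"float32": "MS:1000521", "float64": "MS:1000523"}
_COMP_ACC = {"zlib": "MS:1000574", "none": "MS:1000576"}

EncodingPair = Union[ArrayEncoding, Tuple[ArrayEncoding, ArrayEncoding]]


def _enc_pair(enc: EncodingPair) -> Tuple[ArrayEncoding, ArrayEncoding]:
    if isinstance(enc, ArrayEncoding):
        return enc, enc
    return enc


# ---------------------------------------------------------------------------
# random data


def random_spectra(
    n: int, len_range: Tuple[int, int] = (5, 50), seed: int = 0
) -> List[Spectrum]:
    """Reproducible random spectra: sorted m/z in [100, 1000), intensities
    drawn from an exponential (detector-count-like, non-negative)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        mz = np.sort(rng.uniform(100.0, 1000.0, size=length))
        intensity = rng.exponential(1000.0, size=length)
        out.append(Spectrum(mz=mz, intensity=intensity))
    return out


def random_pixels(
    max_x: int,
    max_y: int,
    n_missing: int = 0,
    len_range: Tuple[int, int] = (5, 50),
    seed: int = 0,
    shuffle: bool = False,
) -> List[PixelSpectrum]:
    """Random per-pixel spectra on a grid; ``n_missing`` cells are dropped
    and ``shuffle`` randomizes the file order (pixels need not be stored in
    grid order)."""
    rng = np.random.default_rng(seed)
    coords = [(x, y) for y in range(1, max_y + 1) for x in range(1, max_x + 1)]
    if n_missing:
        keep_idx = rng.choice(len(coords), size=len(coords) - n_missing,
                              replace=False)
        coords = [coords[i] for i in sorted(keep_idx)]
    if shuffle:
        rng.shuffle(coords)
    spectra = random_spectra(len(coords), len_range, seed=int(rng.integers(2**31)))
    return [
        PixelSpectrum(x=x, y=y, mz=s.mz, intensity=s.intensity)
        for (x, y), s in zip(coords, spectra)
    ]


# ---------------------------------------------------------------------------
# mzML writer


@dataclass
class MzmlGroundTruth:
    """What the writer actually put on disk, for oracle checks."""

    path: str
    spectra: List[Spectrum]
    spectrum_offsets: List[int] = field(default_factory=list)
    index_list_offset: int = 0
    skip_bytes: List[int] = field(default_factory=list)


def _cv(parent: ET.Element, accession: str, value: str = "",
        rng: Optional[np.random.Generator] = None) -> None:
    attrs = [("cvRef", accession.split(":")[0]), ("accession", accession),
             ("name", _CV_NAMES.get(accession, accession))]
    if value != "":
        attrs.append(("value", value))
    if rng is not None:
        order = rng.permutation(len(attrs))
        attrs = [attrs[i] for i in order]
    ET.SubElement(parent, "cvParam", dict(attrs))


def write_mzml(
    spectra: Sequence[Spectrum],
    path: str | os.PathLike,
    enc: EncodingPair = ArrayEncoding("float64", "zlib"),
    axis_order: str = "mz_first",
    jitter_seed: Optional[int] = None,
) -> MzmlGroundTruth:
    """Write an indexed mzML file and return its ground truth.

    ``axis_order`` selects whether the m/z or the intensity array is the
    first ``<binaryDataArray>`` of every spectrum.  With ``jitter_seed`` the
    writer adds random-length attributes to ``<spectrum>`` elements and
    shuffles cvParam attribute order (bounded to 64 bytes so skip hints with
    their guard margin remain valid).
    """
    if axis_order not in ("mz_first", "intensity_first"):
        raise ValueError(f"bad axis_order {axis_order!r}")
    mz_enc, int_enc = _enc_pair(enc)
    rng = np.random.default_rng(jitter_seed) if jitter_seed is not None else None

    root = ET.Element("indexedmzML")
    mzml = ET.SubElement(root, "mzML", {"version": "1.1.0"})
    run = ET.SubElement(mzml, "run", {"id": "run0"})
    slist = ET.SubElement(run, "spectrumList", {"count": str(len(spectra))})
    for i, sp in enumerate(spectra):
        attrs = {
            "index": str(i),
            "id": f"scan={i}",
            "defaultArrayLength": str(len(sp)),
        }
        if rng is not None:
            attrs["comment"] = "x" * int(rng.integers(0, 64))
        spec_el = ET.SubElement(slist, "spectrum", attrs)
        bdal = ET.SubElement(spec_el, "binaryDataArrayList", {"count": "2"})
        axes = [("mz", mz_enc, sp.mz), ("intensity", int_enc, sp.intensity)]
        if axis_order == "intensity_first":
            axes.reverse()
        for role, axis_enc, values in axes:
            payload = encode_binary_array(values, axis_enc)
            bda = ET.SubElement(
                bdal, "binaryDataArray", {"encodedLength": str(len(payload))}
            )
            _cv(bda, _TYPE_ACC[axis_enc.value_type], rng=rng)
            _cv(bda, _COMP_ACC[axis_enc.compression], rng=rng)
            _cv(bda, "MS:1000514" if role == "mz" else "MS:1000515", rng=rng)
            binary = ET.SubElement(bda, "binary")
            binary.text = payload

    index_list = ET.SubElement(root, "indexList", {"count": "1"})
    index = ET.SubElement(index_list, "index", {"name": "spectrum"})
    for i in range(len(spectra)):
        off = ET.SubElement(index, "offset", {"idRef": f"scan={i}"})
        off.text = "0" * _OFFSET_WIDTH
    ilo = ET.SubElement(root, "indexListOffset")
    ilo.text = "0" * _OFFSET_WIDTH

    ET.indent(root)
    data = bytearray(
        b'<?xml version="1.0" encoding="utf-8"?>\n'
        + ET.tostring(root, encoding="utf-8", xml_declaration=False)
    )

    # second pass: patch true byte offsets into the fixed-width placeholders
    spectrum_offsets = [m.start() for m in re.finditer(rb"<spectrum\s", data)]
    assert len(spectrum_offsets) == len(spectra)
    m_idx = re.search(rb"<indexList[\s>]", data)
    index_offset = m_idx.start()
    offset_fields = list(re.finditer(rb"<offset[^>]*>(0{%d})</offset>"
                                     % _OFFSET_WIDTH, data))
    assert len(offset_fields) == len(spectra)
    for m, true_off in zip(offset_fields, spectrum_offsets):
        data[m.start(1): m.end(1)] = b"%0*d" % (_OFFSET_WIDTH, true_off)
    m_ilo = re.search(rb"<indexListOffset>(0{%d})</indexListOffset>"
                      % _OFFSET_WIDTH, data)
    data[m_ilo.start(1): m_ilo.end(1)] = b"%0*d" % (_OFFSET_WIDTH, index_offset)

    skip_bytes = [
        data.find(b"<binaryDataArrayList", off) - off for off in spectrum_offsets
    ]
    with open(path, "wb") as fh:
        fh.write(data)
    return MzmlGroundTruth(
        path=os.fspath(path),
        spectra=list(spectra),
        spectrum_offsets=spectrum_offsets,
        index_list_offset=index_offset,
        skip_bytes=skip_bytes,
    )


# ---------------------------------------------------------------------------
# imzML writer


@dataclass
class ImzmlGroundTruth:
    imzml_path: str
    ibd_path: str
    pixels: List[PixelSpectrum]
    dims: ImageDims
    locators: List[dict] = field(default_factory=list)  # per-pixel offsets


def write_imzml(
    pixels: Sequence[PixelSpectrum],
    dims: ImageDims,
    basename: str | os.PathLike,
    enc: EncodingPair = ArrayEncoding("float64", "none"),
    jitter_seed: Optional[int] = None,
) -> ImzmlGroundTruth:
    """Write a processed-mode imzML/ibd pair and return its ground truth.

    ``dims.n_spectra`` is written as the ``<spectrumList count>`` attribute
    and may deliberately differ from the grid product (missing pixels).  The
    ibd stream starts with the standard 16-byte UUID header; per-pixel
    vectors follow in file order, m/z before intensity.
    """
    mz_enc, int_enc = _enc_pair(enc)
    rng = np.random.default_rng(jitter_seed) if jitter_seed is not None else None
    basename = os.fspath(basename)
    imzml_path = basename + ".imzML"
    ibd_path = basename + ".ibd"

    uuid_rng = np.random.default_rng(
        jitter_seed if jitter_seed is not None else 0
    )
    ibd = bytearray(uuid_rng.bytes(16))
    locators: List[dict] = []
    for px in pixels:
        rec = {}
        for role, axis_enc, values in (
            ("mz", mz_enc, px.mz),
            ("intensity", int_enc, px.intensity),
        ):
            raw = array_to_bytes(values, axis_enc)
            rec[role] = {
                "offset": len(ibd),
                "count": len(values),
                "encoded_length": len(raw),
            }
            ibd += raw
        locators.append(rec)

    root = ET.Element(
        "mzML",
        {"xmlns": "http://psi.hupo.org/ms/mzml", "version": "1.1.0"},
    )
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    ET.SubElement(
        fcontent,
        "cvParam",
        {"cvRef": "IMS", "accession": "IMS:1000031", "name": "processed"},
    )
    rpgl = ET.SubElement(root, "referenceableParamGroupList", {"count": "2"})
    for gid, role, axis_enc in (
        ("mzArray", "MS:1000514", mz_enc),
        ("intensityArray", "MS:1000515", int_enc),
    ):
        grp = ET.SubElement(rpgl, "referenceableParamGroup", {"id": gid})
        _cv(grp, role, rng=rng)
        _cv(grp, _TYPE_ACC[axis_enc.value_type], rng=rng)
        _cv(grp, _COMP_ACC[axis_enc.compression], rng=rng)
    sw_list = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(sw_list, "software", {"id": "msio", "version": "0"})
    ssl = ET.SubElement(root, "scanSettingsList", {"count": "1"})
    ss = ET.SubElement(ssl, "scanSettings", {"id": "scanSettings0"})
    _cv(ss, "IMS:1000042", str(dims.max_x), rng=rng)
    _cv(ss, "IMS:1000043", str(dims.max_y), rng=rng)
    icl = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(icl, "instrumentConfiguration", {"id": "IC0"})
    dpl = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dpl, "dataProcessing", {"id": "DP0"})
    ET.SubElement(
        dp, "processingMethod", {"order": "1", "softwareRef": "msio"}
    )
    run = ET.SubElement(
        root, "run", {"id": "run0", "defaultInstrumentConfigurationRef": "IC0"}
    )
    slist = ET.SubElement(run, "spectrumList", {"count": str(dims.n_spectra)})
    for i, (px, rec) in enumerate(zip(pixels, locators)):
        attrs = {"index": str(i), "id": f"spectrum={i}"}
        if rng is not None:
            attrs["comment"] = "x" * int(rng.integers(0, 64))
        spec_el = ET.SubElement(slist, "spectrum", attrs)
        scan_list = ET.SubElement(spec_el, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "IMS:1000050", str(px.x), rng=rng)
        _cv(scan, "IMS:1000051", str(px.y), rng=rng)
        bdal = ET.SubElement(spec_el, "binaryDataArrayList", {"count": "2"})
        for gid, role in (("mzArray", "mz"), ("intensityArray", "intensity")):
            bda = ET.SubElement(bdal, "binaryDataArray")
            ET.SubElement(bda, "referenceableParamGroupRef", {"ref": gid})
            _cv(bda, "IMS:1000102", str(rec[role]["offset"]), rng=rng)
            _cv(bda, "IMS:1000103", str(rec[role]["count"]), rng=rng)
            _cv(bda, "IMS:1000104", str(rec[role]["encoded_length"]), rng=rng)
            ET.SubElement(bda, "binary")

    ET.indent(root)
    with open(imzml_path, "wb") as fh:
        fh.write(b'<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write(ET.tostring(root, encoding="utf-8", xml_declaration=False))
    with open(ibd_path, "wb") as fh:
        fh.write(bytes(ibd))
    return ImzmlGroundTruth(
        imzml_path=imzml_path,
        ibd_path=ibd_path,
        pixels=list(pixels),
        dims=dims,
        locators=locators,
    )


# ---------------------------------------------------------------------------
# deterministic corruption

_CORRUPT_MODES = ("truncate_index", "truncate_zlib", "drop_accession",
                  "locator_overrun")


def corrupt(path: str | os.PathLike, mode: str, target: int = 0) -> str:
    """Produce one named defect in an existing fixture file, in place.

    truncate_index
        cut the file at the index list, leaving no tail ``<indexListOffset>``.
    truncate_zlib
        damage the tail of spectrum ``target``'s first binary payload (the
        zlib checksum region) without changing byte lengths, so the byte
        index stays valid and inflation fails at exactly that spectrum.
    drop_accession
        blank out the first intensity-array accession cvParam, leaving a
        binary array with no axis role.
    locator_overrun
        rewrite pixel ``target``'s first external-offset accession to point
        far past the end of the ibd file.
    """
    path = os.fspath(path)
    if mode not in _CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    with open(path, "rb") as fh:
        data = bytearray(fh.read())

    if mode == "truncate_index":
        offset = read_tail_offset(path)
        data = data[:offset]
    elif mode == "truncate_zlib":
        start = _nth_spectrum(data, target)
        m = re.compile(rb"<binary>([^<]+)</binary>").search(data, start)
        if m is None:
            raise ValueError(f"spectrum {target} has no non-empty payload")
        payload = data[m.start(1): m.end(1)]
        tail = min(8, len(payload))
        data[m.end(1) - tail: m.end(1)] = b"A" * tail
    elif mode == "drop_accession":
        m = re.search(rb'<cvParam\b[^>]*accession="MS:1000515"[^>]*/>', data)
        if m is None:
            raise ValueError("no intensity-array accession to drop")
        data[m.start(): m.end()] = b" " * (m.end() - m.start())
    elif mode == "locator_overrun":
        start = _nth_spectrum(data, target)
        pat = re.compile(rb'(<cvParam\b[^>]*accession="IMS:1000102"[^>]*value=")(\d+)(")')
        m = pat.search(data, start)
        if m is None:
            raise ValueError("no external-offset accession found")
        data[m.start(2): m.end(2)] = b"999999999999"

    with open(path, "wb") as fh:
        fh.write(data)
    return path


def _nth_spectrum(data: bytes, n: int) -> int:
    hits = [m.start() for m in re.finditer(rb"<spectrum\s", data)]
    if n >= len(hits):
        raise ValueError(f"file has only {len(hits)} spectra, wanted {n}")
    return hits[n]
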