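# Methods

## Reading model

`msio` treats mzML and imzML as *regular* documents rather than general
XML: the elements it needs (`<spectrum>`, `<binaryDataArrayList>`,
`<cvParam>`, the index elements) always occur in a fixed nesting, element
names are ASCII, and the semantics of every array are carried by
controlled-vocabulary accession strings (`MS:1000514` m/z array,
`MS:1000515` intensity array, `MS:1000521`/`MS:1000523` 32/64-bit float,
`MS:1000574`/`MS:1000576` zlib/none). The scanner therefore does substring
matching of `<tagname` on a buffered byte stream (64 KiB chunks with a
small overlap so tags spanning chunk boundaries are found) and extracts
attributes with a regular expression from the single opening tag. It does
no validation, namespace handling, entity expansion, or comment/CDATA
awareness; fixture files never contain such constructs and behavior on them
is unspecified.

### Indexed access (mzML)

Only *indexed* mzML is accepted. The byte offset of the `<indexList>` is
read from `<indexListOffset>` within the final **1,024 bytes** of the file
(configurable; this window comfortably covers the closing elements and
checksum every mainstream writer emits, while guaranteeing the reader never
scans the document body for the index). A file without the tail element
raises `IndexRequiredError`; a full-scan fallback is a documented extension
point, deliberately not implemented, because silently scanning a
multi-gigabyte file is worse than a clear error.

Axis order, float width and compression are configured **once from the
first spectrum** and assumed constant across the file — in practice mzML
writers never vary them mid-file. A `strict=True` mode re-derives the
configuration for every spectrum and errors on any difference.

### Skip-byte hints

The distance from `<spectrum` to its `<binaryDataArrayList` (mzML), and the
stride between successive `<spectrum>` elements (imzML), are measured on
the first occurrence and used as *hints*: the reader seeks ahead by the
hint minus a guard margin (128 bytes in mzML, 256 in imzML) and then
re-locates the target tag by scanning. The hint therefore only saves work;
it can never change the result, provided per-spectrum attribute length
variation stays below the guard (the fixture writer's jitter mode is
bounded at 64 bytes for this reason; the equivalence of the hinted and
naive loops is asserted on randomized jittered fixtures). Reading is a
single forward pass per spectrum — the scanner never rewinds within one.

### Binary payloads

mzML payloads are base64 text (whitespace stripped before decoding, since
writers line-wrap), optionally zlib-compressed, always little-endian IEEE
floats — the byte order the standard mandates. imzML's `.ibd` stream holds
the same float runs as raw bytes after a 16-byte UUID header; each pixel's
vectors are addressed by external offset (`IMS:1000102`) and element count
(`IMS:1000103`). When arrays are zlib-compressed the on-disk byte count
differs from `count × width`, so the reader additionally honors the
external encoded length (`IMS:1000104`); for uncompressed data it is
derived. Locator cvParams are accepted anywhere inside the pixel's
`<binaryDataArray>` block, whether attached beside the
`<referenceableParamGroupRef>` or as direct cvParams — both placements
occur in the wild. Integer array types and lossy compressions are rejected
with `UnsupportedEncodingError` rather than guessed at.

Only processed-mode imzML (per-pixel m/z axes) is supported; a document
declaring continuous mode raises `UnsupportedModeError`. Pixel coordinates
stay 1-based as stored; conversion to 0-based array indices happens only
inside `get_slice`. The `<spectrumList count>` attribute is authoritative
for the number of stored pixels and may be smaller than the grid product —
missing pixels are normal and their grid cells remain 0 in ion images.

## Ion images and TrIQ

`get_slice` aggregates, per pixel, the intensities whose m/z lies in the
**closed** interval `[target − tol, target + tol]`. The default aggregate
is SUM, which is robust when a centroided peak splits into several entries
inside a narrow window; MAX is available via `agg="max"`. Closed bounds
make boundary ties deterministic.

TrIQ maps raw window intensities to display levels in two steps:

1. **Threshold.** `T` is the smallest *observed* value with
   `#{v ≤ v'} / n ≥ p` — the exact empirical quantile over the sorted
   values. Using the exact distribution rather than a binned histogram
   removes a bin-count free parameter and makes `T` minimal by
   construction.
2. **Quantization.** `[v_min, T]` is divided into `L` equal-width bins:
   `level(v) = min(L − 1, floor((min(v, T) − v_min) / (T − v_min) · L))`.
   Everything at or above `T` lands in level `L − 1`, so a single hot
   pixel cannot compress the dynamic range of the rest of the image.
   If `T == v_min` (a constant image, or `p` small enough that the minimum
   already covers it) the image is all level 0.

Defaults `L = 256`, `p = 0.95` match typical MSI display practice: one
palette entry per level of an 8-bit indexed bitmap, with the top 5 % of
intensities clipped. The level→color mapping uses the canonical 256-entry
viridis colormap (perceptually uniform; endpoints (68, 1, 84) and
(253, 231, 37)).

The BMP writer emits the classic byte layout — BITMAPFILEHEADER,
BITMAPINFOHEADER, 256-entry BGRA table, bottom-up rows padded to 4-byte
multiples — with the pixel byte equal to the quantization level, so an
independent image reader recovers both levels and palette exactly. Matrix
row 1 appears at the top of the rendered image; the bottom-up storage is
handled internally.

## Synthetic data

`fixture_gen` writes structurally complete files: indexed mzML with a true
byte-offset index (built with an XML emitter, then exact offsets patched
into fixed-width decimal placeholders in a second pass), and processed
imzML/ibd pairs carrying the full accession vocabulary, a UUID'd ibd
stream, and enough standard skeleton that third-party imzML readers parse
them unchanged. Identical inputs and seeds give byte-identical files.

Random spectra have sorted uniform m/z in [100, 1000) and exponential
intensities (detector-count-like, non-negative), with per-spectrum lengths
drawn uniformly from a configurable range (default 5–50 points; the test
and acceptance runs use 0–60, deliberately including empty spectra). These
emulate the *storage* properties of real data — axis ordering, encodings,
compression, index structure, pixel grids with gaps — not its chemistry:
there are no isotope patterns, peak shapes, or spatial correlation. Passing
tests therefore certify faithful decoding and deterministic imaging
arithmetic, not analytical performance on real samples.

`corrupt` produces one targeted defect per mode: cutting the file at the
index (`truncate_index`), damaging the checksum tail of one spectrum's zlib
payload in place so byte offsets stay valid (`truncate_zlib`), blanking an
axis-role accession (`drop_accession`), or pointing one pixel's external
offset past the end of the ibd (`locator_overrun`). Each must raise exactly
its targeted error class, carrying the spectrum/pixel ordinal where one
exists.

## Verification scale

The randomized verification runs use 50 mzML files, 50 imzML fixtures,
1,000 random TrIQ matrices and 16 bitmap shapes — sizes at which every
encoding combination and structural variant appears several times while the
whole suite runs in seconds. Reference MSI data sets published alongside
the original readers (tens of thousands of pixels) load with the same code
paths; a test checks their documented pixel counts when the files are
present locally.

## Known limitations

- No chromatogram (`<chromatogramList>`) parsing, MS-level filtering,
  retention-time extraction, or precursor metadata.
- No continuous-mode imzML, 3-D coordinates, numpress, or integer arrays.
- Non-indexed mzML is rejected, not scanned.
- Skip hints assume per-spectrum attribute variation below the guard
  margin; pathological writers would still be read correctly only by the
  naive loop.
- No peak picking, alignment, normalization or plotting — the library ends
  where spectra and images are in memory.
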