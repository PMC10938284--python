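# msio

Mass spectrometry produces large files in two open HUPO-PSI standards:
**mzML** (XML with base64-encoded, optionally zlib-compressed binary arrays,
plus a byte-offset index for random spectrum access) for LC-MS and
direct-infusion runs, and **imzML** (an XML metadata file paired with a raw
binary `.ibd` stream) for mass spectrometry imaging (MSI). `msio` reads both
— indexed mzML and *processed-mode* imzML — into plain NumPy-backed
structures, and provides the small set of downstream operations those data
feed:

- **BPC / TIC** — base-peak (per-scan maximum intensity) and total-ion
  (per-scan summed intensity) chromatograms,
- **ion-image slicing** — per pixel, the summed (or maximum) intensity whose
  m/z falls in a closed window `[mz − tol, mz + tol]`,
- **TrIQ** (Threshold Intensity Quantization) — contrast optimization that
  caps intensities at the smallest observed value `T` with
  `#{v ≤ T}/n ≥ p`, then quantizes `[v_min, T]` into `L` equal-width levels,
- **indexed-bitmap export** — byte-exact 8-bit indexed Windows BMP with a
  256-entry palette (viridis by default), plus PNG convenience output.

The readers use a dedicated forward-only byte scanner rather than a DOM
parser: spectrum positions come from the file's own byte index, per-axis
decoding (m/z vs intensity role, float width, compression, array order) is
configured once from the first spectrum, and skip-byte hints jump the
scanner close to each next landmark before re-verifying it — so reading is a
single pass per spectrum. A deterministic fixture writer
(`msio.fixture_gen`) emits valid mzML and imzML/ibd pairs with recorded
ground truth, so the whole stack is testable offline.

It is intended for people writing their own MS processing workflows —
ambient-ionization and MSI work in particular — who need fast, scriptable
raw-data access rather than a vendor GUI.

## Worked example

```python
import msio
from msio import fixture_gen
from msio.imzml_reader import ImageDims

# write a synthetic 4 x 3 imaging data set (or point at your own .imzML)
pixels = fixture_gen.random_pixels(4, 3, seed=2)
gt = fixture_gen.write_imzml(pixels, ImageDims(4, 3, 12), "demo")

pixels, dims = msio.load_imzml("demo.imzML")
print(dims)
# ImageDims(max_x=4, max_y=3, n_spectra=12)

sliced = msio.get_slice(pixels, dims, target_mz=550.0, tol=50.0)
quant = msio.triq(sliced, 256, 0.95)
print(round(quant.threshold, 2), quant.levels.min(), quant.levels.max())
# 6261.34 0 255
msio.save_bitmap(quant, "demo.bmp", msio.viridis_palette())
```

`ImageDims(max_x=4, max_y=3, n_spectra=12)` says the grid is 4 columns by
3 rows with all 12 pixel spectra stored (files may legitimately store
fewer). The TrIQ threshold `6261.34` is the intensity above which values
are clipped before quantization: 95 % of the window intensities lie at or
below it, so a single hot pixel cannot wash out the contrast of the
exported image. Levels span the full 0–255 palette range.

The same pipeline from a shell:

```sh
msio info demo.imzML
msio image demo.imzML --mz 550.0 --tol 50 --levels 256 --prob 0.95 -o demo.bmp
msio bpc run.mzML -o bpc.csv        # base-peak chromatogram of an mzML run
```

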