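import pytest

from msio.binary_codec import ArrayEncoding
from msio.imzml_reader import ImageDims
from msio import fixture_gen as fg


@pytest.fixture
def mzml_file(tmp_path):
    """Factory: write a random indexed mzML fixture, return its ground truth."""

    def make(n=5, enc=ArrayEncoding("float64", "zlib"), axis_order="mz_first",
             seed=0, len_range=(5, 40), jitter_seed=None, name="fix.mzML"):
        spectra = fg.random_spectra(n, len_range, seed=seed)
        return fg.write_mzml(spectra, tmp_path / name, enc=enc,
                             axis_order=axis_order, jitter_seed=jitter_seed)

    return make


@pytest.fixture
def imzml_file(tmp_path):
    """Factory: write a random processed imzML/ibd fixture pair."""

    def make(max_x=4, max_y=3, n_missing=0, enc=ArrayEncoding("float64", "none"),
             seed=0, shuffle=False, jitter_seed=None, name="img",
             declared_count=None):
        pixels = fg.random_pixels(max_x, max_y, n_missing=n_missing,
                                  seed=seed, shuffle=shuffle)
        dims = ImageDims(max_x, max_y,
                         declared_count if declared_count is not None
                         else len(pixels))
        return fg.write_imzml(pixels, dims, tmp_path / name, enc=enc,
                              jitter_seed=jitter_seed)

    return make
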