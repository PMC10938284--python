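import math

import numpy as np
import pytest
from PIL import Image

from msio.errors import MsioError, OutOfGridError
from msio.imaging import (
    IonImage,
    bpc,
    get_slice,
    save_bitmap,
    save_png,
    tic,
    triq,
    triq_threshold,
    viridis_palette,
    write_chromatogram_csv,
)
from msio.imzml_reader import ImageDims, PixelSpectrum
from msio.mzml_reader import Spectrum


def px(x, y, mz, inten):
    return PixelSpectrum(x, y, np.asarray(mz, float), np.asarray(inten, float))


# ---------------------------------------------------------------------------
# brute-force oracles, kept independent of the implementation


def slice_oracle(pixels, dims, target, tol, agg="sum"):
    img = [[0.0] * dims.max_x for _ in range(dims.max_y)]
    for p in pixels:
        hits = [float(i) for m, i in zip(p.mz, p.intensity)
                if target - tol <= m <= target + tol]
        if hits:
            if agg == "sum":
                img[p.y - 1][p.x - 1] += sum(hits)
            else:
                img[p.y - 1][p.x - 1] = max(img[p.y - 1][p.x - 1], max(hits))
    return np.array(img)


def triq_oracle(values, L, p):
    flat = sorted(float(v) for v in np.ravel(values))
    n = len(flat)
    T = next(v for v in flat
             if sum(1 for u in flat if u <= v) / n >= p)
    v_min = flat[0]
    levels = []
    for v in np.ravel(values):
        if T == v_min:
            levels.append(0)
        else:
            levels.append(min(L - 1, math.floor((min(v, T) - v_min)
                                                / (T - v_min) * L)))
    return T, np.array(levels).reshape(np.shape(values))


class TestGetSlice:
    def test_single_pixel_closed_window(self):
        # window [885.545, 885.555] contains 885.548 only -> value 5
        pixels = [px(1, 1, [885.548, 885.556, 900.0], [5, 7, 100])]
        img = get_slice(pixels, ImageDims(1, 1, 1), 885.55, 0.005)
        assert img.values[0, 0] == 5.0

    def test_window_spanning_everything_gives_total_ion_sums(self):
        pixels = [px(1, 1, [100, 200], [3, 4]), px(2, 1, [500], [9])]
        img = get_slice(pixels, ImageDims(2, 1, 2), 500.0, 1000.0)
        assert img.values.tolist() == [[7.0, 9.0]]

    def test_window_outside_all_mz_gives_zero_image(self):
        pixels = [px(1, 1, [100, 200], [3, 4])]
        img = get_slice(pixels, ImageDims(2, 2, 1), 5000.0, 0.5)
        assert not img.values.any()

    def test_absent_grid_cells_stay_zero(self):
        pixels = [px(2, 2, [100.0], [8.0])]
        img = get_slice(pixels, ImageDims(3, 3, 1), 100.0, 1.0)
        assert img.values.sum() == 8.0 and img.values[1, 1] == 8.0

    @pytest.mark.parametrize("agg", ["sum", "max"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_interval_oracle(self, seed, agg):
        rng = np.random.default_rng(seed)
        dims = ImageDims(4, 3, 12)
        pixels = [
            px(x, y, np.sort(rng.uniform(100, 110, 30)),
               rng.exponential(50, 30))
            for y in range(1, 4) for x in range(1, 5)
        ]
        target, tol = 105.0, float(rng.uniform(0.1, 3.0))
        got = get_slice(pixels, dims, target, tol, agg=agg)
        np.testing.assert_allclose(
            got.values, slice_oracle(pixels, dims, target, tol, agg)
        )

    def test_additivity_over_disjoint_windows(self):
        rng = np.random.default_rng(3)
        dims = ImageDims(3, 2, 6)
        pixels = [px(x, y, np.sort(rng.uniform(100, 120, 40)),
                     rng.exponential(10, 40))
                  for y in (1, 2) for x in (1, 2, 3)]
        a = get_slice(pixels, dims, 102.5, 2.5).values
        b = get_slice(pixels, dims, 112.5, 2.49999).values
        union = get_slice(pixels, dims, 107.5, 7.5).values
        # windows A=[100,105], B=[110.00001,114.99998] disjoint; union covers both
        extra = get_slice(pixels, dims, 107.5, 2.49999).values
        np.testing.assert_allclose(a + b + extra, union, rtol=1e-12)

    def test_out_of_grid_pixel_raises(self):
        with pytest.raises(OutOfGridError):
            get_slice([px(5, 1, [100.0], [1.0])], ImageDims(2, 2, 1),
                      100.0, 1.0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            get_slice([], ImageDims(1, 1, 1), 100.0, 0.0)


class TestTriq:
    def test_constant_image_maps_to_all_zeros(self):
        q = triq(np.full((4, 4), 7.0), 256, 0.95)
        assert not q.levels.any()
        assert q.threshold == 7.0

    def test_three_by_three_ramp_two_levels(self):
        # frozen from the brute-force formula: T=8, bin edge at 4
        values = np.arange(9.0).reshape(3, 3)
        q = triq(values, 2, 1.0)
        assert q.threshold == 8.0
        assert q.levels.tolist() == [[0, 0, 0], [0, 1, 1], [1, 1, 1]]

    def test_single_outlier_is_clipped_not_dominant(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 10, (20, 20))
        values[0, 0] = 1e6
        q = triq(values, 256, 0.95)
        assert q.levels[0, 0] == 255
        assert q.threshold < 1e6
        frac = (values <= q.threshold).mean()
        assert frac >= 0.95

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.exponential(100, (8, 9))
        L = int(rng.integers(2, 300))
        p = float(rng.uniform(0.5, 1.0))
        T, levels = triq_oracle(values, L, p)
        q = triq(values, L, p)
        assert q.threshold == T
        np.testing.assert_array_equal(q.levels, levels)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariants_range_monotone_coverage_minimality(self, seed):
        rng = np.random.default_rng(100 + seed)
        values = rng.exponential(50, (10, 10))
        L, p = 256, 0.9
        q = triq(values, L, p)
        flat_v, flat_l = values.ravel(), q.levels.ravel()
        assert flat_l.min() >= 0 and flat_l.max() == L - 1
        order = np.argsort(flat_v, kind="stable")
        assert (np.diff(flat_l[order]) >= 0).all()  # monotone mapping
        n = flat_v.size
        assert (flat_v <= q.threshold).sum() / n >= p
        smaller = flat_v[flat_v < q.threshold]
        if smaller.size:  # minimality: no smaller observed value suffices
            assert (flat_v <= smaller.max()).sum() / n < p

    def test_threshold_is_exact_empirical_quantile(self):
        values = np.array([1.0, 2.0, 2.0, 3.0, 10.0])
        assert triq_threshold(values, 0.8) == 3.0
        assert triq_threshold(values, 1.0) == 10.0
        assert triq_threshold(values, 0.2) == 1.0

    def test_parameter_validation(self):
        img = np.zeros((2, 2))
        with pytest.raises(ValueError):
            triq(img, 1, 0.95)
        with pytest.raises(ValueError):
            triq(img, 256, 0.0)
        with pytest.raises(ValueError):
            triq(img, 256, 1.5)

    def test_accepts_ion_image_wrapper(self):
        img = IonImage(np.arange(4.0).reshape(2, 2), 100.0, 0.1)
        assert triq(img, 4, 1.0).levels.shape == (2, 2)


class TestChromatograms:
    def test_bpc_and_tic_forced_examples(self):
        spectra = [
            Spectrum(np.array([100.0, 200.0]), np.array([5.0, 9.0])),
            Spectrum(np.array([100.0]), np.array([2.0])),
        ]
        assert bpc(spectra).tolist() == [9.0, 2.0]
        assert tic(spectra).tolist() == [14.0, 2.0]

    def test_empty_set_and_empty_spectrum(self):
        assert bpc([]).size == 0 and tic([]).size == 0
        empty = Spectrum(np.array([]), np.array([]))
        assert bpc([empty]).tolist() == [0.0]
        assert tic([empty]).tolist() == [0.0]

    def test_csv_export_layout(self, tmp_path):
        out = tmp_path / "bpc.csv"
        write_chromatogram_csv([3.5, 7.0], out)
        lines = out.read_text().splitlines()
        assert lines[0] == "scan,value"
        assert lines[1:] == ["0,3.5", "1,7"]
        assert all(len(l.split(",")) == 2 for l in lines)


class TestPalette:
    def test_viridis_endpoints_and_length(self):
        pal = viridis_palette()
        assert len(pal) == 256
        assert pal[0] == (68, 1, 84)
        assert pal[255] == (253, 231, 37)
        assert all(0 <= c <= 255 for rgb in pal for c in rgb)


class TestSaveBitmap:
    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 7])
    def test_pillow_round_trip_recovers_levels_and_palette(self, tmp_path, width):
        rng = np.random.default_rng(width)
        levels = rng.integers(0, 256, size=(3, width)).astype(np.uint16)
        pal = viridis_palette()
        path = tmp_path / f"w{width}.bmp"
        save_bitmap(levels, path, pal)
        with Image.open(path) as img:
            assert img.size == (width, 3)
            decoded = np.array(img)
            rgb = np.array(img.convert("RGB"))
        np.testing.assert_array_equal(decoded, levels)
        for (r, g, b), lev in zip(rgb.reshape(-1, 3), levels.ravel()):
            assert (r, g, b) == pal[lev]

    def test_row_stride_padded_to_four_bytes(self, tmp_path):
        path = tmp_path / "pad.bmp"
        save_bitmap(np.zeros((2, 3), np.uint16), path)
        size = path.stat().st_size
        assert size == 14 + 40 + 256 * 4 + 2 * 4  # stride 4 for width 3

    def test_single_pixel_level_zero(self, tmp_path):
        pal = viridis_palette()
        path = tmp_path / "one.bmp"
        save_bitmap(np.zeros((1, 1), np.uint16), path, pal)
        with Image.open(path) as img:
            assert img.convert("RGB").getpixel((0, 0)) == pal[0]

    def test_row_one_is_top_of_rendered_image(self, tmp_path):
        levels = np.array([[10, 10], [200, 200]], dtype=np.uint16)
        path = tmp_path / "orient.bmp"
        save_bitmap(levels, path)
        with Image.open(path) as img:
            arr = np.array(img)
        np.testing.assert_array_equal(arr, levels)

    def test_levels_above_255_rejected(self, tmp_path):
        with pytest.raises(MsioError):
            save_bitmap(np.full((2, 2), 300, np.uint16), tmp_path / "x.bmp")

    def test_png_export_same_pixels(self, tmp_path):
        levels = np.arange(6, dtype=np.uint16).reshape(2, 3) * 40
        path = tmp_path / "p.png"
        save_png(levels, path)
        with Image.open(path) as img:
            np.testing.assert_array_equal(np.array(img), levels)
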