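"""ENVI round trips, NDVI arithmetic, segmentation, mean-spectrum extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafchem.exceptions import ConfigurationError, EmptySegmentationError, FormatError
from leafchem.imaging import (
    HyperspectralCube,
    LeafMask,
    NDVIMap,
    extract_mean_spectrum,
    ndvi_map,
    read_envi_cube,
    segment_leaf,
    write_envi_cube,
)
from leafchem.synthetic_data import default_baseline, generate_cube


def _random_cube(seed=0, shape=(9, 7, 12)):
    rng = np.random.default_rng(seed)
    wl = np.linspace(400, 1000, shape[2])
    return HyperspectralCube(rng.uniform(0, 1, size=shape), wl)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype", [np.float32, np.float64])
    def test_round_trip_lossless(self, tmp_path, interleave, dtype):
        cube = _random_cube(3)
        cube.reflectance = cube.reflectance.astype(dtype).astype(float)
        hdr = tmp_path / f"cube_{interleave}.hdr"
        write_envi_cube(cube, hdr, interleave=interleave, dtype=dtype)
        back = read_envi_cube(hdr)
        np.testing.assert_array_equal(back.reflectance, cube.reflectance)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_generator_cube_shape_preserved(self, tmp_path):
        wl = np.linspace(400, 1000, 300)
        cube, _ = generate_cube(default_baseline(wl), wl, shape=(32, 32), seed=0)
        hdr = tmp_path / "leaf.hdr"
        write_envi_cube(cube, hdr)
        assert read_envi_cube(hdr).shape == (32, 32, 300)

    def test_header_without_wavelengths_rejected(self, tmp_path):
        cube = _random_cube()
        hdr = tmp_path / "c.hdr"
        write_envi_cube(cube, hdr)
        text = "\n".join(l for l in hdr.read_text().splitlines()
                         if not l.startswith("wavelength ="))
        hdr.write_text(text)
        with pytest.raises(FormatError):
            read_envi_cube(hdr)

    def test_size_mismatch_rejected(self, tmp_path):
        cube = _random_cube()
        hdr = tmp_path / "c.hdr"
        data = write_envi_cube(cube, hdr)
        data.write_bytes(data.read_bytes()[:-16])
        with pytest.raises(FormatError):
            read_envi_cube(hdr)

    def test_missing_header_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_envi_cube(tmp_path / "absent.hdr")


class TestNDVI:
    def test_equal_bands_give_zero(self):
        cube = HyperspectralCube(np.full((2, 2, 2), 0.3), np.array([660.0, 780.0]))
        assert np.all(ndvi_map(cube).values == 0.0)

    @pytest.mark.parametrize(
        "nir,red,expected", [(0.5, 0.1, 0.4 / 0.6), (0.1, 0.5, -0.4 / 0.6)]
    )
    def test_hand_computed_values(self, nir, red, expected):
        arr = np.zeros((1, 1, 2))
        arr[0, 0] = [red, nir]
        cube = HyperspectralCube(arr, np.array([660.0, 780.0]))
        assert ndvi_map(cube).values[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_dark_pixels_defined_as_zero(self):
        arr = np.zeros((1, 2, 2))
        arr[0, 1] = [0.2, 0.6]
        cube = HyperspectralCube(arr, np.array([660.0, 780.0]))
        values = ndvi_map(cube).values
        assert values[0, 0] == 0.0 and values[0, 1] == pytest.approx(0.5)

    def test_single_band_rejected(self):
        cube = HyperspectralCube(np.full((2, 2, 1), 0.3), np.array([660.0]))
        with pytest.raises(ConfigurationError):
            ndvi_map(cube)

    def test_off_grid_wavelength_warns(self):
        cube = _random_cube(shape=(3, 3, 5))
        cube.wavelengths = np.linspace(500, 700, 5)
        with pytest.warns(UserWarning):
            ndvi_map(cube)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_bounded_for_nonnegative_reflectance(self, seed):
        cube = _random_cube(seed, shape=(4, 4, 6))
        values = ndvi_map(cube).values
        assert np.all(values >= -1.0) and np.all(values <= 1.0)


class TestSegmentation:
    def test_noise_free_generator_cube_recovers_true_mask(self):
        wl = np.linspace(400, 1000, 40)
        cube, truth = generate_cube(default_baseline(wl), wl, (20, 20), noise_sd=0.0)
        mask = segment_leaf(ndvi_map(cube))
        np.testing.assert_array_equal(mask.keep, truth)

    def test_threshold_one_empties_mask(self):
        cube = _random_cube()
        assert segment_leaf(ndvi_map(cube), threshold=1.0).n_pixels == 0

    def test_all_background_scene_yields_empty_mask(self):
        wl = np.linspace(400, 1000, 20)
        from leafchem.synthetic_data import background_spectrum

        arr = np.broadcast_to(background_spectrum(wl), (8, 8, 20)).copy()
        mask = segment_leaf(ndvi_map(HyperspectralCube(arr, wl)))
        assert mask.n_pixels == 0

    @given(st.floats(-1, 1), st.floats(-1, 1), st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, t2, seed):
        lo, hi = sorted((t1, t2))
        ndvi = NDVIMap(np.random.default_rng(seed).uniform(-1, 1, (6, 6)), 1, 0)
        assert segment_leaf(ndvi, hi).n_pixels <= segment_leaf(ndvi, lo).n_pixels

    def test_mask_ascii_export(self, tmp_path):
        mask = LeafMask(np.array([[True, False], [False, True]]))
        path = tmp_path / "mask.txt"
        mask.to_ascii(path)
        assert path.read_text() == "10\n01\n"


class TestMeanSpectrum:
    def test_uniform_cube_identity(self):
        wl = np.linspace(400, 1000, 10)
        spectrum = np.linspace(0.1, 0.5, 10)
        arr = np.broadcast_to(spectrum, (4, 4, 10)).copy()
        cube = HyperspectralCube(arr, wl)
        mask = LeafMask(np.ones((4, 4), bool))
        np.testing.assert_allclose(extract_mean_spectrum(cube, mask), spectrum)

    def test_two_pixel_average(self):
        wl = np.array([500.0, 600.0])
        arr = np.zeros((1, 2, 2))
        arr[0, 0] = [0.2, 0.4]
        arr[0, 1] = [0.6, 0.8]
        cube = HyperspectralCube(arr, wl)
        mask = LeafMask(np.ones((1, 2), bool))
        np.testing.assert_allclose(extract_mean_spectrum(cube, mask), [0.4, 0.6])

    def test_empty_mask_raises(self):
        cube = _random_cube()
        with pytest.raises(EmptySegmentationError):
            extract_mean_spectrum(cube, LeafMask(np.zeros(cube.shape[:2], bool)))

    def test_disjoint_masks_combine_linearly(self):
        cube = _random_cube(8)
        rng = np.random.default_rng(1)
        keep = rng.uniform(size=cube.shape[:2]) < 0.5
        a = LeafMask(keep & (rng.uniform(size=keep.shape) < 0.5))
        b = LeafMask(keep & ~a.keep)
        combined = LeafMask(a.keep | b.keep)
        expected = (
            a.n_pixels * extract_mean_spectrum(cube, a)
            + b.n_pixels * extract_mean_spectrum(cube, b)
        ) / combined.n_pixels
        np.testing.assert_allclose(
            extract_mean_spectrum(cube, combined), expected, atol=1e-12
        )

    def test_noise_free_pipeline_recovers_leaf_spectrum(self):
        wl = np.linspace(400, 1000, 30)
        spectrum = default_baseline(wl)
        cube, _ = generate_cube(spectrum, wl, (16, 16), noise_sd=0.0)
        mask = segment_leaf(ndvi_map(cube))
        np.testing.assert_allclose(
            extract_mean_spectrum(cube, mask), spectrum, atol=1e-12
        )
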