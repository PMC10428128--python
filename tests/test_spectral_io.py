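"""IO and conditioning of hyperspectral images."""

import numpy as np
import pytest

from conegain import spectral_io as sio
from conegain.spectra import SpectralImage


def _toy_image(h=8, w=6, bands=None, seed=0):
    wl = bands if bands is not None else np.arange(400.0, 721.0, 10.0)
    rng = np.random.default_rng(seed)
    return SpectralImage(rng.uniform(0.1, 2.0, size=(h, w, wl.size)), wl,
                         {"scene_id": "toy"})


class TestReadersWriters:
    def test_h5_roundtrip_bit_identical(self, tmp_path):
        img = _toy_image()
        img.values = img.values.astype(np.float32).astype(float)  # storable
        path = tmp_path / "scene.h5"
        sio.write_hyperspectral(img, path)
        back = sio.read_hyperspectral(path)
        assert np.array_equal(back.values, img.values)
        assert np.array_equal(back.wavelengths, img.wavelengths)
        assert back.metadata["scene_id"] == "toy"

    def test_non_monotone_wavelengths_rejected(self, tmp_path):
        import h5py
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("radiance", data=np.ones((2, 2, 3), np.float32))
            f.create_dataset("wavelengths_nm", data=[500.0, 400.0, 600.0])
        with pytest.raises(ValueError):
            sio.read_hyperspectral(path)

    def test_envi_cube_33_bands(self, tmp_path):
        # 33 bands labelled 400-720 nm at 10-nm steps, BSQ float32.
        wl = np.arange(400.0, 721.0, 10.0)
        cube = np.random.default_rng(1).uniform(0, 1, (5, 4, 33)).astype(np.float32)
        (tmp_path / "scene.raw").write_bytes(
            np.transpose(cube, (2, 0, 1)).tobytes())
        (tmp_path / "scene.hdr").write_text(
            "ENVI\nsamples = 4\nlines = 5\nbands = 33\ndata type = 4\n"
            "interleave = bsq\nwavelength = {" + ", ".join(
                f"{v:.1f}" for v in wl) + "}\n")
        img = sio.read_hyperspectral(tmp_path / "scene.raw")
        assert img.wavelengths.size == 33
        assert np.allclose(np.diff(img.wavelengths), 10.0)
        assert np.allclose(img.values, cube, atol=1e-6)

    def test_envi_without_wavelengths_fatal(self, tmp_path):
        (tmp_path / "s.raw").write_bytes(np.zeros(8, np.float32).tobytes())
        (tmp_path / "s.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 2\ndata type = 4\n"
            "interleave = bsq\n")
        with pytest.raises(ValueError, match="wavelength"):
            sio.read_hyperspectral(tmp_path / "s.raw")

    def test_mat_v73_cube(self, tmp_path):
        import h5py
        wl = np.arange(400.0, 701.0, 10.0)
        cube = np.random.default_rng(2).uniform(0, 1, (wl.size, 6, 5))
        path = tmp_path / "scene.mat"
        with h5py.File(path, "w") as f:
            f.create_dataset("rad", data=cube)
            f.create_dataset("wavelengths", data=wl)
        img = sio.read_hyperspectral(path)
        assert img.shape == (6, 5, wl.size)


class TestResampling:
    def test_identity_grid_unchanged(self):
        img = _toy_image()
        out = sio.resample_wavelengths(img, img.wavelengths)
        assert np.allclose(out.values, img.values)

    def test_downsample_400_1000_to_31_bands(self):
        src = np.arange(400.0, 1001.0, 5.0)
        img = _toy_image(bands=src)
        grid = np.arange(400.0, 701.0, 10.0)
        out = sio.resample_wavelengths(img, grid)
        assert out.values.shape[2] == 31

    def test_constant_spectrum_exact(self):
        wl = np.arange(400.0, 721.0, 10.0)
        img = SpectralImage(np.full((3, 3, wl.size), 1.7), wl)
        out = sio.resample_wavelengths(img, np.arange(405.0, 700.0, 7.0))
        assert np.allclose(out.values, 1.7)

    def test_extrapolation_refused(self):
        img = _toy_image()
        with pytest.raises(ValueError):
            sio.resample_wavelengths(img, np.arange(390.0, 700.0, 10.0))


class TestDownsample2x2:
    def test_uniform_image(self):
        wl = np.arange(400.0, 721.0, 10.0)
        img = SpectralImage(np.full((4, 4, wl.size), 2.5), wl)
        out = sio.downsample_2x2(img)
        assert out.shape == (2, 2, wl.size)
        assert np.allclose(out.values, 2.5)

    def test_block_mean_definition(self):
        wl = np.array([500.0, 510.0])
        vals = np.zeros((2, 2, 2))
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            vals[i // 2, i % 2] = v
        out = sio.downsample_2x2(SpectralImage(vals, wl))
        assert np.allclose(out.values, 2.5)

    def test_checkerboard_against_bruteforce(self, rng):
        wl = np.arange(400.0, 721.0, 10.0)
        a = rng.uniform(0, 1, wl.size)
        b = rng.uniform(0, 1, wl.size)
        vals = np.empty((6, 6, wl.size))
        for i in range(6):
            for j in range(6):
                vals[i, j] = a if (i + j) % 2 == 0 else b
        out = sio.downsample_2x2(SpectralImage(vals, wl))
        assert np.allclose(out.values, (a + b) / 2.0)

    def test_odd_trailing_dropped_and_mean_preserved(self):
        img = _toy_image(h=6, w=8)
        out = sio.downsample_2x2(img)
        assert out.shape[:2] == (3, 4)
        assert np.allclose(out.values.mean(axis=(0, 1)),
                           img.values.mean(axis=(0, 1)))


class TestDarkOffset:
    def test_zero_offset_identity(self):
        img = _toy_image()
        out = sio.subtract_dark_offset(img, np.zeros(img.wavelengths.size))
        assert np.allclose(out.values, img.values)

    def test_per_band_minimum_goes_to_zero(self):
        img = _toy_image()
        mins = img.values.min(axis=(0, 1))
        out = sio.subtract_dark_offset(img, mins)
        assert np.allclose(out.values.min(axis=(0, 1)), 0.0)

    def test_known_additive_constant_recovered(self):
        img = _toy_image()
        shifted = SpectralImage(img.values + 0.25, img.wavelengths)
        out = sio.subtract_dark_offset(shifted, np.full(img.wavelengths.size,
                                                        0.25))
        assert np.allclose(out.values, img.values)

    def test_suspicious_offset_refused(self):
        img = _toy_image()
        big = np.full(img.wavelengths.size, 100.0)
        with pytest.raises(ValueError):
            sio.subtract_dark_offset(img, big)
        forced = sio.subtract_dark_offset(img, big, force=True)
        assert np.all(forced.values == 0.0)


class TestSampling:
    def test_full_draw_without_replacement_is_permutation(self):
        img = _toy_image(h=4, w=4)
        s = sio.sample_spectra(img, 16, seed=0, replace=False)
        assert sorted(s.provenance["pixel_index"]) == list(range(16))

    def test_draw_counts_and_determinism(self, small_scene):
        a = sio.sample_spectra(small_scene, 1000, seed=5)
        b = sio.sample_spectra(small_scene, 1000, seed=5)
        c = sio.sample_spectra(small_scene, 1000, seed=6)
        assert len(a) == 1000
        assert np.array_equal(a.spectra, b.spectra)
        assert not np.array_equal(a.provenance["pixel_index"],
                                  c.provenance["pixel_index"])

    def test_invalid_counts(self):
        img = _toy_image(h=2, w=2)
        with pytest.raises(ValueError):
            sio.sample_spectra(img, 0)
        with pytest.raises(ValueError):
            sio.sample_spectra(img, 5, replace=False)


class TestCropUpperHalf:
    def test_row_convention(self):
        wl = np.array([500.0, 510.0])
        vals = np.arange(100)[:, None, None] * np.ones((1, 3, 2))
        out = sio.crop_upper_half(SpectralImage(vals, wl))
        # 100-row image: rows 50..99 retained (row 0 = top).
        assert out.values.shape[0] == 50
        assert out.values[0, 0, 0] == 50.0

    def test_sky_removed(self):
        wl = np.arange(400.0, 721.0, 10.0)
        sky = np.linspace(2.0, 3.0, wl.size)
        ground = np.linspace(0.5, 0.2, wl.size)
        vals = np.empty((10, 4, wl.size))
        vals[:5] = sky
        vals[5:] = ground
        out = sio.crop_upper_half(SpectralImage(vals, wl))
        assert not np.any(np.all(np.isclose(
            out.values.reshape(-1, wl.size), sky), axis=1))

    def test_single_row_refused(self):
        wl = np.array([500.0, 510.0])
        with pytest.raises(ValueError):
            sio.crop_upper_half(SpectralImage(np.ones((1, 3, 2)), wl))
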