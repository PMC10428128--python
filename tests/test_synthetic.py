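"""Synthetic scene/palette generator: calibration and contracts."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import entropy

from conegain import colorimetry as cm
from conegain import synthetic as syn


VC = cm.ViewingConditions.from_cct(6500.0)


def _shares_and_axis(img):
    ucs = cm.set_to_ucs(img.flatten(), VC)
    var = ucs.var(axis=0)
    shares = var / var.sum()
    return shares, cm.major_chromatic_axis(ucs).phi, ucs


class TestDaylight:
    def test_normalized_at_560(self):
        sp = syn.daylight_spectrum(6500.0, np.arange(400.0, 725.0, 10.0))
        assert np.interp(560.0, sp.wavelengths, sp.values) == pytest.approx(
            100.0)

    def test_bluer_at_higher_cct(self):
        grid = np.arange(400.0, 725.0, 10.0)
        ratio = lambda sp: (np.interp(450.0, grid, sp.values)
                            / np.interp(650.0, grid, sp.values))
        assert ratio(syn.daylight_spectrum(10_000.0, grid)) > \
            ratio(syn.daylight_spectrum(6500.0, grid))

    def test_cct_range_enforced(self):
        with pytest.raises(ValueError):
            syn.daylight_spectrum(3000.0, np.arange(400.0, 725.0, 10.0))


class TestReflectanceBasis:
    def test_constant_first_function(self):
        grid = np.arange(400.0, 725.0, 10.0)
        basis = syn.gaussian_reflectance_basis(grid)
        w = np.zeros(basis.shape[0])
        w[0] = 1.0
        sp = syn.reflectance_from_basis(w, basis, grid)
        assert np.allclose(sp.values, 0.5)

    def test_clipping_with_warning(self, caplog):
        grid = np.arange(400.0, 725.0, 10.0)
        basis = syn.gaussian_reflectance_basis(grid)
        w = np.zeros(basis.shape[0])
        w[0] = 4.0  # pushes values to 2.0
        with caplog.at_level("WARNING"):
            sp = syn.reflectance_from_basis(w, basis, grid)
        assert sp.values.max() == 1.0
        assert "clipped" in caplog.text

    def test_range_and_smoothness_over_many_draws(self, rng):
        grid = np.arange(400.0, 725.0, 10.0)
        basis = syn.gaussian_reflectance_basis(grid)
        for _ in range(1000):
            w = np.zeros(basis.shape[0])
            w[0] = rng.uniform(0.2, 1.6)
            w[1:] = rng.standard_normal(basis.shape[0] - 1) * 0.15
            sp = syn.reflectance_from_basis(w, basis, grid)
            assert sp.values.min() >= 0.0 and sp.values.max() <= 1.0
            assert np.max(np.abs(np.diff(sp.values))) <= 0.5

    def test_dimension_mismatch(self):
        grid = np.arange(400.0, 725.0, 10.0)
        basis = syn.gaussian_reflectance_basis(grid)
        with pytest.raises(ValueError):
            syn.reflectance_from_basis(np.ones(3), basis, grid)


class TestSceneGeneration:
    def test_achromatic_target_gives_grayscale(self):
        img = syn.generate_scene(syn.SceneSpec(width=48, height=48, seed=2,
                                               target_shares=(1.0, 0.0, 0.0)))
        ucs = cm.set_to_ucs(img.flatten(), VC)
        assert np.ptp(ucs[:, 1]) < 0.7 and np.ptp(ucs[:, 2]) < 0.7

    def test_variance_share_recovery_headline(self):
        img = syn.generate_scene(syn.SceneSpec(seed=1))
        shares, _, _ = _shares_and_axis(img)
        assert np.allclose(shares, (0.77, 0.08, 0.15), atol=0.05)

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_variance_share_recovery_across_targets(self, seed):
        targets = [(0.8, 0.07, 0.13), (0.7, 0.22, 0.08), (0.5, 0.1, 0.4)]
        tgt = targets[seed % 3]
        phi = {0.13: 90.0, 0.08: 150.0, 0.4: 90.0}[tgt[2]]
        img = syn.generate_scene(syn.SceneSpec(
            seed=seed, target_shares=tgt, chromatic_axis_deg=phi))
        shares, _, _ = _shares_and_axis(img)
        assert np.allclose(shares, tgt, atol=0.05)

    def test_axis_recovery(self):
        for phi in (54.0, 120.0):
            img = syn.generate_scene(syn.SceneSpec.with_axis(phi, seed=6))
            _, realized, _ = _shares_and_axis(img)
            err = abs((realized - phi + 90.0) % 180.0 - 90.0)
            assert err <= 5.0

    def test_bit_identical_determinism(self):
        spec = syn.SceneSpec(width=48, height=48, seed=7)
        a = syn.generate_scene(spec)
        b = syn.generate_scene(spec)
        assert np.array_equal(a.values, b.values)

    def test_64px_scene_calibrates(self):
        img = syn.generate_scene(syn.SceneSpec(width=64, height=64, seed=8))
        shares, _, _ = _shares_and_axis(img)
        assert np.allclose(shares, (0.77, 0.08, 0.15), atol=0.05)

    def test_inconsistent_axis_and_split_rejected(self):
        # Axis along redness-greenness but variance concentrated in
        # yellowness-blueness: geometrically impossible.
        with pytest.raises(ValueError):
            syn.generate_scene(syn.SceneSpec(seed=0, chromatic_axis_deg=0.0,
                                             target_shares=(0.77, 0.03, 0.2)))

    def test_chroma_lightness_tunable(self):
        img = syn.generate_scene(syn.SceneSpec(seed=2, chroma_lightness=0.25))
        ucs = cm.set_to_ucs(img.flatten(), VC)
        median = np.median(np.hypot(ucs[:, 1], ucs[:, 2]) / ucs[:, 0])
        assert median == pytest.approx(0.25, abs=0.05)

    def test_frequency_skew_entropy_monotone(self):
        # Seed-averaged entropy of realized material frequencies must be
        # non-increasing in the skew exponent.
        skews = (0.0, 0.7, 1.5, 2.5)
        means = []
        for skew in skews:
            ents = []
            for seed in range(6):
                rng = np.random.default_rng(seed)
                draws = rng.choice(64, size=48 * 48,
                                   p=syn._zipf_frequencies(64, skew))
                freqs = np.bincount(draws, minlength=64)
                ents.append(entropy(freqs / freqs.sum()))
            means.append(np.mean(ents))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestPalettes:
    def test_achromatic_palette(self):
        pal = syn.generate_palette(8, gamut_scale=0.0, seed=0)
        ucs = cm.set_to_ucs(syn.palette_radiances(pal), VC)
        assert np.all(np.abs(ucs[:, 1:]) < 0.5)
        assert np.all(np.diff(ucs[:, 0]) > 0)

    def test_near_uniform_in_ucs(self):
        pal = syn.generate_palette(500, seed=1)
        ucs = cm.set_to_ucs(syn.palette_radiances(pal), VC)
        d, _ = cKDTree(ucs).query(ucs, k=2)
        nn = d[:, 1]
        assert nn.std() / nn.mean() < 0.5

    def test_palette_more_chromatic_than_natural_scene(self, natural_scene):
        pal = syn.generate_palette(500, seed=2)
        ucs = cm.set_to_ucs(syn.palette_radiances(pal), VC)
        pal_share = cm.variance_partition(ucs)
        scene_share = cm.variance_partition(
            cm.set_to_ucs(natural_scene.flatten(), VC))
        assert pal_share.chromatic > scene_share.chromatic

    def test_deterministic(self):
        a = syn.generate_palette(64, seed=5)
        b = syn.generate_palette(64, seed=5)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            syn.generate_palette(4)
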