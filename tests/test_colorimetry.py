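"""Colorimetry: CIECAM02/CAM02-UCS correctness and scene descriptors."""

import math

import numpy as np
import pytest

from conegain import colorimetry as cm
from conegain.synthetic import daylight_spectrum


class TestAppearanceModel:
    def test_published_ciecam02_worked_example(self):
        # CIE 159:2004 worked example 1: XYZ=(19.01, 20.00, 21.78) under
        # XYZw=(95.05, 100, 108.88), LA=318.31, Yb=20, average surround
        # gives J=41.73, h=219.05. The example uses the model's D formula.
        vc = cm.ViewingConditions(white_xyz=np.array([95.05, 100.0, 108.88]),
                                  adapting_luminance=318.31,
                                  background_luminance_factor=20.0,
                                  full_adaptation=False)
        p = cm.xyz_to_cam02ucs(np.array([19.01, 20.00, 21.78]), vc)
        j = p.J / (1.7 - 0.007 * p.J)  # invert the UCS lightness transform
        h = math.degrees(math.atan2(p.b, p.a)) % 360.0
        assert j == pytest.approx(41.73, abs=0.1)
        assert h == pytest.approx(219.05, abs=0.5)

    def test_adapting_white_is_achromatic_origin(self):
        vc = cm.ViewingConditions()
        p = cm.xyz_to_cam02ucs(vc.white_xyz, vc)
        assert abs(p.a) < 0.5 and abs(p.b) < 0.5

    def test_neutral_series_varies_only_in_lightness(self):
        vc = cm.ViewingConditions()
        factors = np.array([0.1, 0.3, 0.5, 0.8, 1.0])
        pts = cm.xyz_array_to_ucs(vc.white_xyz[None, :] * factors[:, None], vc)
        assert np.all(np.abs(pts[:, 1:]) < 0.5)
        assert np.all(np.diff(pts[:, 0]) > 0)

    def test_equal_energy_chromaticity(self):
        wl = np.arange(380.0, 781.0, 1.0)
        xyz = cm.spectra_to_xyz(np.ones((1, wl.size)), wl)[0]
        chrom = xyz / xyz.sum()
        assert chrom[0] == pytest.approx(1 / 3, abs=0.01)
        assert chrom[1] == pytest.approx(1 / 3, abs=0.01)

    def test_zero_spectrum_gives_zero_tristimulus(self):
        wl = np.arange(400.0, 721.0, 10.0)
        assert np.allclose(cm.spectra_to_xyz(np.zeros((1, wl.size)), wl), 0.0)

    def test_daylight_chromaticity_on_locus(self):
        # Independent oracle: the CIE daylight-locus polynomials, evaluated
        # here, against the chromaticity of the constructed spectrum.
        wl = np.arange(400.0, 721.0, 5.0)
        for cct in (5000.0, 6500.0, 10000.0):
            t = cct
            if t <= 7000:
                x_locus = (-4.6070e9 / t**3 + 2.9678e6 / t**2
                           + 99.11 / t + 0.244063)
            else:
                x_locus = (-2.0064e9 / t**3 + 1.9018e6 / t**2
                           + 247.48 / t + 0.237040)
            y_locus = -3.0 * x_locus**2 + 2.87 * x_locus - 0.275
            sp = daylight_spectrum(cct, wl)
            xyz = cm.spectra_to_xyz(sp.values[None, :], wl)[0]
            chrom = xyz / xyz.sum()
            assert chrom[0] == pytest.approx(x_locus, abs=1e-3)
            assert chrom[1] == pytest.approx(y_locus, abs=1e-3)


class TestDescriptors:
    def test_variance_partition_lightness_only(self):
        pts = np.column_stack([np.linspace(10, 90, 50),
                               np.full(50, 1.0), np.full(50, -2.0)])
        shares = cm.variance_partition(pts)
        assert shares.lightness == pytest.approx(1.0, abs=1e-12)
        assert shares.rg == 0.0 and shares.yb == 0.0

    def test_variance_partition_isotropic(self, rng):
        pts = rng.standard_normal((20000, 3))
        shares = cm.variance_partition(pts)
        for s in (shares.lightness, shares.rg, shares.yb):
            assert s == pytest.approx(1 / 3, abs=0.02)

    def test_variance_partition_invariant_to_order(self, rng):
        pts = rng.standard_normal((200, 3)) * [3.0, 1.0, 2.0]
        a = cm.variance_partition(pts)
        b = cm.variance_partition(pts[rng.permutation(200)])
        assert a.lightness == pytest.approx(b.lightness)
        assert a.lightness + a.rg + a.yb == pytest.approx(1.0, abs=1e-12)

    def test_chroma_lightness_ratio(self):
        assert cm.chroma_lightness_ratio(np.array([[10.0, 3.0, 4.0]])) == \
            pytest.approx(0.5)
        achromatic = np.column_stack([np.linspace(5, 50, 10),
                                      np.zeros(10), np.zeros(10)])
        assert cm.chroma_lightness_ratio(achromatic) == 0.0
        with pytest.raises(ValueError):
            cm.chroma_lightness_ratio(np.array([[0.0, 1.0, 1.0]]))

    @pytest.mark.parametrize("axis_pts,expected", [
        (np.column_stack([np.zeros(9), np.linspace(-4, 4, 9), np.zeros(9)]), 0.0),
        (np.column_stack([np.zeros(9), np.zeros(9), np.linspace(-4, 4, 9)]), 90.0),
    ])
    def test_major_axis_cardinal_directions(self, axis_pts, expected):
        assert cm.major_chromatic_axis(axis_pts).phi == pytest.approx(
            expected, abs=1e-6)

    def test_major_axis_closed_form(self, rng):
        # Covariance [[2,1],[1,1]]: leading direction at atan2(2,1)/2.
        cov = np.array([[2.0, 1.0], [1.0, 1.0]])
        chol = np.linalg.cholesky(cov)
        ab = rng.standard_normal((200_000, 2)) @ chol.T
        pts = np.column_stack([np.full(ab.shape[0], 50.0), ab])
        expected = 0.5 * math.degrees(math.atan2(2.0, 1.0))
        assert cm.major_chromatic_axis(pts).phi == pytest.approx(expected,
                                                                 abs=0.5)

    def test_major_axis_rotation_equivariance(self, rng):
        ab = rng.standard_normal((500, 2)) * [3.0, 1.0]
        for theta in (20.0, 75.0, 130.0):
            r = math.radians(theta)
            rot = np.array([[math.cos(r), -math.sin(r)],
                            [math.sin(r), math.cos(r)]])
            base = cm.major_chromatic_axis(
                np.column_stack([np.zeros(500), ab])).phi
            rotated = cm.major_chromatic_axis(
                np.column_stack([np.zeros(500), ab @ rot.T])).phi
            diff = (rotated - base - theta) % 180.0
            assert min(diff, 180.0 - diff) < 0.1

    def test_isotropic_axis_is_an_error(self):
        pts = np.column_stack([np.zeros(4), [1, -1, 0, 0], [0, 0, 1, -1]])
        with pytest.raises(ValueError):
            cm.major_chromatic_axis(pts)


class TestConfusionLoci:
    def test_confusion_axis_directions(self):
        # Expected axial directions at the origin: ~12 (protan), ~178
        # (deutan), ~114 (tritan) degrees from the redness-greenness axis.
        vc = cm.ViewingConditions()
        assert cm.confusion_axis_direction("protan", vc) == pytest.approx(
            12.0, abs=3.0)
        assert cm.confusion_axis_direction("deutan", vc) == pytest.approx(
            178.0, abs=3.0)
        assert cm.confusion_axis_direction("tritan", vc) == pytest.approx(
            114.0, abs=3.0)

    def test_orthogonal_directions(self):
        vc = cm.ViewingConditions()
        for kind, expected in (("protan", 102.0), ("deutan", 88.0),
                               ("tritan", 24.0)):
            assert cm.confusion_axis_direction(
                kind, vc, orthogonal=True) == pytest.approx(expected, abs=3.0)

    def test_stability_over_step_sizes(self):
        vc = cm.ViewingConditions()
        for kind in ("protan", "deutan", "tritan"):
            vals = [cm.confusion_axis_direction(kind, vc, step=s)
                    for s in (1e-2, 1e-3, 1e-4)]
            assert max(vals) - min(vals) < 1.0  # +-0.5 degrees about the mean

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            cm.confusion_axis_direction("tetartan")
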