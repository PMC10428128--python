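"""Colorimetry: CIE XYZ, CIECAM02 / CAM02-UCS, and scene color descriptors.

This module maps radiance spectra into the approximately perceptually
uniform color space CAM02-UCS, with lightness J', redness-greenness a'M and
yellowness-blueness b'M, and computes the descriptive statistics used to
characterize scene color: the partition of total CAM02-UCS variance across
(J', a'M, b'M), the mean chroma-to-lightness ratio, the major chromatic axis
of a scene's chromatic distribution, and the axial directions of dichromatic
confusion loci at the achromatic point.

Notes on implementation
-----------------------
* CIE 1931 2-degree color-matching functions are the piecewise-Gaussian
  analytic fits of Wyman, Sloan & Shirley (2013); worst-case errors are below
  about 1% of peak, which is ample for the descriptive statistics here.
* The CIECAM02 forward model follows CIE 159:2004 and is validated against
  the published worked example.
* Colorimetric quantities are descriptive only and are deliberately kept out
  of the information-estimation pipeline (`conegain.information` does not
  import this module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, SpectralSet, check_wavelengths

__all__ = [
    "ViewingConditions",
    "UCSPoint",
    "VarianceShares",
    "ChromaticAxis",
    "cmf_1931",
    "spectrum_to_xyz",
    "spectra_to_xyz",
    "xyz_to_cam02ucs",
    "xyz_array_to_ucs",
    "set_to_ucs",
    "variance_partition",
    "chroma_lightness_ratio",
    "major_chromatic_axis",
    "confusion_axis_direction",
    "daylight_chromaticity",
    "COPUNCTAL_POINTS",
]

# Surround parameters (F, c, Nc) from CIE 159:2004.
_SURROUNDS = {
    "average": (1.0, 0.69, 1.0),
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}

_M_CAT02 = np.array(
    [[0.7328, 0.4296, -0.1624],
     [-0.7036, 1.6975, 0.0061],
     [0.0030, 0.0136, 0.9834]]
)
_M_HPE = np.array(
    [[0.38971, 0.68898, -0.07868],
     [-0.22981, 1.18340, 0.04641],
     [0.00000, 0.00000, 1.00000]]
)
_M_HPE_CAT02INV = _M_HPE @ np.linalg.inv(_M_CAT02)

# Dichromatic copunctal points in CIE 1931 (x, y): standard literature values.
COPUNCTAL_POINTS = {
    "protan": (0.747, 0.253),
    "deutan": (1.400, -0.400),
    "tritan": (0.171, 0.000),
}

# CAM02-UCS coefficients (Luo, Cui & Li 2006).
_UCS_KL, _UCS_C1, _UCS_C2 = 1.0, 0.007, 0.0228


# ---------------------------------------------------------------------------
# CIE 1931 color-matching functions and daylight chromaticity
# ---------------------------------------------------------------------------

def _pw_gauss(wl: np.ndarray, mu: float, t1: float, t2: float) -> np.ndarray:
    t = np.where(wl < mu, t1, t2)
    return np.exp(-0.5 * ((wl - mu) * t) ** 2)


def cmf_1931(wavelengths: np.ndarray) -> np.ndarray:
    """CIE 1931 2-degree color-matching functions, shape (n, 3).

    Analytic piecewise-Gaussian fits (Wyman, Sloan & Shirley 2013).
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = (0.362 * _pw_gauss(wl, 442.0, 0.0624, 0.0374)
         + 1.056 * _pw_gauss(wl, 599.8, 0.0264, 0.0323)
         - 0.065 * _pw_gauss(wl, 501.1, 0.0490, 0.0382))
    y = (0.821 * _pw_gauss(wl, 568.8, 0.0213, 0.0247)
         + 0.286 * _pw_gauss(wl, 530.9, 0.0613, 0.0322))
    z = (1.217 * _pw_gauss(wl, 437.0, 0.0845, 0.0278)
         + 0.681 * _pw_gauss(wl, 459.0, 0.0385, 0.0725))
    return np.stack([x, y, z], axis=-1)


def daylight_chromaticity(cct: float) -> tuple[float, float]:
    """CIE daylight-locus chromaticity (xD, yD) for a correlated color temperature.

    Valid for 4000 K <= cct <= 25000 K.
    """
    if not 4000.0 <= cct <= 25000.0:
        raise ValueError("daylight series is defined for 4000-25000 K")
    t = cct
    if t <= 7000.0:
        x = (-4.6070e9 / t**3 + 2.9678e6 / t**2 + 0.09911e3 / t + 0.244063)
    else:
        x = (-2.0064e9 / t**3 + 1.9018e6 / t**2 + 0.24748e3 / t + 0.237040)
    y = -3.000 * x * x + 2.870 * x - 0.275
    return x, y


# ---------------------------------------------------------------------------
# Spectra -> XYZ
# ---------------------------------------------------------------------------

def spectra_to_xyz(spectra: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Tristimulus integrals of radiance rows by the trapezoid rule, shape (n, 3).

    The grid must cover at least 400-700 nm. Values are unnormalized
    (relative radiance in, relative XYZ out).
    """
    wl = check_wavelengths(wavelengths)
    if wl[0] > 400.0 + 1e-9 or wl[-1] < 700.0 - 1e-9:
        raise ValueError("wavelength grid must cover 400-700 nm for colorimetry")
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    cmf = cmf_1931(wl)  # (b, 3)
    return np.trapezoid(spectra[:, :, None] * cmf[None, :, :], wl, axis=1)


def spectrum_to_xyz(spectrum: Spectrum) -> np.ndarray:
    """Tristimulus (X, Y, Z) of a single radiance spectrum."""
    return spectra_to_xyz(spectrum.values[None, :], spectrum.wavelengths)[0]


def _xy_to_xyz(x: float, y: float, Y: float) -> np.ndarray:
    if y <= 0:
        raise ValueError("chromaticity y must be positive")
    return np.array([x * Y / y, Y, (1.0 - x - y) * Y / y])


# ---------------------------------------------------------------------------
# Viewing conditions and CAM02-UCS
# ---------------------------------------------------------------------------

@dataclass
class ViewingConditions:
    """CIECAM02 viewing conditions.

    Defaults: 6500 K daylight white, adapting luminance 64 cd/m^2,
    background luminance factor 20, average surround, and full chromatic
    adaptation (degree of adaptation D forced to 1, appropriate for
    well-adapted viewing of outdoor scenes). Set ``full_adaptation=False``
    to use the CIECAM02 D formula instead.
    """

    white_xyz: np.ndarray = field(
        default_factory=lambda: _xy_to_xyz(*daylight_chromaticity(6500.0), 100.0))
    adapting_luminance: float = 64.0
    background_luminance_factor: float = 20.0
    surround: str = "average"
    full_adaptation: bool = True

    def __post_init__(self) -> None:
        self.white_xyz = np.asarray(self.white_xyz, dtype=float)
        if self.white_xyz.shape != (3,) or np.any(self.white_xyz <= 0):
            raise ValueError("white_xyz must be three positive numbers")
        if self.adapting_luminance <= 0 or self.background_luminance_factor <= 0:
            raise ValueError("luminances must be positive")
        if self.surround not in _SURROUNDS:
            raise ValueError(f"unknown surround {self.surround!r}")

    @classmethod
    def from_cct(cls, cct: float, **kwargs) -> "ViewingConditions":
        x, y = daylight_chromaticity(cct)
        return cls(white_xyz=_xy_to_xyz(x, y, 100.0), **kwargs)


@dataclass
class UCSPoint:
    """A CAM02-UCS coordinate: lightness J', redness-greenness a'M,
    yellowness-blueness b'M."""

    J: float
    a: float
    b: float

    @property
    def chroma(self) -> float:
        return math.hypot(self.a, self.b)


def _nonlinear_adaptation(rgb: np.ndarray, fl: float) -> np.ndarray:
    x = (fl * np.abs(rgb) / 100.0) ** 0.42
    return np.sign(rgb) * 400.0 * x / (27.13 + x) + 0.1


def xyz_array_to_ucs(xyz: np.ndarray, viewing: ViewingConditions | None = None) -> np.ndarray:
    """CIECAM02 forward model + CAM02-UCS transform, vectorized.

    Parameters
    ----------
    xyz : (n, 3) array with Y on a 0-100 scale relative to the white (Yw=100).

    Returns
    -------
    (n, 3) array of (J', a'M, b'M).
    """
    if viewing is None:
        viewing = ViewingConditions()
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    F, c, Nc = _SURROUNDS[viewing.surround]
    la = viewing.adapting_luminance
    xyz_w = viewing.white_xyz
    yw = xyz_w[1]

    rgb = xyz @ _M_CAT02.T
    rgb_w = _M_CAT02 @ xyz_w
    if viewing.full_adaptation:
        d = 1.0
    else:
        d = F * (1.0 - (1.0 / 3.6) * math.exp((-la - 42.0) / 92.0))
        d = min(max(d, 0.0), 1.0)

    dr = yw * d / rgb_w + 1.0 - d
    rgb_c = rgb * dr
    rgb_wc = rgb_w * dr

    k = 1.0 / (5.0 * la + 1.0)
    fl = 0.2 * k**4 * 5.0 * la + 0.1 * (1.0 - k**4) ** 2 * (5.0 * la) ** (1.0 / 3.0)
    n = viewing.background_luminance_factor / yw
    nbb = ncb = 0.725 * (1.0 / n) ** 0.2
    z = 1.48 + math.sqrt(n)

    rgb_p = rgb_c @ _M_HPE_CAT02INV.T
    rgb_wp = _M_HPE_CAT02INV @ rgb_wc
    rgb_a = _nonlinear_adaptation(rgb_p, fl)
    rgb_wa = _nonlinear_adaptation(rgb_wp, fl)

    ra, ga, ba = rgb_a[:, 0], rgb_a[:, 1], rgb_a[:, 2]
    a = ra - 12.0 * ga / 11.0 + ba / 11.0
    b = (ra + ga - 2.0 * ba) / 9.0
    h = np.arctan2(b, a)  # radians
    et = 0.25 * (np.cos(h + 2.0) + 3.8)

    A = (2.0 * ra + ga + ba / 20.0 - 0.305) * nbb
    Aw = (2.0 * rgb_wa[0] + rgb_wa[1] + rgb_wa[2] / 20.0 - 0.305) * nbb
    J = 100.0 * np.clip(A / Aw, 0.0, None) ** (c * z)

    t = (50000.0 / 13.0 * Nc * ncb * et * np.hypot(a, b)
         / (ra + ga + 21.0 / 20.0 * ba))
    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**n) ** 0.73
    M = C * fl**0.25

    jp = (1.0 + 100.0 * _UCS_C1) * J / (1.0 + _UCS_C1 * J)
    mp = np.log1p(_UCS_C2 * M) / _UCS_C2
    return np.stack([jp, mp * np.cos(h), mp * np.sin(h)], axis=-1)


def xyz_to_cam02ucs(xyz: np.ndarray, viewing: ViewingConditions | None = None) -> UCSPoint:
    """CAM02-UCS coordinates of a single XYZ triple (Y relative to Yw=100)."""
    j, a, b = xyz_array_to_ucs(np.asarray(xyz, dtype=float)[None, :], viewing)[0]
    return UCSPoint(float(j), float(a), float(b))


def set_to_ucs(spectra: SpectralSet, viewing: ViewingConditions | None = None,
               white_percentile: float = 99.0) -> np.ndarray:
    """Map a set of radiance spectra into CAM02-UCS, shape (n, 3).

    Absolute luminance calibration: the scene's near-white, taken as the
    given percentile of the luminance (Y) distribution, is scaled to the
    adapting white's Y. Pixels brighter than the near-white may exceed Y=100;
    the appearance model handles them smoothly.
    """
    xyz = spectra_to_xyz(spectra.spectra, spectra.wavelengths)
    ref = np.percentile(xyz[:, 1], white_percentile)
    if ref <= 0:
        raise ValueError("scene has no positive luminance; cannot calibrate")
    return xyz_array_to_ucs(xyz * (100.0 / ref), viewing)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

@dataclass
class VarianceShares:
    """Fractions of total CAM02-UCS variance due to J', a'M, b'M."""

    lightness: float
    rg: float
    yb: float

    def __post_init__(self) -> None:
        total = self.lightness + self.rg + self.yb
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("variance shares must sum to 1")
        for v in (self.lightness, self.rg, self.yb):
            if not 0.0 <= v <= 1.0:
                raise ValueError("variance shares must lie in [0, 1]")

    @property
    def chromatic(self) -> float:
        return self.rg + self.yb


@dataclass
class ChromaticAxis:
    """Axial direction (degrees in [0, 180), anticlockwise from +a'M) of the
    major chromatic axis, with the fraction of chromatic variance it explains."""

    phi: float
    variance_explained: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 180.0:
            raise ValueError("phi must lie in [0, 180)")
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValueError("variance_explained must lie in [0, 1]")


def _as_ucs_array(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        arr = np.atleast_2d(points)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], UCSPoint):
            arr = np.array([[p.J, p.a, p.b] for p in pts])
        else:
            arr = np.atleast_2d(np.asarray(pts, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of (J', a'M, b'M)")
    return arr.astype(float)


def variance_partition(points) -> VarianceShares:
    """Proportions of total CAM02-UCS variance due to J', a'M and b'M."""
    arr = _as_ucs_array(points)
    if arr.shape[0] < 2:
        raise ValueError("variance partition needs at least 2 points")
    var = arr.var(axis=0, ddof=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance; partition undefined")
    share = var / total
    return VarianceShares(float(share[0]), float(share[1]), float(share[2]))


def chroma_lightness_ratio(points, statistic: str = "mean") -> float:
    """Ratio of chroma (a'M^2+b'M^2)^(1/2) to lightness J', aggregated over points."""
    arr = _as_ucs_array(points)
    if np.any(arr[:, 0] <= 0):
        raise ValueError("chroma/lightness ratio undefined for J' <= 0")
    ratios = np.hypot(arr[:, 1], arr[:, 2]) / arr[:, 0]
    if statistic == "mean":
        return float(ratios.mean())
    if statistic == "median":
        return float(np.median(ratios))
    raise ValueError(f"unknown statistic {statistic!r}")


def major_chromatic_axis(points, isotropy_tol: float = 1e-12) -> ChromaticAxis:
    """Principal axis of the (a'M, b'M) distribution, folded to [0, 180) degrees."""
    arr = _as_ucs_array(points)
    if arr.shape[0] < 3:
        raise ValueError("major chromatic axis needs at least 3 points")
    ab = arr[:, 1:3]
    cov = np.cov(ab, rowvar=False)
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("no chromatic variance; axis undefined")
    # Leading eigen-direction of a 2x2 symmetric matrix, closed form.
    diff = cov[0, 0] - cov[1, 1]
    off = cov[0, 1]
    if abs(diff) < isotropy_tol * total and abs(off) < isotropy_tol * total:
        raise ValueError("isotropic chromatic covariance; axis undefined")
    phi = 0.5 * math.degrees(math.atan2(2.0 * off, diff))
    phi %= 180.0
    lam_max = 0.5 * (np.trace(cov) + math.hypot(diff, 2.0 * off))
    return ChromaticAxis(phi, float(lam_max / total))


# ---------------------------------------------------------------------------
# Confusion loci
# ---------------------------------------------------------------------------

def confusion_axis_direction(kind: str, viewing: ViewingConditions | None = None,
                             step: float = 1e-3, luminance_factor: float = 20.0,
                             orthogonal: bool = False) -> float:
    """Axial direction of a dichromatic confusion locus at the CAM02-UCS origin.

    The confusion line through the adapting white toward the copunctal point
    of the missing cone class is constructed in the CIE 1931 (x, y)
    chromaticity diagram; chromaticities a small step either side of the
    white are mapped into CAM02-UCS at fixed luminance, and the tangent
    direction at the origin is returned, folded to [0, 180) degrees measured
    anticlockwise from the +a'M axis.

    Parameters
    ----------
    kind : {"protan", "deutan", "tritan"}
    step : chromaticity-space half-step for the central difference.
    luminance_factor : Y (relative to Yw=100) at which points are mapped.
    orthogonal : if True, return the direction orthogonal to the confusion
        axis (the ideally optimal discrimination direction).
    """
    if kind not in COPUNCTAL_POINTS:
        raise ValueError(f"unknown dichromat type {kind!r}")
    if viewing is None:
        viewing = ViewingConditions()
    wx = viewing.white_xyz
    w_sum = wx.sum()
    white_xy = np.array([wx[0] / w_sum, wx[1] / w_sum])
    cop = np.array(COPUNCTAL_POINTS[kind])
    direction = cop - white_xy
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("degenerate confusion line: white at copunctal point")
    direction /= norm

    p_plus = white_xy + step * direction
    p_minus = white_xy - step * direction
    xyz = np.stack([_xy_to_xyz(*p, luminance_factor) for p in (p_plus, p_minus)])
    ucs = xyz_array_to_ucs(xyz, viewing)
    dab = ucs[0, 1:3] - ucs[1, 1:3]
    if np.hypot(*dab) < 1e-12:
        raise ValueError("degenerate tangent at the origin")
    phi = math.degrees(math.atan2(dab[1], dab[0])) % 180.0
    if orthogonal:
        phi = (phi + 90.0) % 180.0
    return phi
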