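"""Synthetic hyperspectral scenes, palettes, and illuminants.

The generator is a statistical surrogate for hyperspectral image sets of
natural scenes, not a photorealistic renderer. It reproduces the color
statistics the downstream analysis depends on:

* dominant lightness variance (by default ~77% of CAM02-UCS variance, the
  natural-scene regime), produced by a spatially smoothed log-normal
  shading field on top of per-material gray levels;
* small chromatic variance concentrated along a controllable axis in the
  (a'M, b'M) plane, produced by low-dimensional smooth reflectance spectra
  whose chromatic coordinates are drawn from an axis-aligned covariance;
* a bounded gamut (reflectances clipped to [0, 1]);
* strongly uneven frequencies of different colored surfaces (Zipf-like
  material frequencies with exponent ``frequency_skew``), with the rarer
  surfaces the more chromatic ones (``rarity_chroma`` couples a material's
  chromatic spread to its rarity, emulating the colorful-outlier structure
  of natural scenes: common surfaces cluster near neutral, rare ones carry
  the gamut).

Requested CAM02-UCS variance shares are achieved by an internal calibration
loop: the mapping from generator knobs to realized shares is nonlinear
(clipping, appearance-model curvature), so the chromatic scale is solved
iteratively against measured shares rather than assumed. All randomness is
drawn once up front, so calibration preserves bit-exact determinism for a
given spec.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import colorimetry
from .colorimetry import ViewingConditions
from .spectra import Spectrum, SpectralImage, SpectralSet, check_wavelengths

__all__ = [
    "SceneSpec",
    "daylight_spectrum",
    "gaussian_reflectance_basis",
    "reflectance_from_basis",
    "generate_scene",
    "generate_palette",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``target_shares`` are the desired fractions of total CAM02-UCS variance
    due to (lightness J', redness-greenness a'M, yellowness-blueness b'M);
    the defaults mimic the natural-scene regime in which lightness
    dominates. ``chromatic_axis_deg`` is the direction of dominant chromatic
    variation in the (a'M, b'M) plane, degrees in [0, 180) anticlockwise
    from +a'M. ``gamut_scale`` multiplies the chromatic spread reachable by
    the calibration (1.0 is comfortable for natural-like shares);
    ``chroma_lightness`` optionally calibrates the median chroma/lightness
    ratio by shifting the mean chromatic coordinate away from neutral.
    """

    width: int = 128
    height: int = 128
    wavelengths: tuple[float, float, float] = (400.0, 720.0, 10.0)
    n_materials: int = 64
    frequency_skew: float = 1.0
    target_shares: tuple[float, float, float] = (0.77, 0.08, 0.15)
    chromatic_axis_deg: float = 90.0
    gamut_scale: float = 1.0
    illuminant_cct: float = 6500.0
    seed: int = 0
    chroma_lightness: float | None = None
    shading_log_sd: float = 0.35
    shading_smoothness_px: float = 4.0
    texture_sd: float = 0.012
    rarity_chroma: float = 0.5

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene dimensions must be positive")
        if self.n_materials < 2:
            raise ValueError("need at least 2 materials")
        if self.frequency_skew < 0:
            raise ValueError("frequency_skew must be >= 0")
        if abs(sum(self.target_shares) - 1.0) > 1e-9:
            raise ValueError("target_shares must sum to 1")
        if any(s < 0 for s in self.target_shares):
            raise ValueError("target_shares must be non-negative")
        if not 0.0 <= self.chromatic_axis_deg < 180.0:
            raise ValueError("chromatic_axis_deg must lie in [0, 180)")
        if self.gamut_scale < 0:
            raise ValueError("gamut_scale must be >= 0")
        start, stop, step = self.wavelengths
        if step <= 0 or stop <= start:
            raise ValueError("invalid wavelength grid")

    @property
    def grid(self) -> np.ndarray:
        start, stop, step = self.wavelengths
        return check_wavelengths(np.arange(start, stop + step / 2, step))

    @classmethod
    def with_axis(cls, chromatic_axis_deg: float, chromatic_share: float = 0.23,
                  anisotropy: float = 4.0, **kwargs) -> "SceneSpec":
        """Spec with target shares derived consistently from a chromatic axis.

        The chromatic covariance is taken as anisotropic (major/minor
        variance ratio ``anisotropy``) along ``chromatic_axis_deg``; the
        implied (rg, yb) variance split is computed from that geometry, so
        any axis direction is feasible.
        """
        if not 0.0 < chromatic_share < 1.0:
            raise ValueError("chromatic_share must lie in (0, 1)")
        if anisotropy < 1.0:
            raise ValueError("anisotropy must be >= 1")
        phi = math.radians(chromatic_axis_deg)
        l1 = chromatic_share * anisotropy / (anisotropy + 1.0)
        l2 = chromatic_share - l1
        c2, s2 = math.cos(phi) ** 2, math.sin(phi) ** 2
        var_a = l1 * c2 + l2 * s2
        var_b = l1 * s2 + l2 * c2
        return cls(target_shares=(1.0 - chromatic_share, var_a, var_b),
                   chromatic_axis_deg=chromatic_axis_deg % 180.0, **kwargs)


# ---------------------------------------------------------------------------
# Illuminant
# ---------------------------------------------------------------------------

def _planck(wl_nm: np.ndarray, t: float) -> np.ndarray:
    """Relative blackbody spectral radiance (arbitrary units)."""
    lam = wl_nm * 1e-9
    c2 = 1.4388e-2  # m K
    x = np.exp(c2 / (lam * t))
    return 1.0 / (lam**5 * (x - 1.0))


def daylight_spectrum(cct: float, wavelengths: np.ndarray) -> Spectrum:
    """Daylight-series illuminant on the requested grid.

    The spectrum is a Planckian radiator at the requested correlated color
    temperature multiplied by a smooth quadratic correction solved (exactly,
    by a linear system) so that its chromaticity lies on the CIE daylight
    locus for that temperature, then normalized to 100 at 560 nm. Valid for
    4000 K <= cct <= 25000 K.
    """
    grid = check_wavelengths(np.asarray(wavelengths, dtype=float))
    xd, yd = colorimetry.daylight_chromaticity(cct)  # validates the range
    base = _planck(grid, cct)
    u = (grid - 560.0) / 160.0
    basis = np.stack([base, base * u, base * u * u], axis=1)  # (b, 3)
    xyz = colorimetry.spectra_to_xyz(basis.T, grid)  # (3, 3): XYZ per basis fn
    # Chromaticity constraints are linear in the coefficients c:
    #   (1-xd) X - xd Y - xd Z = 0 ;  -yd X + (1-yd) Y - yd Z = 0
    a1 = (1.0 - xd) * xyz[:, 0] - xd * xyz[:, 1] - xd * xyz[:, 2]
    a2 = -yd * xyz[:, 0] + (1.0 - yd) * xyz[:, 1] - yd * xyz[:, 2]
    # Fix c0 = 1, solve for c1, c2.
    mat = np.array([[a1[1], a1[2]], [a2[1], a2[2]]])
    rhs = -np.array([a1[0], a2[0]])
    c1, c2 = np.linalg.solve(mat, rhs)
    values = basis @ np.array([1.0, c1, c2])
    if values.min() < 0:
        raise ValueError("daylight construction produced negative power; "
                         "cct outside the supported range")
    v560 = np.interp(560.0, grid, values)
    return Spectrum(grid, values * (100.0 / v560), "radiance")


# ---------------------------------------------------------------------------
# Reflectance basis
# ---------------------------------------------------------------------------

def gaussian_reflectance_basis(wavelengths: np.ndarray, n_functions: int = 6,
                               width_nm: float | None = None) -> np.ndarray:
    """Smooth non-negative reflectance basis: Gaussian bumps on wavelength.

    Returns an (n_functions, bands) array; the first function is constant
    0.5 (the achromatic component), the rest are bumps spread across the
    grid. Natural reflectance spectra are low-dimensional and smooth; 6-8
    functions capture that regime.
    """
    wl = check_wavelengths(np.asarray(wavelengths, dtype=float))
    if n_functions < 2:
        raise ValueError("need at least 2 basis functions")
    span = wl[-1] - wl[0]
    width = width_nm if width_nm is not None else span / (n_functions - 1)
    centers = np.linspace(wl[0], wl[-1], n_functions - 1)
    basis = [np.full(wl.size, 0.5)]
    for c in centers:
        basis.append(np.exp(-0.5 * ((wl - c) / width) ** 2))
    return np.stack(basis)


def reflectance_from_basis(weights: np.ndarray, basis: np.ndarray,
                           wavelengths: np.ndarray) -> Spectrum:
    """Reflectance as a weighted sum of basis functions, clipped to [0, 1]."""
    weights = np.asarray(weights, dtype=float)
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if weights.size != basis.shape[0]:
        raise ValueError("weight count does not match basis size")
    values = weights @ basis
    if values.min() < -1e-12 or values.max() > 1 + 1e-12:
        logger.warning("reflectance clipped to [0, 1] (range was [%.3f, %.3f])",
                       values.min(), values.max())
    return Spectrum(np.asarray(wavelengths, dtype=float),
                    np.clip(values, 0.0, 1.0), "reflectance")


# ---------------------------------------------------------------------------
# Chromatic covariance from (axis, variance shares)
# ---------------------------------------------------------------------------

def _chromatic_covariance(phi_deg: float, var_a: float, var_b: float,
                          default_anisotropy: float = 4.0) -> np.ndarray:
    """2x2 covariance with principal axis at phi and diagonal (var_a, var_b).

    Raises if no covariance with that axis can have those diagonal
    variances (the requested shares and axis are inconsistent).
    """
    phi = math.radians(phi_deg)
    c2 = math.cos(phi) ** 2
    total = var_a + var_b
    if total <= 0:
        return np.zeros((2, 2))
    if abs(c2 - 0.5) < 1e-9:
        # 45/135 degrees: the diagonal constraint forces var_a == var_b and
        # leaves the anisotropy free; use the default ratio.
        if abs(var_a - var_b) > 0.05 * total:
            raise ValueError("requested chromatic axis is inconsistent with "
                             "the requested rg/yb variance split")
        lam1 = total * default_anisotropy / (default_anisotropy + 1.0)
        lam2 = total - lam1
    else:
        lam1 = (var_a * c2 - var_b * (1.0 - c2)) / (2.0 * c2 - 1.0)
        lam2 = total - lam1
    if lam1 < lam2 - 1e-12 or lam2 < -1e-12:
        raise ValueError("requested chromatic axis is inconsistent with the "
                         "requested rg/yb variance split")
    lam2 = max(lam2, 0.0)
    s, c = math.sin(phi), math.cos(phi)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag([lam1, lam2]) @ rot.T


def _zipf_frequencies(n: int, skew: float) -> np.ndarray:
    p = np.arange(1, n + 1, dtype=float) ** (-skew)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _chromatic_directions(grid: np.ndarray, illuminant: np.ndarray,
                          viewing: ViewingConditions, basis: np.ndarray,
                          base_gray: float = 0.35) -> tuple[np.ndarray, np.ndarray, float]:
    """Reflectance perturbation spectra moving the appearance by unit a'M or
    unit b'M, linearized around a flat gray under the illuminant.

    Returns (e_a, e_b, ucs_scale) where ucs_scale converts reflectance-space
    chromatic draws to approximate CAM02-UCS units.
    """
    white_y = colorimetry.spectra_to_xyz(illuminant[None, :], grid)[0, 1]
    scale = 100.0 / white_y

    def to_ucs(refl_rows: np.ndarray) -> np.ndarray:
        xyz = colorimetry.spectra_to_xyz(refl_rows * illuminant, grid) * scale
        return colorimetry.xyz_array_to_ucs(xyz, viewing)

    base = np.full(grid.size, base_gray)
    eps = 0.01
    u0 = to_ucs(base[None, :])[0]
    # Jacobian of (a, b) with respect to the chromatic basis functions.
    jac = np.empty((2, basis.shape[0] - 1))
    for j in range(1, basis.shape[0]):
        u1 = to_ucs((base + eps * basis[j])[None, :])[0]
        jac[:, j - 1] = (u1[1:] - u0[1:]) / eps
    pinv = np.linalg.pinv(jac)  # (n_chromatic_basis, 2)
    e_a = pinv[:, 0] @ basis[1:]
    e_b = pinv[:, 1] @ basis[1:]
    return e_a, e_b, 1.0


def generate_scene(spec: SceneSpec,
                   viewing: ViewingConditions | None = None,
                   calibrate: bool = True, max_iter: int = 24,
                   share_tol: float = 0.02) -> SpectralImage:
    """Generate a synthetic hyperspectral radiance scene.

    Deterministic given ``spec`` (including its seed). The realized
    CAM02-UCS variance shares match ``spec.target_shares`` within about
    +-0.05 for scenes of at least 64x64 pixels; if the calibration cannot
    reach them under the requested ``gamut_scale``, a ValueError is raised
    rather than silently clamping.
    """
    if viewing is None:
        viewing = ViewingConditions.from_cct(spec.illuminant_cct)
    grid = spec.grid
    illum = daylight_spectrum(spec.illuminant_cct, grid).values
    basis = gaussian_reflectance_basis(grid)
    e_a, e_b, _ = _chromatic_directions(grid, illum, viewing, basis)

    rng = np.random.default_rng(spec.seed)
    n_mat = spec.n_materials
    # All randomness is drawn once; the calibration below is deterministic.
    gray = rng.uniform(0.10, 0.65, size=n_mat)
    unit_draws = rng.standard_normal((n_mat, 2))
    freqs = _zipf_frequencies(n_mat, spec.frequency_skew)
    # Rarer materials get proportionally larger chromatic spread; the
    # pixel-level covariance correction in the calibration absorbs the
    # resulting non-identity draw covariance.
    rarity_mult = (freqs.max() / freqs) ** (spec.rarity_chroma / 2.0)
    rarity_mult /= np.sqrt(np.mean(rarity_mult**2))
    unit_draws = unit_draws * rarity_mult[:, None]
    material = rng.choice(n_mat, size=(spec.height, spec.width), p=freqs)
    shade_noise = rng.standard_normal((spec.height, spec.width))
    smooth = gaussian_filter(shade_noise, spec.shading_smoothness_px, mode="wrap")
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    shading = np.exp(spec.shading_log_sd * smooth)
    # Within-material spectral texture: smooth per-pixel reflectance
    # perturbations (weights on the same low-dimensional basis). Real
    # surfaces are not spectrally uniform; without this the radiance
    # distribution would collapse onto a near-1-D manifold per material.
    # The chromatic components are suppressed for purely achromatic
    # targets so a grayscale scene stays exactly gray.
    texture_w = rng.standard_normal((spec.height * spec.width,
                                     basis.shape[0])) * spec.texture_sd
    if spec.target_shares[1] + spec.target_shares[2] == 0:
        texture_w[:, 1:] = 0.0

    sub = min(8192, spec.height * spec.width)
    sub_idx = rng.choice(spec.height * spec.width, size=sub, replace=False)

    target_l, target_a, target_b = spec.target_shares
    chromatic_target = target_a + target_b
    cov_unit = _chromatic_covariance(spec.chromatic_axis_deg,
                                     max(target_a, 1e-12),
                                     max(target_b, 1e-12))

    mean_offset = np.zeros(2)
    if spec.chroma_lightness is not None:
        phi = math.radians(spec.chromatic_axis_deg)
        mean_offset = np.array([math.cos(phi), math.sin(phi)])

    flat_mat = material.reshape(-1)[sub_idx]
    flat_shade = shading.reshape(-1)[sub_idx]

    def build(mixing: np.ndarray, mean_mag: float) -> tuple[np.ndarray, np.ndarray]:
        coords = unit_draws @ mixing.T + mean_mag * mean_offset
        refl = np.clip(gray[:, None]
                       + coords[:, 0:1] * e_a[None, :]
                       + coords[:, 1:2] * e_b[None, :], 0.001, 1.0)
        return refl, coords  # (n_mat, bands), (n_mat, 2)

    def measure(refl: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        pix_refl = np.clip(refl[flat_mat] + texture_w[sub_idx] @ basis, 0.001, 1.0)
        radiance = pix_refl * illum[None, :] * flat_shade[:, None]
        ucs = colorimetry.set_to_ucs(SpectralSet(radiance, grid), viewing)
        var = ucs.var(axis=0)
        shares = var / var.sum()
        ratio = float(np.median(np.hypot(ucs[:, 1], ucs[:, 2]) / ucs[:, 0]))
        return shares, ratio, ucs

    # Mixing matrix: material chromatic coords = unit_draws @ mixing.T. The
    # calibration below solves it so the *realized* pixel-level (a'M, b'M)
    # covariance matches the requested axis/share structure, compensating
    # the cross-talk introduced by clipping, gray-level dependence of the
    # linearization, and the appearance model's luminance dependence.
    if chromatic_target == 0:
        mixing = np.zeros((2, 2))
    else:
        mixing = (8.0 * spec.gamut_scale * math.sqrt(chromatic_target)
                  * np.linalg.cholesky(cov_unit / cov_unit.trace()
                                       + 1e-15 * np.eye(2)))
    mean_mag = 0.0
    refl, coords = build(mixing, mean_mag)
    if chromatic_target > 0 and calibrate:
        max_norm = 80.0 * max(spec.gamut_scale, 1e-9)
        converged = False
        for _ in range(max_iter):
            shares, ratio, ucs = measure(refl)
            realized_c = shares[1] + shares[2]
            done_shares = (abs(realized_c - chromatic_target) <= share_tol
                           and abs(shares[1] - target_a) <= share_tol * 1.5
                           and abs(shares[2] - target_b) <= share_tol * 1.5)
            c_real_now = np.cov(ucs[:, 1:3], rowvar=False)
            diff = c_real_now[0, 0] - c_real_now[1, 1]
            off = c_real_now[0, 1]
            phi_real = (0.5 * math.degrees(math.atan2(2 * off, diff))) % 180.0
            axis_err = abs((phi_real - spec.chromatic_axis_deg + 90.0) % 180.0
                           - 90.0)
            anisotropy = (c_real_now.trace()
                          + math.hypot(diff, 2 * off)) / max(
                c_real_now.trace() - math.hypot(diff, 2 * off), 1e-12)
            done_axis = axis_err <= 2.0 or anisotropy < 1.3
            done_shares = done_shares and done_axis
            done_ratio = (spec.chroma_lightness is None
                          or abs(ratio - spec.chroma_lightness)
                          <= 0.05 * max(spec.chroma_lightness, 0.05))
            if done_shares and done_ratio:
                converged = True
                break
            # Desired absolute chromatic covariance for the current J'
            # variance, then the mixing that realizes it given the measured
            # linear transfer from material coords to pixel appearance.
            var_j = float(ucs[:, 0].var())
            v_c_des = var_j * chromatic_target / max(1.0 - chromatic_target, 1e-9)
            c_des = cov_unit / cov_unit.trace() * v_c_des
            x = coords[flat_mat] - coords[flat_mat].mean(axis=0)
            y = ucs[:, 1:3] - ucs[:, 1:3].mean(axis=0)
            t_mat, *_ = np.linalg.lstsq(x, y, rcond=None)  # y ~ x @ t_mat
            t_mat = t_mat.T  # (a,b)_real = T @ coords
            if abs(np.linalg.det(t_mat)) < 1e-9:
                raise ValueError("chromatic transfer degenerate; cannot "
                                 "calibrate target shares")
            # Chromatic variance not explained by the linear transfer
            # (gray-level and shading dependence of chroma) still counts
            # toward the realized shares; aim the linear part at the
            # remainder.
            c_real = np.cov(ucs[:, 1:3], rowvar=False)
            resid = c_real - t_mat @ np.cov(x, rowvar=False) @ t_mat.T
            c_goal = c_des - resid
            evals, evecs = np.linalg.eigh((c_goal + c_goal.T) / 2.0)
            evals = np.clip(evals, 0.02 * v_c_des, None)
            c_goal = evecs @ np.diag(evals) @ evecs.T
            # Pixel-level covariance of the unit draws: uneven material
            # frequencies make it differ from the identity.
            u_cov = np.cov(unit_draws[flat_mat], rowvar=False)
            chol_u = np.linalg.cholesky(u_cov + 1e-12 * np.eye(2))
            new_mixing = np.linalg.solve(
                t_mat, np.linalg.cholesky(c_goal + 1e-15 * np.eye(2))
            ) @ np.linalg.inv(chol_u)
            # Damp the update and cap the reachable gamut.
            mixing = 0.5 * mixing + 0.5 * new_mixing
            norm = np.linalg.norm(mixing, 2)
            if norm > max_norm:
                mixing *= max_norm / norm
            if spec.chroma_lightness is not None:
                mean_mag = max(mean_mag + 20.0 * (spec.chroma_lightness - ratio),
                               0.0)
            refl, coords = build(mixing, mean_mag)
        if not converged:
            shares, ratio, _ = measure(refl)
            if (abs(shares[1] + shares[2] - chromatic_target) > 2.5 * share_tol
                    or abs(shares[1] - target_a) > 0.05
                    or abs(shares[2] - target_b) > 0.05):
                raise ValueError(
                    "target variance shares unreachable at this gamut_scale "
                    f"(realized {np.round(shares, 3).tolist()}, "
                    f"target {spec.target_shares})")

    pix_refl = np.clip(refl[material.reshape(-1)] + texture_w @ basis, 0.001, 1.0)
    radiance = (pix_refl.reshape(spec.height, spec.width, -1)
                * illum[None, None, :] * shading[:, :, None])
    meta = {"scene_id": f"synthetic-{spec.seed}", "landcover": "synthetic",
            "source": "conegain.synthetic"}
    return SpectralImage(radiance, grid, meta)


# ---------------------------------------------------------------------------
# Palettes
# ---------------------------------------------------------------------------

def generate_palette(n: int, gamut_scale: float = 1.0, seed: int = 0,
                     wavelengths: np.ndarray | None = None,
                     illuminant_cct: float = 6500.0) -> list[Spectrum]:
    """Approximately CAM02-UCS-uniform reflectance palette.

    Reflectances are constructed on a jittered lattice in (J', a'M, b'M),
    mapped back to smooth spectra through the chromatic linearization, and
    clipped to [0, 1]; points whose realized appearance drifts far from the
    lattice (gamut clipping) are replaced by their nearest feasible
    neighbor. ``gamut_scale=0`` yields an achromatic lightness series.
    """
    if n < 8:
        raise ValueError("palettes need at least 8 samples")
    grid = (check_wavelengths(wavelengths) if wavelengths is not None
            else np.arange(400.0, 725.0, 10.0))
    viewing = ViewingConditions.from_cct(illuminant_cct)
    illum = daylight_spectrum(illuminant_cct, grid).values
    rng = np.random.default_rng(seed)

    grays = np.linspace(0.08, 0.85, n)
    if gamut_scale == 0:
        return [Spectrum(grid, np.full(grid.size, g), "reflectance")
                for g in grays]

    basis = gaussian_reflectance_basis(grid)
    e_a, e_b, _ = _chromatic_directions(grid, illum, viewing, basis)
    # Jittered lattice in (gray, a, b): near-uniform by construction.
    n_side = max(2, round(n ** (1.0 / 3.0)))
    n_j = max(2, math.ceil(n / n_side**2))
    pts = []
    for i in range(n_j):
        for ja in range(n_side):
            for jb in range(n_side):
                pts.append((i, ja, jb))
    pts = np.array(pts[:n], dtype=float)
    jitter = rng.uniform(-0.2, 0.2, size=pts.shape)
    pts += jitter
    g = 0.12 + (pts[:, 0] / max(n_j - 1, 1)) * 0.58
    amp = 25.0 * gamut_scale
    a = (pts[:, 1] / max(n_side - 1, 1) - 0.5) * 2 * amp
    b = (pts[:, 2] / max(n_side - 1, 1) - 0.5) * 2 * amp
    refl = np.clip(g[:, None] + a[:, None] * e_a[None, :]
                   + b[:, None] * e_b[None, :], 0.001, 1.0)
    return [Spectrum(grid, r, "reflectance") for r in refl]


def palette_radiances(palette: list[Spectrum], illuminant_cct: float = 6500.0
                      ) -> SpectralSet:
    """Radiance spectra of a reflectance palette under a daylight illuminant,
    treated as a single 'scene' for information estimation."""
    grid = palette[0].wavelengths
    illum = daylight_spectrum(illuminant_cct, grid).values
    rows = np.stack([p.values * illum for p in palette])
    return SpectralSet(rows, grid, {"scene_id": "palette"})
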