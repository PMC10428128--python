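"""Cone photoreceptors: fundamentals, hybrid pigment shifts, excitations, noise.

Observers are built from corneal cone spectral sensitivities (fundamentals)
with peaks at approximately 559 (L), 530 (M), and 426 (S) nm. Color
deficiency is modeled at the receptor level:

* protanopia: L absent, cones {M, S};
* deuteranopia: M absent, cones {L, S};
* protanomaly: normal M plus a hybrid pigment at 536 nm, cones {M, M', S};
* deuteranomaly: normal L plus a hybrid pigment at 549 nm, cones {L, L', S};
* cone monochromacy: a single M or L class.

Hybrid pigments are produced by smoothing the corneal template with a
quadratic loess fit of sensitivity against log wavelength (bandwidth chosen
by leave-one-out cross-validation) and translating it along the
log-wavelength axis to the target peak; shape is preserved on that axis, and
the S pigment is assumed unaltered. Optical density is held constant (no
self-screening adjustment).

Cone noise is a Gaussian process whose standard deviation is a fixed
fraction (Weber fraction) of the local cone excitation, with the L-cone
fraction as the headline parameter (default 0.02, a practical minimum) and
the M and S fractions scaled by the ratios of Stiles' increment-threshold
Weber fractions 0.018 : 0.019 : 0.087.

The shipped fundamental tables are synthetic: Govardovskii et al. (2000)
A1 visual-pigment templates filtered by a smooth lens/macular-like
short-wave attenuation, with pigment peaks solved so the corneal peaks land
at 559/530/426 nm. They are stand-ins with realistic shape and peak
placement, not measured human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .spectra import SpectralSet, check_wavelengths

__all__ = [
    "ConeFundamental",
    "Observer",
    "NoiseModel",
    "ExcitationSample",
    "pigment_template",
    "corneal_sensitivity",
    "load_fundamentals",
    "loess_smooth",
    "shift_pigment",
    "make_observer",
    "cone_excitations",
    "add_cone_noise",
    "OBSERVER_NAMES",
]

# Normal corneal peak wavelengths (nm) and hybrid peaks used for anomalous
# trichromacy: protanomaly {530, 536}, deuteranomaly {559, 549}.
PEAK_L, PEAK_M, PEAK_S = 559.0, 530.0, 426.0
PEAK_PROTANOMAL_HYBRID = 536.0
PEAK_DEUTERANOMAL_HYBRID = 549.0

OBSERVER_NAMES = ("normal", "protanope", "deuteranope", "protanomal",
                  "deuteranomal", "m_monochromat", "l_monochromat")

# Stiles increment-threshold Weber fractions for L, M, S.
_STILES_WEBER = (0.018, 0.019, 0.087)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ConeFundamental:
    """Corneal spectral sensitivity of one cone class, peak-normalized to 1."""

    wavelengths: np.ndarray
    sensitivity: np.ndarray
    lambda_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.wavelengths = check_wavelengths(self.wavelengths)
        s = np.asarray(self.sensitivity, dtype=float)
        if s.shape != self.wavelengths.shape:
            raise ValueError("sensitivity and wavelengths must match")
        if s.min() < -1e-12:
            raise ValueError("sensitivity must be non-negative")
        peak = s.max()
        if peak <= 0:
            raise ValueError("sensitivity is identically zero")
        self.sensitivity = s / peak
        self.lambda_max = _interpolated_peak(self.wavelengths, self.sensitivity)

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Sensitivity linearly interpolated onto a wavelength grid."""
        grid = check_wavelengths(grid)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise ValueError("grid extends beyond the fundamental's support")
        return np.interp(grid, self.wavelengths, self.sensitivity)


def _interpolated_peak(wl: np.ndarray, s: np.ndarray) -> float:
    """Peak wavelength on a 0.1-nm interpolated grid around the coarse argmax."""
    i = int(np.argmax(s))
    lo = wl[max(i - 2, 0)]
    hi = wl[min(i + 2, wl.size - 1)]
    fine = np.arange(lo, hi + 0.05, 0.1)
    return float(fine[np.argmax(np.interp(fine, wl, s))])


@dataclass
class Observer:
    """A set of cone classes defining one (possibly color-deficient) observer."""

    name: str
    cones: list[ConeFundamental]
    cone_classes: list[str]  # each in {"L", "M", "S"}; hybrids take the
    # class of the nearest normal pigment (used for Weber-fraction scaling)

    def __post_init__(self) -> None:
        expected = {"normal": 3, "protanomal": 3, "deuteranomal": 3,
                    "protanope": 2, "deuteranope": 2,
                    "m_monochromat": 1, "l_monochromat": 1}
        if self.name in expected and len(self.cones) != expected[self.name]:
            raise ValueError(f"{self.name} must have {expected[self.name]} cones")
        if len(self.cone_classes) != len(self.cones):
            raise ValueError("cone_classes must match cones")
        if any(c not in ("L", "M", "S") for c in self.cone_classes):
            raise ValueError("cone classes must be L, M, or S")

    @property
    def n_cones(self) -> int:
        return len(self.cones)


@dataclass
class NoiseModel:
    """Weber-scaled Gaussian cone noise.

    ``weber_l`` is the relative SD for L cones; other classes use
    ``weber_l * weber_ratios[class]``, defaulting to the ratios of Stiles'
    Weber fractions (M/L = 0.019/0.018, S/L = 0.087/0.018).
    """

    weber_l: float = 0.02
    weber_ratios: dict[str, float] = field(default_factory=lambda: {
        "L": 1.0,
        "M": _STILES_WEBER[1] / _STILES_WEBER[0],
        "S": _STILES_WEBER[2] / _STILES_WEBER[0],
    })

    def __post_init__(self) -> None:
        if self.weber_l <= 0:
            raise ValueError("weber_l must be positive")
        if any(r <= 0 for r in self.weber_ratios.values()):
            raise ValueError("weber ratios must be positive")

    def relative_sd(self, cone_class: str) -> float:
        return self.weber_l * self.weber_ratios[cone_class]


@dataclass
class ExcitationSample:
    """Paired MI variables: X = radiance vectors, Y = noisy cone excitations."""

    x: np.ndarray
    y: np.ndarray
    observer: str
    weber_l: float

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must be paired (equal row counts)")
        if self.y.shape[1] not in (1, 2, 3):
            raise ValueError("y must have 1, 2, or 3 cone channels")


# ---------------------------------------------------------------------------
# Synthetic fundamentals
# ---------------------------------------------------------------------------

def pigment_template(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. (2000) A1 visual-pigment absorbance template."""
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lam_b = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_b) / b) ** 2))
    return alpha + beta


def _prereceptor_density(wl: np.ndarray) -> np.ndarray:
    # Smooth lens/macular-like optical density: strong below ~450 nm,
    # negligible beyond ~550 nm.
    return 1.2 * np.exp(-(wl - 380.0) / 45.0)


def corneal_sensitivity(wavelengths: np.ndarray, corneal_peak: float) -> np.ndarray:
    """Synthetic corneal sensitivity whose post-filter peak is at corneal_peak.

    The pigment lambda_max is solved so that after the pre-receptor
    attenuation the realized corneal peak equals the target.
    """
    wl = np.asarray(wavelengths, dtype=float)
    trans = 10.0 ** (-_prereceptor_density(wl))

    def realized_peak(pigment_peak: float) -> float:
        s = pigment_template(wl, pigment_peak) * trans
        return _interpolated_peak(wl, s / s.max())

    f = lambda p: realized_peak(p) - corneal_peak
    lo, hi = corneal_peak - 30.0, corneal_peak + 5.0
    pigment = brentq(f, lo, hi, xtol=0.01)
    s = pigment_template(wl, pigment) * trans
    return s / s.max()


def _data_path(name: str) -> Path:
    return Path(str(resources.files("conegain").joinpath("data", name)))


def load_fundamentals(fixture_table: str | Path | None = None
                      ) -> tuple[ConeFundamental, ConeFundamental, ConeFundamental]:
    """Load the L, M, S cone fundamentals from a fixture CSV.

    The CSV has columns wavelength_nm, L, M, S. The default table is the
    shipped synthetic one (corneal peaks 559/530/426 nm). The table must
    cover at least 400-720 nm.
    """
    path = Path(fixture_table) if fixture_table is not None else _data_path(
        "cone_fundamentals_synthetic.csv")
    data = np.genfromtxt(path, delimiter=",", names=True)
    wl = np.asarray(data["wavelength_nm"], dtype=float)
    if wl[0] > 400.0 or wl[-1] < 720.0:
        raise ValueError("fundamental table must cover at least 400-720 nm")
    out = tuple(ConeFundamental(wl, np.asarray(data[c], dtype=float))
                for c in ("L", "M", "S"))
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Loess smoothing and pigment shifting
# ---------------------------------------------------------------------------

def _loess_weights(u: np.ndarray, u0: float, h: float) -> np.ndarray:
    d = np.abs(u - u0) / h
    w = np.clip(1.0 - d**3, 0.0, None) ** 3
    return w


def _loess_fit_at(u: np.ndarray, y: np.ndarray, u0: float, h: float
                  ) -> tuple[float, np.ndarray]:
    """Local quadratic fit at u0; returns (fitted value, equivalent kernel)."""
    w = _loess_weights(u, u0, h)
    if np.count_nonzero(w) < 3:
        raise ValueError("loess bandwidth too small for the data spacing")
    du = u - u0
    X = np.stack([np.ones_like(du), du, du * du], axis=1)
    XtW = X.T * w
    beta_mat = np.linalg.solve(XtW @ X, XtW)  # (3, n): beta = beta_mat @ y
    return float(beta_mat[0] @ y), beta_mat[0]


def loess_smooth(u: np.ndarray, y: np.ndarray, span: float,
                 eval_u: np.ndarray | None = None) -> np.ndarray:
    """Quadratic loess smoother with tricube weights.

    ``span`` is the bandwidth as a fraction of the range of ``u``.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    h = span * (u.max() - u.min())
    pts = u if eval_u is None else np.asarray(eval_u, dtype=float)
    return np.array([_loess_fit_at(u, y, u0, h)[0] for u0 in pts])


def _loess_cv_error(u: np.ndarray, y: np.ndarray, span: float) -> float:
    """Exact leave-one-out CV error of the loess smoother (linear-smoother
    shortcut via the hat diagonal)."""
    h = span * (u.max() - u.min())
    resid2 = 0.0
    for i, u0 in enumerate(u):
        fit, kernel = _loess_fit_at(u, y, u0, h)
        hii = kernel[i]
        if hii >= 1.0 - 1e-12:
            return np.inf
        resid2 += ((y[i] - fit) / (1.0 - hii)) ** 2
    return resid2 / u.size


# Bandwidth grid for cross-validation, as fractions of the log-wavelength
# range. Lower bound keeps >= ~15 points in each window on a 1-nm table;
# upper bound avoids flattening the peak.
_LOESS_SPAN_GRID = (0.03, 0.05, 0.08, 0.12, 0.2)


def _best_span(u: np.ndarray, y: np.ndarray) -> float:
    errors = [_loess_cv_error(u, y, s) for s in _LOESS_SPAN_GRID]
    return _LOESS_SPAN_GRID[int(np.argmin(errors))]


def shift_pigment(fundamental: ConeFundamental, target_peak: float,
                  span: float | None = None, cv_subsample: int = 4
                  ) -> ConeFundamental:
    """Spectrally shift a cone fundamental to a new peak wavelength.

    The sensitivity is smoothed by a quadratic loess fit against log
    wavelength (bandwidth by leave-one-out cross-validation unless ``span``
    is given) and translated along the log-wavelength axis so its peak lands
    on ``target_peak``; shape on the log-wavelength axis is preserved.
    Shifts are limited to 35 nm. ``cv_subsample`` thins the table for the
    cross-validation pass only (it is O(n^2)).
    """
    shift = target_peak - fundamental.lambda_max
    if abs(shift) > 35.0:
        raise ValueError("pigment shifts beyond 35 nm are not supported")
    wl = fundamental.wavelengths
    u = np.log(wl)
    y = fundamental.sensitivity
    if span is None:
        sl = slice(None, None, max(int(cv_subsample), 1))
        span = _best_span(u[sl], y[sl])
    lo, hi = u.min(), u.max()
    if not (wl.min() + 5.0 < target_peak < wl.max() - 5.0):
        raise ValueError("shift target outside the fitted template's support")
    if abs(shift) < 1e-9:
        # Zero shift: return the smoothed template untranslated (the loess
        # peak may sit up to ~1 nm from the raw argmax, which the peak
        # contract tolerates).
        return ConeFundamental(wl, np.clip(loess_smooth(u, y, span),
                                           0.0, None))
    # Fixed-point refinement: the loess peak can sit a fraction of a nm away
    # from the raw argmax, so adjust the log-shift until the realized peak is
    # within the 1-nm contract.
    delta = np.log(target_peak / fundamental.lambda_max)
    out = None
    for _ in range(4):
        eval_u = np.clip(u - delta, lo, hi)
        shifted = np.clip(loess_smooth(u, y, span, eval_u=eval_u), 0.0, None)
        out = ConeFundamental(wl, shifted)
        err = out.lambda_max - target_peak
        if abs(err) <= 0.3:
            break
        delta -= np.log(out.lambda_max / target_peak)
    return out


# ---------------------------------------------------------------------------
# Observers
# ---------------------------------------------------------------------------

def make_observer(name: str,
                  fundamentals: tuple[ConeFundamental, ConeFundamental,
                                      ConeFundamental] | None = None) -> Observer:
    """Build a named observer from L, M, S fundamentals.

    protanope = {M, S}; deuteranope = {L, S};
    protanomal = {M(530), M'(536), S}; deuteranomal = {L(559), L'(549), S};
    m_monochromat = {M}; l_monochromat = {L}. S is unaltered throughout.
    """
    if name not in OBSERVER_NAMES:
        raise ValueError(f"unknown observer {name!r}; choose from {OBSERVER_NAMES}")
    if fundamentals is None:
        fundamentals = load_fundamentals()
    L, M, S = fundamentals
    if name == "normal":
        return Observer(name, [L, M, S], ["L", "M", "S"])
    if name == "protanope":
        return Observer(name, [M, S], ["M", "S"])
    if name == "deuteranope":
        return Observer(name, [L, S], ["L", "S"])
    if name == "protanomal":
        hybrid = shift_pigment(M, PEAK_PROTANOMAL_HYBRID)
        return Observer(name, [M, hybrid, S], ["M", "M", "S"])
    if name == "deuteranomal":
        hybrid = shift_pigment(L, PEAK_DEUTERANOMAL_HYBRID)
        return Observer(name, [L, hybrid, S], ["L", "L", "S"])
    if name == "m_monochromat":
        return Observer(name, [M], ["M"])
    return Observer(name, [L], ["L"])


# ---------------------------------------------------------------------------
# Excitations and noise
# ---------------------------------------------------------------------------

def cone_excitations(spectra: SpectralSet, observer: Observer) -> np.ndarray:
    """Noiseless cone excitations q_c = integral of L(lambda) S_c(lambda) d lambda.

    Fundamentals are resampled onto the spectra's wavelength grid and the
    integral is evaluated by the trapezoid rule. Returns an (n, c) matrix.
    """
    wl = spectra.wavelengths
    # Trapezoid quadrature weights for the (possibly non-uniform) grid.
    w = np.zeros_like(wl)
    dw = np.diff(wl)
    w[:-1] += dw / 2.0
    w[1:] += dw / 2.0
    sens = np.stack([c.resample(wl) for c in observer.cones], axis=1)  # (b, c)
    return spectra.spectra @ (sens * w[:, None])


def add_cone_noise(excitations: np.ndarray, noise: NoiseModel,
                   cone_classes: list[str],
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add Weber-scaled Gaussian noise: y = q + eps, eps ~ N(0, (w_c q)^2).

    Noise is independent across samples and cone classes; zero excitation
    yields exactly zero noise.
    """
    q = np.atleast_2d(np.asarray(excitations, dtype=float))
    if q.min() < 0:
        raise ValueError("excitations must be non-negative")
    if q.shape[1] != len(cone_classes):
        raise ValueError("cone_classes must match excitation columns")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = np.array([noise.relative_sd(c) for c in cone_classes])
    return q + rng.standard_normal(q.shape) * (q * sd)


def excitation_sample(spectra: SpectralSet, observer: Observer,
                      noise: NoiseModel,
                      seed: int | np.random.Generator = 0) -> ExcitationSample:
    """Paired (X, Y) draw for mutual-information estimation."""
    q = cone_excitations(spectra, observer)
    y = add_cone_noise(q, noise, observer.cone_classes, seed)
    return ExcitationSample(spectra.spectra, y, observer.name, noise.weber_l)
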