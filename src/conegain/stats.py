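"""Resampling and regression statistics for the scene analyses.

Covers Efron's percentile bootstrap (nonparametric, resampling cases),
the logit transform used to linearize variance proportions, ordinary
least-squares regression with a bootstrap CI on the gradient, and
linear-circular regression for axial data (angles defined modulo 180°,
doubled onto the circle, regressed on cosine and sine, and folded back).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "BootstrapCI",
    "LinearFit",
    "CircularFit",
    "percentile_bootstrap_ci",
    "logit",
    "linear_regression",
    "circular_linear_regression",
    "circular_mean_axial",
]


@dataclass
class BootstrapCI:
    """Percentile-bootstrap 95% confidence interval."""

    point_estimate: float
    lo: float
    hi: float
    reps: int

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("use at least 100 bootstrap replications")
        if not self.lo <= self.hi:
            raise ValueError("interval bounds out of order")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def percentile_bootstrap_ci(samples: np.ndarray, statistic_fn,
                            reps: int = 1000,
                            seed: int | np.random.Generator = 0,
                            level: float = 0.95) -> BootstrapCI:
    """Efron's percentile bootstrap CI for a statistic of an i.i.d. sample.

    Cases (rows) are resampled with replacement ``reps`` times; the interval
    is the (2.5th, 97.5th) percentile pair of the bootstrap distribution of
    the statistic (for the default 95% level).
    """
    samples = np.asarray(samples)
    n = samples.shape[0]
    if n < 5:
        raise ValueError("bootstrap needs at least 5 cases")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = float(statistic_fn(samples))
    boot = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        boot[r] = statistic_fn(samples[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(point, float(lo), float(hi), reps)


def logit(p: float | np.ndarray) -> float | np.ndarray:
    """Logistic transform ln(p / (1 - p)); refuses boundary values.

    Callers must clamp proportions away from {0, 1} explicitly; silently
    nudging data here would hide an edit.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("logit requires proportions strictly inside (0, 1)")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class LinearFit:
    """OLS fit with a bootstrap CI on the gradient."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci: BootstrapCI | None = None


def linear_regression(x: np.ndarray, y: np.ndarray, reps: int = 1000,
                      seed: int = 0, ci: bool = True) -> LinearFit:
    """Least-squares line with R^2 and a case-resampling bootstrap CI on the
    slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = sstats.linregress(x, y)
    fit = LinearFit(float(res.slope), float(res.intercept),
                    float(res.rvalue**2))
    if ci:
        data = np.column_stack([x, y])

        def stat(rows: np.ndarray) -> float:
            if np.ptp(rows[:, 0]) == 0:
                return fit.slope  # degenerate resample; fall back
            return sstats.linregress(rows[:, 0], rows[:, 1]).slope

        fit.slope_ci = percentile_bootstrap_ci(data, stat, reps=reps, seed=seed)
    return fit


@dataclass
class CircularFit:
    """Linear-circular regression on axial data.

    The model is y = b0 + b1 cos(2 phi) + b2 sin(2 phi) with phi the axial
    angle in degrees; extremum directions are folded back to [0, 180).
    """

    intercept: float
    cos_coef: float
    sin_coef: float
    r_squared: float
    max_dir: float
    min_dir: float
    circular_mean_dir: float

    def __post_init__(self) -> None:
        sep = abs((self.max_dir - self.min_dir) % 180.0)
        if min(sep, 180.0 - sep) - 90.0 > 1e-6:
            raise ValueError("extremum directions must be 90 degrees apart")

    def predict(self, angles_deg: np.ndarray) -> np.ndarray:
        t = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
        return self.intercept + self.cos_coef * np.cos(t) + self.sin_coef * np.sin(t)


def circular_mean_axial(angles_deg: np.ndarray) -> float:
    """Circular mean of axial data (mod 180): double, average on the circle,
    halve."""
    t = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    mean = math.atan2(np.sin(t).mean(), np.cos(t).mean())
    return (math.degrees(mean) / 2.0) % 180.0


def circular_linear_regression(angles_axial_deg: np.ndarray,
                               y: np.ndarray) -> CircularFit:
    """Regress y on an axial angle by doubling it onto the full circle.

    Axial angles (mod 180 deg) are doubled, y is regressed on the cosine and
    sine of the doubled angle, and the fitted extremum directions are folded
    back to [0, 180).
    """
    phi = np.asarray(angles_axial_deg, dtype=float)
    y = np.asarray(y, dtype=float)
    if phi.size != y.size or phi.size < 4:
        raise ValueError("need at least 4 paired points")
    if np.any((phi < 0) | (phi >= 180)):
        raise ValueError("axial angles must lie in [0, 180)")
    t = np.radians(2.0 * phi)
    design = np.column_stack([np.ones_like(t), np.cos(t), np.sin(t)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("collinear design; angles do not span the circle")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    b0, b1, b2 = (float(v) for v in beta)
    if math.hypot(b1, b2) < 1e-12:
        max_dir = 0.0
        min_dir = 90.0
    else:
        max_dir = (math.degrees(math.atan2(b2, b1)) / 2.0) % 180.0
        min_dir = (max_dir + 90.0) % 180.0
    return CircularFit(b0, b1, b2, r2, max_dir, min_dir,
                       circular_mean_axial(phi))
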