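"""Containers for spectra, hyperspectral images, and spectral sets.

The whole pipeline works on three closely related objects: a single
:class:`Spectrum` (radiance or reflectance versus wavelength), a
:class:`SpectralImage` (an ``h x w x bands`` radiance cube with its
wavelength grid), and a :class:`SpectralSet` (a flat ``n x bands`` matrix of
spectra sampled from one or more images, with provenance).  All wavelength
grids are in nanometres and must be strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Spectrum", "SpectralImage", "SpectralSet", "check_wavelengths"]


def check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    """Validate a wavelength grid: 1-D, finite, strictly increasing (nm)."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with >= 2 entries")
    if not np.all(np.isfinite(wl)):
        raise ValueError("wavelength grid contains non-finite values")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return wl


@dataclass
class Spectrum:
    """A single spectrum on a wavelength grid.

    Parameters
    ----------
    wavelengths : array, nm
    values : array
        Spectral radiance (power per area per solid angle per nm, arbitrary
        linear units) or dimensionless reflectance in [0, 1].
    kind : {"radiance", "reflectance"}
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "radiance"

    def __post_init__(self) -> None:
        self.wavelengths = check_wavelengths(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values and wavelengths must have the same length")
        if self.kind not in ("radiance", "reflectance"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
        if self.kind == "reflectance":
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError("reflectance values must lie in [0, 1]")
        elif self.values.min() < -1e-12:
            raise ValueError("radiance values must be non-negative")

    def interpolate(self, grid: np.ndarray) -> "Spectrum":
        """Linearly interpolate onto a new grid (no extrapolation)."""
        grid = check_wavelengths(grid)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise ValueError("interpolation grid extends beyond the source range")
        vals = np.interp(grid, self.wavelengths, self.values)
        return Spectrum(grid, vals, self.kind)


@dataclass
class SpectralImage:
    """Hyperspectral radiance image: ``values[h, w, b]`` with wavelengths[b]."""

    values: np.ndarray
    wavelengths: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = check_wavelengths(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("image values must be h x w x bands")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        self.metadata = dict(self.metadata)
        self.metadata.setdefault("scene_id", "unknown")
        self.metadata.setdefault("landcover", "unknown")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0] * self.values.shape[1]

    def flatten(self) -> "SpectralSet":
        """All pixels as a SpectralSet (row-major pixel order)."""
        h, w, b = self.values.shape
        return SpectralSet(
            spectra=self.values.reshape(h * w, b),
            wavelengths=self.wavelengths,
            provenance={"scene_id": self.metadata.get("scene_id"),
                        "pixel_index": np.arange(h * w)},
        )


@dataclass
class SpectralSet:
    """A flat collection of spectra sharing one wavelength grid."""

    spectra: np.ndarray
    wavelengths: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = check_wavelengths(self.wavelengths)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[0] < 1:
            raise ValueError("spectral set must contain at least one spectrum")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra band count does not match wavelength grid")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectral set contains non-finite values")

    def __len__(self) -> int:
        return self.spectra.shape[0]
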