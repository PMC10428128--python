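"""Reading, writing, and conditioning of hyperspectral radiance images.

Native storage is a single HDF5 layout::

    /radiance        float32, shape (h, w, bands)
    /wavelengths_nm  float64, shape (bands,)
    attrs: scene_id, landcover

Read-only adapters exist for ENVI (.hdr + binary) and MATLAB v7.3 cubes
(which are HDF5 files underneath). Conditioning operations cover wavelength
resampling, 2x2 spatial averaging (used to reduce pixel-pixel correlations
and non-imaging noise), dark-offset subtraction, random pixel sampling, and
removal of the upper half of a scene (the sky-crop control).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import h5py
import numpy as np

from .spectra import SpectralImage, SpectralSet, check_wavelengths

__all__ = [
    "read_hyperspectral",
    "write_hyperspectral",
    "resample_wavelengths",
    "downsample_2x2",
    "subtract_dark_offset",
    "estimate_dark_offset",
    "sample_spectra",
    "crop_upper_half",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def write_hyperspectral(image: SpectralImage, path: str | Path) -> None:
    """Write a SpectralImage in the native HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("radiance", data=image.values.astype(np.float32))
        f.create_dataset("wavelengths_nm", data=image.wavelengths.astype(np.float64))
        f.attrs["scene_id"] = str(image.metadata.get("scene_id", "unknown"))
        f.attrs["landcover"] = str(image.metadata.get("landcover", "unknown"))


def _read_native_h5(path: Path) -> SpectralImage:
    with h5py.File(path, "r") as f:
        if "radiance" not in f or "wavelengths_nm" not in f:
            raise ValueError(f"{path}: not a native layout (radiance/wavelengths_nm)")
        values = np.asarray(f["radiance"], dtype=float)
        wl = np.asarray(f["wavelengths_nm"], dtype=float)
        meta = {"scene_id": f.attrs.get("scene_id", path.stem),
                "landcover": f.attrs.get("landcover", "unknown"),
                "source": str(path)}
    return SpectralImage(values, wl, meta)


def _read_mat_v73(path: Path) -> SpectralImage:
    """MAT v7.3 cube: first 3-D dataset is the cube; a 1-D dataset whose name
    contains 'wave'/'bands'/'lambda' supplies wavelengths (required)."""
    cube = None
    wl = None
    with h5py.File(path, "r") as f:
        for name, ds in f.items():
            if not isinstance(ds, h5py.Dataset):
                continue
            if ds.ndim == 3 and cube is None:
                cube = np.asarray(ds, dtype=float)
            elif ds.ndim <= 2 and re.search(r"wave|band|lambda", name, re.I):
                wl = np.asarray(ds, dtype=float).ravel()
    if cube is None:
        raise ValueError(f"{path}: no 3-D cube found")
    if wl is None:
        raise ValueError(f"{path}: wavelength metadata missing; refusing to guess")
    # MATLAB stores arrays column-major, so the band axis may land anywhere;
    # identify it by the wavelength count and move it last.
    band_axes = [ax for ax, size in enumerate(cube.shape) if size == wl.size]
    if not band_axes:
        raise ValueError(f"{path}: no cube axis matches the wavelength count")
    cube = np.moveaxis(cube, band_axes[0], -1)
    return SpectralImage(cube, wl, {"scene_id": path.stem, "source": str(path)})


def _read_envi(path: Path) -> SpectralImage:
    """ENVI header + raw binary (BSQ/BIL/BIP interleave)."""
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr}")
    text = hdr.read_text()
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.M):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    try:
        h = int(fields["lines"]); w = int(fields["samples"]); b = int(fields["bands"])
    except KeyError as e:
        raise ValueError(f"{hdr}: missing ENVI field {e}") from e
    if "wavelength" not in fields:
        raise ValueError(f"{hdr}: wavelength metadata missing; refusing to guess")
    wl = np.array([float(v) for v in
                   re.split(r"[,\s]+", fields["wavelength"].strip("{} \n")) if v])
    dtype_map = {"1": np.uint8, "2": np.int16, "4": np.float32, "5": np.float64,
                 "12": np.uint16}
    dt = dtype_map.get(fields.get("data type", "4"), np.float32)
    interleave = fields.get("interleave", "bsq").lower()
    raw_path = None
    for suffix in ("", ".raw", ".img", ".dat", ".bsq"):
        cand = path.with_suffix(suffix) if suffix else path.with_suffix("")
        if cand.exists() and cand != hdr:
            raw_path = cand
            break
    if raw_path is None:
        raise FileNotFoundError(f"ENVI binary for {hdr} not found")
    data = np.fromfile(raw_path, dtype=dt)
    if data.size != h * w * b:
        raise ValueError(f"{raw_path}: size mismatch with header dimensions")
    if interleave == "bsq":
        cube = data.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = data.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = data.reshape(h, w, b)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    return SpectralImage(cube.astype(float), wl,
                         {"scene_id": path.stem, "source": str(raw_path)})


def read_hyperspectral(path: str | Path, format_hint: str | None = None) -> SpectralImage:
    """Read a hyperspectral radiance image.

    Formats: native HDF5 layout (``"h5"``), ENVI header+binary (``"envi"``),
    MAT v7.3 cube (``"mat"``). Wavelength metadata is required in every
    format and is never guessed. No resampling is applied.
    """
    path = Path(path)
    if not path.exists() and not path.with_suffix(".hdr").exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"": "envi", ".hdr": "envi", ".raw": "envi", ".img": "envi",
               ".mat": "mat", ".h5": "h5", ".hdf5": "h5"}.get(suffix)
    if fmt == "h5":
        return _read_native_h5(path)
    if fmt == "mat":
        return _read_mat_v73(path)
    if fmt == "envi":
        return _read_envi(path)
    raise ValueError(f"unknown hyperspectral format for {path}")


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def resample_wavelengths(image: SpectralImage, grid: np.ndarray) -> SpectralImage:
    """Linearly interpolate an image onto a new wavelength grid.

    The target grid must lie within the source range; extrapolation is
    refused.
    """
    grid = check_wavelengths(grid)
    src = image.wavelengths
    if grid[0] < src[0] - 1e-9 or grid[-1] > src[-1] + 1e-9:
        raise ValueError("target grid requires extrapolation beyond source range")
    h, w, b = image.values.shape
    flat = image.values.reshape(h * w, b)
    # Precompute linear-interpolation indices and weights once per target band.
    i1 = np.clip(np.searchsorted(src, grid), 1, b - 1)
    i0 = i1 - 1
    t = (grid - src[i0]) / (src[i1] - src[i0])
    t = np.clip(t, 0.0, 1.0)
    out = flat[:, i0] * (1.0 - t) + flat[:, i1] * t
    return SpectralImage(out.reshape(h, w, grid.size), grid, dict(image.metadata))


def downsample_2x2(image: SpectralImage) -> SpectralImage:
    """Spatial averaging over 2x2 pixel blocks; trailing odd row/column dropped."""
    h, w, b = image.values.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2 for downsampling")
    h2, w2 = h // 2, w // 2
    v = image.values[: 2 * h2, : 2 * w2]
    out = v.reshape(h2, 2, w2, 2, b).mean(axis=(1, 3))
    return SpectralImage(out, image.wavelengths, dict(image.metadata))


def estimate_dark_offset(image: SpectralImage, percentile: float = 0.1) -> np.ndarray:
    """Per-band dark-offset estimate: a low percentile of each band."""
    h, w, b = image.values.shape
    return np.percentile(image.values.reshape(h * w, b), percentile, axis=0)


def subtract_dark_offset(image: SpectralImage, offset: np.ndarray,
                         force: bool = False) -> SpectralImage:
    """Subtract a per-band dark-noise offset, clipping at zero.

    An offset exceeding the 99th percentile of any band is treated as
    suspicious and refused unless ``force=True``.
    """
    offset = np.asarray(offset, dtype=float)
    if offset.ndim == 0:
        offset = np.full(image.wavelengths.size, float(offset))
    if offset.shape != image.wavelengths.shape:
        raise ValueError("offset must be scalar or per-band")
    if np.any(offset < 0):
        raise ValueError("dark offset must be non-negative")
    h, w, b = image.values.shape
    p99 = np.percentile(image.values.reshape(h * w, b), 99, axis=0)
    if np.any(offset > p99) and not force:
        raise ValueError("offset exceeds the 99th percentile of a band; "
                         "pass force=True if this is intended")
    corrected = image.values - offset
    n_clipped = int(np.count_nonzero(corrected < 0))
    if n_clipped:
        logger.info("dark-offset subtraction clipped %d negative values", n_clipped)
    return SpectralImage(np.maximum(corrected, 0.0), image.wavelengths,
                         dict(image.metadata))


def sample_spectra(image: SpectralImage, n: int, seed: int | np.random.Generator = 0,
                   replace: bool = True) -> SpectralSet:
    """Draw ``n`` pixels uniformly at random from an image.

    With ``replace=True`` (default) the image is treated as an empirical
    distribution over the underlying continuous radiance distribution; with
    ``replace=False`` at most the pixel count may be drawn.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    h, w, b = image.values.shape
    n_pix = h * w
    if not replace and n > n_pix:
        raise ValueError("cannot draw more pixels than exist without replacement")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n_pix, size=n, replace=replace)
    flat = image.values.reshape(n_pix, b)
    return SpectralSet(flat[idx], image.wavelengths,
                       {"scene_id": image.metadata.get("scene_id"),
                        "pixel_index": idx})


def crop_upper_half(image: SpectralImage) -> SpectralImage:
    """Remove the upper half of a scene (row 0 = top), keeping the lower
    ceil(h/2) rows. Used as the sky-removal control."""
    h = image.values.shape[0]
    if h < 2:
        raise ValueError("image must have at least 2 rows to crop")
    keep_from = h // 2
    meta = dict(image.metadata)
    meta["sky_cropped"] = True
    return SpectralImage(image.values[keep_from:], image.wavelengths, meta)
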