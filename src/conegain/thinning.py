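"""Uniformization of spectral sets by sup-metric thinning.

Natural scenes contain strongly uneven frequencies of different colored
surfaces. To approximate a uniform frequency distribution over the gamut,
spectra lying within sup-metric distance d of already retained spectra are
removed (thinning); taking the union of thinned sets across scenes and
thinning once more yields a gamut-maximizing condition. The sup metric is
d(l_r, l_s) = sup_lambda |l_r(lambda) - l_s(lambda)|.

The greedy retention order is randomized with a seed: the removal order is
not uniquely defined by the criterion and changes which spectra survive, so
order-sensitive results should be seed-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .spectra import Spectrum, SpectralSet

__all__ = ["ThinningResult", "sup_distance", "thin_spectra", "adaptive_thin",
           "union_gamut"]


@dataclass
class ThinningResult:
    """Outcome of a thinning pass.

    Every pair of retained spectra is at sup-distance >= d; every removed
    spectrum lies within d of some retained one. ``history`` records
    (d, retained_count, info_bits) rows when produced adaptively.
    """

    retained: SpectralSet
    d: float
    removed_count: int
    history: list[tuple[float, int, float | None]] = field(default_factory=list)


def sup_distance(s1: Spectrum | np.ndarray, s2: Spectrum | np.ndarray) -> float:
    """Sup-metric distance: max over bands of the absolute difference."""
    v1 = s1.values if isinstance(s1, Spectrum) else np.asarray(s1, dtype=float)
    v2 = s2.values if isinstance(s2, Spectrum) else np.asarray(s2, dtype=float)
    if isinstance(s1, Spectrum) and isinstance(s2, Spectrum):
        if not np.array_equal(s1.wavelengths, s2.wavelengths):
            raise ValueError("spectra are on different wavelength grids")
    if v1.shape != v2.shape:
        raise ValueError("spectra have different band counts")
    return float(np.max(np.abs(v1 - v2)))


def thin_spectra(spectral_set: SpectralSet, d: float,
                 order_seed: int | np.random.Generator = 0) -> ThinningResult:
    """Greedy sequential thinning at sup-metric radius d.

    Spectra are visited in a seeded random order; each is retained iff its
    sup-distance to every already retained spectrum is >= d.
    """
    if d < 0:
        raise ValueError("thinning radius must be non-negative")
    spectra = spectral_set.spectra
    n = spectra.shape[0]
    rng = (order_seed if isinstance(order_seed, np.random.Generator)
           else np.random.default_rng(order_seed))
    order = rng.permutation(n)
    if d == 0:
        return ThinningResult(spectral_set, 0.0, 0)

    retained_idx: list[int] = []
    # Incremental KD-tree rebuilds amortize neighbor checks; the Chebyshev
    # metric (p=inf) is exactly the sup metric.
    tree: cKDTree | None = None
    tree_size = 0
    pending: list[int] = []
    for i in order:
        ok = True
        if tree is not None:
            dist, _ = tree.query(spectra[i], k=1, p=np.inf)
            ok = dist >= d
        if ok and pending:
            block = spectra[pending]
            if np.min(np.max(np.abs(block - spectra[i]), axis=1)) < d:
                ok = False
        if ok:
            retained_idx.append(i)
            pending.append(i)
            if len(pending) >= max(64, tree_size // 4):
                tree = cKDTree(spectra[retained_idx])
                tree_size = len(retained_idx)
                pending = []
    idx = np.array(retained_idx)
    prov = dict(spectral_set.provenance)
    prov["thinned_index"] = idx
    retained = SpectralSet(spectra[idx], spectral_set.wavelengths, prov)
    return ThinningResult(retained, d, n - idx.size)


def adaptive_thin(spectral_set: SpectralSet, info_fn, d_grid,
                  stability_tol: float = 0.05, count_floor: int = 500,
                  order_seed: int = 0) -> ThinningResult:
    """Thin at progressively larger d until information estimates stabilize.

    ``info_fn(spectral_set) -> bits`` evaluates the information measure on a
    candidate subset. Returns the result at the largest d in the increasing
    ``d_grid`` for which the estimate changed by less than ``stability_tol``
    bits from the previous d and the retained count is at least
    ``count_floor``. The full (d, count, bits) history is recorded.
    """
    d_grid = np.asarray(list(d_grid), dtype=float)
    if np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be strictly increasing")
    history: list[tuple[float, int, float | None]] = []
    best: ThinningResult | None = None
    prev_bits: float | None = None
    for d in d_grid:
        res = thin_spectra(spectral_set, float(d), order_seed)
        n_ret = len(res.retained)
        if n_ret < count_floor:
            history.append((float(d), n_ret, None))
            break
        bits = float(info_fn(res.retained))
        history.append((float(d), n_ret, bits))
        if prev_bits is None or abs(bits - prev_bits) < stability_tol:
            best = res
        prev_bits = bits
    if best is None:
        raise ValueError("no thinning radius meets the retained-count floor")
    best.history = history
    return best


def union_gamut(thinned_sets: list[SpectralSet], d: float,
                order_seed: int = 0) -> ThinningResult:
    """Union of thinned per-scene sets, thinned once more at radius d."""
    if not thinned_sets:
        raise ValueError("need at least one spectral set")
    wl = thinned_sets[0].wavelengths
    for s in thinned_sets[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("spectral sets are on different wavelength grids")
    spectra = np.concatenate([s.spectra for s in thinned_sets], axis=0)
    prov = {"scene_id": [s.provenance.get("scene_id") for s in thinned_sets],
            "union_sizes": [len(s) for s in thinned_sets]}
    merged = SpectralSet(spectra, wl, prov)
    return thin_spectra(merged, d, order_seed)
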