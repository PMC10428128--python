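"""Shared fixtures: fundamentals, observers, and small synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from conegain import synthetic
from conegain.cones import NoiseModel, load_fundamentals, make_observer


@pytest.fixture(scope="session")
def fundamentals():
    return load_fundamentals()


@pytest.fixture(scope="session")
def observers(fundamentals):
    names = ("normal", "protanope", "deuteranope", "protanomal",
             "deuteranomal", "m_monochromat", "l_monochromat")
    return {n: make_observer(n, fundamentals) for n in names}


@pytest.fixture(scope="session")
def noise_2pct():
    return NoiseModel(weber_l=0.02)


@pytest.fixture(scope="session")
def natural_scene():
    """One calibrated natural-like scene (77/8/15 variance shares)."""
    return synthetic.generate_scene(synthetic.SceneSpec(seed=1))


@pytest.fixture(scope="session")
def small_scene():
    """A fast 64x64 scene for IO and conditioning tests."""
    return synthetic.generate_scene(synthetic.SceneSpec(width=64, height=64,
                                                        seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
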