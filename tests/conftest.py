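"""Shared fixtures: phantoms and probes are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from hepavess.phantom import PhantomSpec, make_phantom, make_shape_probe


@pytest.fixture(scope="session")
def phantom_triplet():
    """Default-sized noisy phantom: (volume, liver mask, vessel mask)."""
    return make_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def small_phantom():
    """Quick 64^3 phantom for tests that only need plausible structure."""
    spec = PhantomSpec(shape=(64, 64, 64), tree_depth=2, root_radius=4.0,
                      n_blobs=2, n_plates=1, noise_sigma=8.0, seed=5)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def tube_probe():
    return make_shape_probe("tube", size=64, radius=5.0)


@pytest.fixture(scope="session")
def blob_probe():
    return make_shape_probe("blob", size=64, radius=5.0)


@pytest.fixture(scope="session")
def plate_probe():
    return make_shape_probe("plate", size=64, radius=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
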