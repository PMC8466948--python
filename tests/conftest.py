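import numpy as np
import pytest

import trabmorph as tm


@pytest.fixture(scope="session")
def plate_spec():
    """Canonical plate phantom: 0.25 mm plates / 0.75 mm gaps at 0.05 mm.

    265 rows = 13 full periods + one closing plate, so every gap is bounded
    by bone on both sides; morphometry uses an interior ROI one period in
    from the top/bottom edges.
    """
    return tm.PhantomSpec("plates", {"t": 0.25, "s": 0.75}, (265, 64), 0.05)


@pytest.fixture(scope="session")
def plate_phantom(plate_spec):
    return tm.make_plate_phantom(plate_spec)


@pytest.fixture(scope="session")
def plate_roi():
    return (20, 0, 220, 64)


@pytest.fixture(scope="session")
def rod_phantom_bimodal():
    spec = tm.PhantomSpec(
        "rods",
        {"angles_deg": [67.0, 157.0], "weights": [0.7, 0.3],
         "rod_width": 0.12, "base_spacing": 0.55},
        (160, 160), 0.05, seed=1)
    return tm.make_rod_phantom(spec)


@pytest.fixture(scope="session")
def rod_phantom_single():
    spec = tm.PhantomSpec(
        "rods",
        {"angles_deg": [67.0], "weights": [1.0],
         "rod_width": 0.12, "base_spacing": 0.6},
        (160, 160), 0.05, seed=1)
    return tm.make_rod_phantom(spec)


def random_mask(rng, max_size=32, p=None):
    """Random binary mask with both phases present."""
    h = int(rng.integers(8, max_size + 1))
    w = int(rng.integers(8, max_size + 1))
    if p is None:
        p = rng.uniform(0.2, 0.8)
    while True:
        m = rng.random((h, w)) < p
        if m.any() and (~m).any():
            return m
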