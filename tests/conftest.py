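import numpy as np
import pytest

from thermoroi.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def hand_phantom():
    return generate_phantom(PhantomSpec(region="hand", seed=1, side="right"))


@pytest.fixture(scope="session")
def hand_phantom_left():
    return generate_phantom(PhantomSpec(region="hand", seed=1, side="left"))


@pytest.fixture(scope="session")
def shin_phantom():
    return generate_phantom(PhantomSpec(region="shin", seed=1, side="both"))


@pytest.fixture(scope="session")
def foot_phantom():
    return generate_phantom(PhantomSpec(region="foot", seed=1, side="right"))


def structured_masks(max_side=64):
    """Small binary masks exercising morphology edge cases: discs,
    rectangles, blobs with protrusions, sparse noise."""
    rng = np.random.default_rng(7)
    masks = []
    rr, cc = np.mgrid[0:max_side, 0:max_side]
    masks.append((rr - 32) ** 2 + (cc - 32) ** 2 <= 100)        # disc r=10
    m = np.zeros((max_side, max_side), bool)
    m[10:50, 20:44] = True                                       # rectangle
    masks.append(m)
    m = m.copy()
    m[4:12, 30:36] = True                                        # protrusion
    masks.append(m)
    for density in (0.3, 0.6):
        masks.append(rng.random((48, 48)) < density)
    m = np.zeros((40, 60), bool)                                 # two blobs
    m[5:20, 5:25] = True
    m[22:38, 30:55] = True
    masks.append(m)
    return masks


@pytest.fixture(scope="session")
def mask_suite():
    return structured_masks()
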